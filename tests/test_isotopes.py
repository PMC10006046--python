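"""Isotopologue forward model against exhaustive enumeration oracles."""

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from sipturnover import (
    IsotopePattern,
    MolecularFormula,
    NATURAL_ABUNDANCE,
    NATURAL_C13,
    ObservedSpectrum,
    carbon_pattern,
    convolve,
    isotope_pattern,
    mixture_spectrum,
)


def enumerate_pattern_by_atom(formula: MolecularFormula, c13_fraction: float) -> np.ndarray:
    """Oracle: enumerate every isotope assignment of every atom (small formulas)."""
    atom_tables = []
    for el, cnt in formula.counts.items():
        table = {0: 1.0 - c13_fraction, 1: c13_fraction} if el == "C" else NATURAL_ABUNDANCE[el]
        atom_tables.extend([sorted(table.items())] * cnt)
    dist: dict[int, float] = defaultdict(float)
    for combo in itertools.product(*atom_tables):
        shift = sum(s for s, _ in combo)
        prob = math.prod(p for _, p in combo)
        dist[shift] += prob
    out = np.zeros(max(dist) + 1)
    for shift, p in dist.items():
        out[shift] = p
    return out


def enumerate_pattern_by_counts(formula: MolecularFormula, c13_fraction: float) -> np.ndarray:
    """Oracle: enumerate isotope-count compositions per element (multinomial pmf)."""
    dist = {0: 1.0}
    for el, cnt in formula.counts.items():
        if cnt == 0:
            continue
        table = {0: 1.0 - c13_fraction, 1: c13_fraction} if el == "C" else NATURAL_ABUNDANCE[el]
        shifts = sorted(table)
        el_dist: dict[int, float] = defaultdict(float)
        for counts in itertools.product(range(cnt + 1), repeat=len(shifts)):
            if sum(counts) != cnt:
                continue
            coef = math.factorial(cnt)
            p = 1.0
            shift = 0
            for s, k in zip(shifts, counts):
                coef //= math.factorial(k)
                p *= table[s] ** k
                shift += s * k
            el_dist[shift] += coef * p
        new: dict[int, float] = defaultdict(float)
        for s1, p1 in dist.items():
            for s2, p2 in el_dist.items():
                new[s1 + s2] += p1 * p2
        dist = new
    out = np.zeros(max(dist) + 1)
    for shift, p in dist.items():
        out[shift] = p
    return out


class TestCarbonPattern:
    def test_single_carbon_is_bernoulli(self):
        assert np.allclose(carbon_pattern(1, NATURAL_C13), [1 - NATURAL_C13, NATURAL_C13])

    def test_two_carbons_half_enriched(self):
        assert np.allclose(carbon_pattern(2, 0.5), [0.25, 0.5, 0.25], atol=1e-15)

    @pytest.mark.parametrize("n_c,frac", [(1, 0.0107), (6, 0.5), (40, 0.99), (65, 0.65), (10, 0.0)])
    def test_mean_is_binomial_mean(self, n_c, frac):
        pat = carbon_pattern(n_c, frac)
        mean = float(np.arange(pat.size) @ pat)
        assert mean == pytest.approx(n_c * frac, abs=1e-10)
        assert pat.sum() == pytest.approx(1.0, abs=1e-12)


class TestIsotopePattern:
    @pytest.mark.parametrize(
        "hill, frac",
        [("CH4", 0.0107), ("C2H2O", 0.3), ("C3NOS", 0.99), ("C4H6N2", 0.65)],
    )
    def test_matches_atom_enumeration_small_formulas(self, hill, frac):
        f = MolecularFormula.from_hill(hill)
        assert f.n_atoms <= 12
        oracle = enumerate_pattern_by_atom(f, frac)
        got = isotope_pattern(f, frac, tail=0).abundance
        assert got.size == oracle.size
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_glucose_matches_count_enumeration(self, glucose):
        oracle = enumerate_pattern_by_counts(glucose, NATURAL_C13)
        got = isotope_pattern(glucose, tail=0).abundance
        assert abs(got[1] - oracle[1]) < 1e-4
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_natural_fraction_equals_default_path(self, tryptic_peptide):
        a = isotope_pattern(tryptic_peptide).abundance
        b = isotope_pattern(tryptic_peptide, NATURAL_C13).abundance
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_truncation_keeps_normalization(self, tryptic_peptide):
        pat = isotope_pattern(tryptic_peptide, 0.99)
        assert pat.abundance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_carbon_only_mode_is_pure_binomial(self, glucose):
        pat = isotope_pattern(glucose, 0.5, carbon_only=True, tail=0)
        np.testing.assert_allclose(pat.abundance, carbon_pattern(6, 0.5), atol=1e-12)

    def test_zero_atom_formula_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(MolecularFormula())

    @settings(derandomize=True, max_examples=25)
    @given(
        c=hst.integers(1, 30), h=hst.integers(0, 40), o=hst.integers(0, 10),
        frac=hst.floats(0.0, 1.0),
    )
    def test_every_pattern_is_normalized(self, c, h, o, frac):
        pat = isotope_pattern(MolecularFormula(c=c, h=h, o=o), frac)
        assert pat.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pat.abundance >= 0)


class TestConvolve:
    def test_identity_element(self, glucose):
        p = isotope_pattern(glucose)
        out = convolve(p, IsotopePattern(np.array([1.0])))
        np.testing.assert_allclose(out.abundance, p.abundance, atol=1e-15)

    def test_binomial_composition(self):
        p = IsotopePattern(np.array([0.5, 0.5]))
        np.testing.assert_allclose(convolve(p, p).abundance, [0.25, 0.5, 0.25], atol=1e-15)

    @settings(derandomize=True, max_examples=25)
    @given(hst.integers(0, 2**31 - 1))
    def test_commutativity(self, seed):
        rng = np.random.default_rng(seed)
        a = IsotopePattern(rng.dirichlet(np.ones(rng.integers(1, 8))))
        b = IsotopePattern(rng.dirichlet(np.ones(rng.integers(1, 8))))
        np.testing.assert_allclose(
            convolve(a, b).abundance, convolve(b, a).abundance, atol=1e-12
        )


class TestMixtureSpectrum:
    def test_unlabeled_mixture_is_natural_pattern(self, glucose):
        spec = mixture_spectrum(glucose, ria=0.99, lr=0.0, scale=2.0, noise_cv=0.0)
        nat = isotope_pattern(glucose).abundance
        np.testing.assert_allclose(spec.intensity, 2.0 * nat, atol=1e-12)

    def test_fully_labeled_mixture_is_enriched_pattern(self, glucose):
        spec = mixture_spectrum(glucose, ria=0.99, lr=1.0, scale=1.0, noise_cv=0.0)
        enr = isotope_pattern(glucose, 0.99).abundance
        np.testing.assert_allclose(spec.intensity[: enr.size], enr, atol=1e-12)

    def test_half_mixture_is_channelwise_average(self, glucose):
        spec = mixture_spectrum(glucose, ria=0.65, lr=0.5, scale=1.0, noise_cv=0.0)
        nat = isotope_pattern(glucose).abundance
        enr = isotope_pattern(glucose, 0.65).abundance
        n = max(nat.size, enr.size)
        expected = 0.5 * np.pad(nat, (0, n - nat.size)) + 0.5 * np.pad(enr, (0, n - enr.size))
        np.testing.assert_allclose(spec.intensity, expected, atol=1e-12)

    def test_noise_is_reproducible_under_seed(self, glucose):
        a = mixture_spectrum(glucose, 0.99, 0.5, noise_cv=0.1, seed=42).intensity
        b = mixture_spectrum(glucose, 0.99, 0.5, noise_cv=0.1, seed=42).intensity
        c = mixture_spectrum(glucose, 0.99, 0.5, noise_cv=0.1, seed=43).intensity
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_indistinguishable_label_rejected(self, glucose):
        with pytest.raises(ValueError, match="natural"):
            mixture_spectrum(glucose, ria=0.005, lr=0.5)

    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValueError):
            ObservedSpectrum(np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            ObservedSpectrum(np.array([1.0, -0.1]))
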