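"""Forward modeling of isotopologue distributions at arbitrary 13C enrichment.

The model underlying stable-isotope probing of biopolymers: every carbon
atom of a molecule is 13C with probability ``c13_fraction`` (binomial
over the carbon count), while the other elements contribute their
natural isotope distributions. The isotopologue distribution of the
whole molecule is the discrete convolution of the per-element patterns,
indexed by nominal mass shift (0, 1, 2, ... extra neutrons).

An observed peak cluster is modeled as a two-population mixture: a
native (natural-abundance) population and a labeled population at a
common relative isotope abundance (RIA), mixed by the labeling ratio
(LR), with optional multiplicative lognormal noise per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formula import MolecularFormula

#: Mass difference between 13C and 12C in Da; purely cosmetic for the
#: nominal-shift axis used here (it never affects abundances).
C13_MASS_SHIFT_DA = 1.003355

#: Natural 13C atom fraction.
NATURAL_C13 = 0.0107

#: Natural isotope abundances per element as {mass shift: probability}.
#: Standard IUPAC values; 36S (1e-4 natural) is folded into the 32S
#: remainder so each element sums to exactly 1. Configurable: pass a
#: modified mapping via the ``abundances`` argument of the pattern
#: functions.
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "C": {0: 1.0 - NATURAL_C13, 1: NATURAL_C13},
    "H": {0: 1.0 - 0.000115, 1: 0.000115},
    "N": {0: 1.0 - 0.00364, 1: 0.00364},
    "O": {0: 1.0 - 0.00038 - 0.00205, 1: 0.00038, 2: 0.00205},
    "S": {0: 1.0 - 0.0075 - 0.0429, 1: 0.0075, 2: 0.0429},
}


@dataclass(frozen=True)
class IsotopePattern:
    """Normalized isotopologue abundance vector over nominal mass shift.

    ``abundance[m]`` is the probability of carrying ``m`` extra
    neutrons relative to the monoisotopic species.
    """

    abundance: np.ndarray
    mass_shift_da: float = C13_MASS_SHIFT_DA

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundance, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("abundance must be a non-empty 1-D vector")
        if np.any(arr < 0):
            raise ValueError("abundances must be >= 0")
        total = float(arr.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 +- 1e-9, got {total!r}")
        object.__setattr__(self, "abundance", arr)

    def __len__(self) -> int:
        return self.abundance.size

    @property
    def mean_shift(self) -> float:
        """Intensity-weighted mean nominal mass shift."""
        return float(np.arange(len(self)) @ self.abundance)


@dataclass(frozen=True)
class ObservedSpectrum:
    """Synthetic stand-in for an extracted isotope peak cluster.

    Intensities are arbitrary units over the nominal mass-shift axis.
    """

    intensity: np.ndarray
    compound_id: str = ""
    time_days: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("intensity must be a non-empty 1-D vector")
        if np.any(arr < 0):
            raise ValueError("intensities must be >= 0")
        if not np.any(arr > 0):
            raise ValueError("spectrum must have at least one positive intensity")
        object.__setattr__(self, "intensity", arr)


def _normalized(vec: np.ndarray) -> np.ndarray:
    total = vec.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero vector")
    return vec / total


def carbon_pattern(n_c: int, c13_fraction: float) -> np.ndarray:
    """Binomial isotopologue pattern of ``n_c`` carbons, full length ``n_c + 1``.

    Untruncated, so the mean shift equals ``n_c * c13_fraction`` to
    floating-point precision (binomial mean).
    """
    if n_c < 0:
        raise ValueError("carbon count must be >= 0")
    if not 0.0 <= c13_fraction <= 1.0:
        raise ValueError(f"c13_fraction must lie in [0, 1], got {c13_fraction}")
    if n_c == 0:
        return np.array([1.0])
    # Row of the binomial pmf built by iterated convolution: exact up to
    # float rounding and free of scipy's pmf edge cases at p in {0, 1}.
    atom = np.array([1.0 - c13_fraction, c13_fraction])
    return _power_pattern(atom, n_c)


def _power_pattern(atom: np.ndarray, count: int) -> np.ndarray:
    """``atom`` convolved with itself ``count`` times (binary exponentiation)."""
    result = np.array([1.0])
    base = atom
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, base)
        k >>= 1
        if k:
            base = np.convolve(base, base)
    return result


def _element_pattern(element: str, count: int, abundances: dict[str, dict[int, float]]) -> np.ndarray:
    table = abundances[element]
    length = max(table) + 1
    atom = np.zeros(length)
    for shift, p in table.items():
        atom[shift] = p
    return _power_pattern(atom, count)


def isotope_pattern(
    formula: MolecularFormula,
    c13_fraction: float | None = None,
    *,
    abundances: dict[str, dict[int, float]] | None = None,
    carbon_only: bool = False,
    tail: float = 1e-6,
) -> IsotopePattern:
    """Isotopologue distribution of a molecular formula.

    Parameters
    ----------
    formula:
        Element counts; must contain at least one atom, and at least one
        carbon for any 13C analysis to be meaningful.
    c13_fraction:
        13C atom fraction of the carbon atoms. ``None`` means natural
        abundance (the all-natural pattern).
    abundances:
        Override of the natural per-element isotope tables.
    carbon_only:
        Simplified pedagogical mode: only carbon contributes, all other
        elements are treated as monoisotopic.
    tail:
        The pattern is truncated at the smallest length whose cumulative
        abundance reaches ``1 - tail`` and renormalized. Pass ``0`` to
        keep the full convolution.
    """
    if formula.n_atoms == 0:
        raise ValueError("formula has no atoms")
    abundances = abundances if abundances is not None else NATURAL_ABUNDANCE
    frac = NATURAL_C13 if c13_fraction is None else float(c13_fraction)
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"c13_fraction must lie in [0, 1], got {frac}")

    pattern = carbon_pattern(formula.c, frac)
    if not carbon_only:
        for el, cnt in (("H", formula.h), ("N", formula.n), ("O", formula.o), ("S", formula.s)):
            if cnt:
                pattern = np.convolve(pattern, _element_pattern(el, cnt, abundances))
    if tail > 0:
        cum = np.cumsum(pattern)
        cut = int(np.searchsorted(cum, cum[-1] * (1.0 - tail))) + 1
        pattern = pattern[:cut]
    return IsotopePattern(_normalized(pattern))


def convolve(p1: IsotopePattern, p2: IsotopePattern) -> IsotopePattern:
    """Isotopologue pattern of two independent sub-patterns combined."""
    return IsotopePattern(_normalized(np.convolve(p1.abundance, p2.abundance)))


def _pad(vec: np.ndarray, length: int) -> np.ndarray:
    if vec.size >= length:
        return vec
    return np.pad(vec, (0, length - vec.size))


def mixture_spectrum(
    formula: MolecularFormula,
    ria: float,
    lr: float,
    scale: float = 1e6,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    compound_id: str = "",
    time_days: float = 0.0,
    abundances: dict[str, dict[int, float]] | None = None,
) -> ObservedSpectrum:
    """Synthetic observed spectrum of a native/labeled two-population mixture.

    Expected intensity per channel is
    ``scale * [(1 - lr) * natural + lr * enriched(ria)]``, with
    mean-preserving multiplicative lognormal noise of coefficient of
    variation ``noise_cv`` applied per channel.

    Raises if ``lr > 0`` but ``ria`` does not exceed the natural 13C
    abundance (the labeled population would be indistinguishable).
    """
    if not 0.0 <= lr <= 1.0:
        raise ValueError(f"labeling ratio must lie in [0, 1], got {lr}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    abund = abundances if abundances is not None else NATURAL_ABUNDANCE
    natural_c13 = abund["C"][1]
    if lr > 0 and ria <= natural_c13:
        raise ValueError(
            f"ria ({ria}) must exceed the natural 13C abundance ({natural_c13}) when lr > 0"
        )

    native = isotope_pattern(formula, abundances=abund).abundance
    if lr > 0:
        labeled = isotope_pattern(formula, ria, abundances=abund).abundance
    else:
        labeled = np.zeros(1)
    length = max(native.size, labeled.size)
    expected = scale * ((1.0 - lr) * _pad(native, length) + lr * _pad(labeled, length))

    if noise_cv > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        expected = expected * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=expected.size)
    return ObservedSpectrum(expected, compound_id=compound_id, time_days=time_days)
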