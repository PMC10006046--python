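"""Elemental composition of sugars and tryptic peptides.

Only the five CHNOS elements of common biopolymers are tracked. The
isotopologue machinery in :mod:`sipturnover.isotopes` works on nominal
integer mass shifts, so element counts (not exact masses) are all that
is needed downstream.

Peptide compositions are obtained from :mod:`pyteomics`, which carries
the standard residue formulas; sugar formulas are written in Hill
notation (e.g. ``"C6H12O6"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from pyteomics import mass as _ptmass

ELEMENTS = ("C", "H", "N", "O", "S")

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_HILL_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral molecule or ion over C, H, N, O, S.

    Counts are non-negative integers. Any compound subjected to a
    carbon-13 labeling analysis must contain at least one carbon atom;
    this is enforced where a pattern is actually computed, not here,
    so that intermediate arithmetic (e.g. neutral losses) stays legal.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for el in ("c", "h", "n", "o", "s"):
            v = getattr(self, el)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"element count {el!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"element count {el!r} must be >= 0, got {v}")

    # -- construction ----------------------------------------------------

    @classmethod
    def from_hill(cls, text: str) -> "MolecularFormula":
        """Parse Hill notation such as ``"C6H12O6"`` (CHNOS only)."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        counts = {el: 0 for el in ELEMENTS}
        pos = 0
        for m in _HILL_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in formula {text!r}")
            counts[el] += int(num) if num else 1
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"], s=counts["S"])

    # -- views ------------------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    @property
    def n_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.s

    def to_hill(self) -> str:
        parts = []
        for el, cnt in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o), ("S", self.s)):
            if cnt == 0:
                continue
            parts.append(el if cnt == 1 else f"{el}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_hill()

    # -- arithmetic --------------------------------------------------------

    def minus(self, **loss: int) -> "MolecularFormula":
        """Return the formula after a neutral/charged loss, e.g. ``minus(h=1)``."""
        updates = {}
        for el, cnt in loss.items():
            have = getattr(self, el)
            if cnt > have:
                raise ValueError(f"cannot remove {cnt} {el.upper()} from {self.to_hill()}")
            updates[el] = have - cnt
        return replace(self, **updates)


def formula_of_peptide(sequence: str) -> MolecularFormula:
    """Elemental composition of a (tryptic) peptide, termini included.

    The composition is the sum of residue formulas plus one water, as
    computed by pyteomics' standard amino-acid table.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string over the 20 standard residues.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    bad = sorted(set(sequence) - STANDARD_RESIDUES)
    if bad:
        raise ValueError(
            f"unknown residue letter(s) {', '.join(repr(b) for b in bad)} in peptide {sequence!r}"
        )
    comp = _ptmass.Composition(sequence=sequence)
    return MolecularFormula(
        c=comp.get("C", 0), h=comp.get("H", 0), n=comp.get("N", 0),
        o=comp.get("O", 0), s=comp.get("S", 0),
    )


def deprotonated(formula: MolecularFormula) -> MolecularFormula:
    """Composition of the [M-H]- ion (loses one hydrogen, same carbon count)."""
    return formula.minus(h=1)


def decarboxylated(formula: MolecularFormula) -> MolecularFormula:
    """Composition of the [M-COO]- ion of a sugar.

    Interpreted as the deprotonated ion after neutral loss of CO2, i.e.
    one fewer carbon and two fewer oxygens than [M-H]-. The notation in
    negative-mode sugar analysis is ambiguous for neutral
    monosaccharides; this reading keeps the carbon count one lower than
    the parent ion, which is what matters for the isotopologue axis.
    """
    return formula.minus(c=1, o=2, h=1)
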