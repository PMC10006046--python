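"""Forward-model isotopologue distributions of a sugar and a peptide.

Shows how the isotope envelope of a molecule shifts when its carbon
atoms are enriched in 13C: at natural abundance (1.07%) the monoisotopic
peak dominates, at 99 atom % the envelope sits near the fully labeled
mass. These envelopes are what the labeling-ratio estimators decompose.
"""

from sipturnover import MolecularFormula, formula_of_peptide, isotope_pattern

glucose = MolecularFormula.from_hill("C6H12O6")
peptide = formula_of_peptide("ASDFLKGHTWER")

for name, formula in [("glucose", glucose), ("tryptic peptide", peptide)]:
    print(f"\n{name} ({formula.to_hill()}, {formula.c} carbons)")
    for frac, label in [(None, "natural"), (0.5, "50 atom %"), (0.99, "99 atom %")]:
        pat = isotope_pattern(formula, frac)
        top = max(range(len(pat)), key=lambda m: pat.abundance[m])
        print(
            f"  {label:>9}: mean shift {pat.mean_shift:6.2f} Da/1.003355, "
            f"most abundant isotopologue M+{top} ({pat.abundance[top]:.3f})"
        )

# The mean shift of the carbon envelope is n_C * atom fraction: a 13C
# atom fraction can be read off a measured envelope as mean / n_C.
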