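import numpy as np
import pytest

from sipturnover import MolecularFormula, SBRConfig, formula_of_peptide


@pytest.fixture
def glucose() -> MolecularFormula:
    return MolecularFormula.from_hill("C6H12O6")


@pytest.fixture
def tryptic_peptide() -> MolecularFormula:
    # 12-residue tryptic peptide, 65 carbons: representative of protein SIP.
    return formula_of_peptide("ASDFLKGHTWER")


@pytest.fixture
def sbr() -> SBRConfig:
    return SBRConfig()


@pytest.fixture
def cycle_times(sbr) -> np.ndarray:
    return sbr.times
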