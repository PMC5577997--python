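import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from intrachain import synth


@pytest.fixture(scope="session")
def helix12():
    return synth.make_helix(12)


@pytest.fixture(scope="session")
def ion_pair_close():
    return synth.make_ion_pair(3.5, "GLU", "LYS")


@pytest.fixture(scope="session")
def trio_default():
    return synth.make_ortholog_trio(
        synth.SyntheticSpec(seed=11), shared=2, private_per_species=(1, 1, 1))


MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.840  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.506   6.215  -4.118  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(MINIMAL_ALA_PDB)
    return p
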