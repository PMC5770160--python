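import numpy as np
import pytest

from sipris import (FixtureSpec, ResidueKey, make_structure, plant_pattern)


@pytest.fixture(scope="session")
def helix30():
    """Small ideal-helix model, CA-only, 30 residues."""
    return make_structure(FixtureSpec(n_residues=30, seed=5))


@pytest.fixture(scope="session")
def cloud12():
    """12-residue random point cloud for brute-force distance oracles."""
    return make_structure(FixtureSpec(n_residues=12, geometry="random-cloud",
                                      seed=9))


@pytest.fixture(scope="session")
def planted300():
    """Helix of 300 residues with a 25-residue pattern, 20 planted in the
    50-residue ball around the center."""
    spec = FixtureSpec(n_residues=300, seed=11, planted_count=20, D=25,
                       ball_size=50)
    model = make_structure(spec)
    return model, plant_pattern(model, spec), spec


def toy_pdb_text():
    """Hand-constructed 3-residue + 1-ligand PDB fixture with an altLoc pair."""
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C",
        "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C",
        "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O",
        "ATOM      5  N   SER A   2       3.332   1.536   0.000  1.00 10.00           N",
        "ATOM      6  CA  SER A   2       3.988   2.839   0.000  1.00 10.00           C",
        "ATOM      7  OG ASER A   2       5.388   2.700   0.000  0.60 10.00           O",
        "ATOM      8  OG BSER A   2       5.200   3.200   0.000  0.40 10.00           O",
        "ATOM      9  N   GLY A   3       3.510   5.300   0.000  1.00 10.00           N",
        "ATOM     10  CA  GLY A   3       4.100   6.600   0.000  1.00 10.00           C",
        "TER      11      GLY A   3",
        "HETATM   12  P1  LIG A 101       8.000   8.000   0.000  1.00 10.00           P",
        "HETATM   13  O1  LIG A 101       9.000   8.000   0.000  1.00 10.00           O",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture()
def toy_pdb():
    return toy_pdb_text()


CMA_WORKED_EXAMPLE = """[0_(1)=name(1){go = 10000,gx = 2000,pn = 1000.0,lf = 0,rf = 0}:
(20)********************
$41 = 34(28):
>4ABC_A
{(QEYP)ID-QTGKCEPYigqiTKCStfLPNST(NVTN)}*
_0].
"""


@pytest.fixture()
def cma_worked_example():
    return CMA_WORKED_EXAMPLE
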