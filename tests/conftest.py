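"""Shared fixtures: toy structures, simulated cohorts, text PDB fixtures."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from tp53conform import (
    SimulationConfig,
    ToyStructureSpec,
    make_toy_structure,
    simulate_cohort,
)

# Minimal hand-written PDB: two ALA residues (3 atoms) in chain A plus one
# atom with two alternate conformers (A occ 0.60 at x=1, B occ 0.40 at x=9).
MINI_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  N   ALA A 100      11.000   6.000  -6.000  1.00  0.00           N
ATOM      2  CA  ALA A 100      12.400   6.200  -6.300  1.00  0.00           C
ATOM      3  CB  ALA A 101      15.000   8.000  -4.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  N   ALA A 100      11.000   6.000  -6.000  1.00  0.00           N
ATOM      2  CA AALA A 100       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A 100       9.000   0.000   0.000  0.40  0.00           C
END
"""


@pytest.fixture(scope="session")
def mini_pdb(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("pdb") / "mini.pdb"
    path.write_text(MINI_PDB)
    return str(path)


@pytest.fixture(scope="session")
def altloc_pdb(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("pdb") / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return str(path)


@pytest.fixture(scope="session")
def cluster_structure():
    return make_toy_structure(ToyStructureSpec("compact_cluster", n_atoms=30, seed=1))


@pytest.fixture(scope="session")
def contact_structure():
    return make_toy_structure(ToyStructureSpec("two_chain_contact"))


@pytest.fixture(scope="session")
def default_cohort():
    """One default 24+24 simulated cohort (variants, features, outcome 0/1)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_features(default_cohort) -> pd.DataFrame:
    return default_cohort[1]


@pytest.fixture(autouse=False)
def quiet_separation():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
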