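import os
import tempfile

# keep hypothesis' on-disk caches out of the repository
os.environ.setdefault("HYPOTHESIS_STORAGE_DIRECTORY", tempfile.mkdtemp(prefix="hyp-"))

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from kinsig.chem_io import parse_smiles

#: diverse small molecules, all with <= 12 heavy atoms (signature oracle set)
FIXTURE_SMILES = (
    "CCO",
    "c1ccccc1",
    "NS(=O)(=O)c1ccccc1",
    "NC(=O)N",
    "c1cc[nH]c1",
    "CC(=O)O",
    "FC(F)(F)F",
    "CCN(CC)CC",
    "c1ccncc1",
    "OCC(O)CO",
    "CSC",
    "C1CCNCC1",
    "Clc1ccccc1",
    "CC(C)=O",
    "N#Cc1ccco1",
    "CNC(=O)c1ccco1",
    "C[N+](C)(C)C",
)

#: tiny molecules (<= 8 heavy atoms) for the exhaustive miner oracle
MINER_SMILES = (
    "CCO",
    "CCC",
    "CCN",
    "c1ccccc1",
    "C1CCC1",
    "CC(C)O",
    "CCOC",
    "NCCO",
)


@pytest.fixture(scope="session")
def fixture_molecules():
    return [parse_smiles(s) for s in FIXTURE_SMILES]


@pytest.fixture(scope="session")
def miner_molecules():
    return [parse_smiles(s) for s in MINER_SMILES]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
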