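import numpy as np
import pandas as pd
import pytest

from voxelprot.digest import PeptideRecord
from voxelprot.synthetic import (
    SimulationConfig,
    generate_peptide_table,
    generate_proteome,
)


def make_record(seq, prev="K", nxt="A", voxel=1, mods=(), protein="P1", count=1):
    return PeptideRecord(
        sequence=seq,
        prev_aa=prev,
        next_aa=nxt,
        protein=protein,
        voxel=voxel,
        spectral_count=count,
        modifications=tuple(mods),
    )


@pytest.fixture(scope="session")
def proteome():
    """Small composition-controlled synthetic proteome shared across tests."""
    return generate_proteome(n_proteins=120, seed=42)


@pytest.fixture(scope="session")
def default_peptides(proteome):
    """One peptide table drawn at the default digest statistics."""
    cfg = SimulationConfig(seed=11)
    records, truth = generate_peptide_table(cfg, proteome)
    return cfg, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_matrix(rng):
    """Complete random log2 intensity matrix, 50 proteins x 6 voxels."""
    data = rng.normal(20, 1, size=(50, 6))
    return pd.DataFrame(
        data, index=[f"P{i:03d}" for i in range(50)], columns=list(range(1, 7))
    )
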