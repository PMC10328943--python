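import numpy as np
import pandas as pd
import pytest

from methylink import simulate
from methylink.types import CountMatrix, GeneModel, GenomeSequence, MethCountTable


@pytest.fixture(scope="session")
def small_study():
    """A complete small synthetic study shared across tests (read-only)."""
    cfg = simulate.SimulationConfig(
        seed=42, n_contigs=2, contig_len=150_000, n_genes=120, ccgg_rate=0.0008,
        de_fraction=0.15, dmc_fraction=0.08,
    )
    return simulate.simulate_study(cfg)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gA", "c1", "+", 5000, 8000, ((5000, 6000), (7000, 8000))),
        GeneModel("gB", "c1", "-", 12000, 15000, ((12000, 15000),)),
    ]


@pytest.fixture
def two_group_counts():
    rng = np.random.default_rng(0)
    groups = {f"A{i}": "A" for i in range(4)} | {f"B{i}": "B" for i in range(4)}
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 8)).astype(np.int64),
        index=[f"g{i}" for i in range(50)],
        columns=list(groups),
    )
    return CountMatrix(counts, groups)


def make_meth_table(n_meth, coverage, positions=None, contig="c1"):
    """Build a MethCountTable from (sites x samples) arrays; sample names A*/B*
    split half/half."""
    n_sites, n_samp = n_meth.shape
    half = n_samp // 2
    samples = [f"A{i}" for i in range(half)] + [f"B{i}" for i in range(n_samp - half)]
    groups = {s: s[0] for s in samples}
    if positions is None:
        positions = np.arange(n_sites) * 10
    rec = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.repeat(positions, n_samp),
            "sample_id": np.tile(samples, n_sites),
            "n_meth": np.asarray(n_meth).ravel(),
            "n_unmeth": (np.asarray(coverage) - np.asarray(n_meth)).ravel(),
        }
    )
    return MethCountTable(rec, groups)
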