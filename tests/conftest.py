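import numpy as np
import pytest

from popmito.seqio import Alignment


def make_alignment(seqs, pops=None, ids=None):
    """Build an Alignment from plain sequence strings."""
    n = len(seqs)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    pops = pops or ["P1"] * n
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(n, len(seqs[0])).copy()
    return Alignment(sample_ids=list(ids), populations=dict(zip(ids, pops)),
                     seqs=arr, locus_label="test")


@pytest.fixture
def mk():
    return make_alignment


@pytest.fixture(scope="session")
def metapop():
    """Two-lineage nine-population synthetic dataset (seed 1), with truth."""
    from popmito.synthetic_data import SimulationConfig, simulate_two_lineage_metapopulation

    cfg = SimulationConfig(seed=1)
    aln, truth = simulate_two_lineage_metapopulation(cfg)
    return cfg, aln, truth


def random_alignment(rng, n=None, L=None, pops=None):
    """Uniform-random alignment for property tests."""
    n = n or int(rng.integers(2, 12))
    L = L or int(rng.integers(1, 40))
    seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
    return make_alignment(seqs, pops=pops or ["P1"] * n)
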