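import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from topochron.core import CircularGenome, GeneRecord, GeneTable
from topochron.simulate import SimConfig, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_genome(rng: np.random.Generator, length: int,
                  ori: int = 0, ter: int | None = None) -> CircularGenome:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return CircularGenome(seq, ori, ter if ter is not None else length // 2)


def random_gene_table(rng: np.random.Generator, length: int, n_genes: int,
                      gene_len: int = 300) -> GeneTable:
    """Non-overlapping random genes on [0, length), random strands."""
    max_genes = length // (gene_len + 1)
    n_genes = min(n_genes, max_genes)
    starts = np.sort(rng.choice(length - gene_len, size=n_genes, replace=False))
    records, prev_end = [], 0
    for i, s in enumerate(starts):
        s = max(int(s), prev_end)
        if s + gene_len > length:
            break
        records.append(GeneRecord(f"g{i}", s, s + gene_len,
                                  "+" if rng.random() < 0.5 else "-"))
        prev_end = s + gene_len
    return GeneTable(records, length)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study conditions: 1 Mb genome, 400 genes, seed 1."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, smaller growth cycle for unit-level checks."""
    return simulate(SimConfig(length=120_000, n_genes=40, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
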