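import numpy as np
import pandas as pd
import pytest

from flylife.annotation import Transcript, TranscriptCatalog
from flylife.benchmarks import _confounded_design
from flylife.simulate import make_catalog, make_truth, simulate_positional_counts


@pytest.fixture(scope="session")
def small_catalog() -> TranscriptCatalog:
    return make_catalog(300, seed=11, max_transcripts=1)


@pytest.fixture(scope="session")
def confounded_pc(small_catalog):
    """Positional counts with RIN fully confounded with genotype, no DE."""
    info = _confounded_design(11, (5.0, 5.5, 6.0), (7.0, 7.5, 8.0), libsize=3e5)
    truth = make_truth(small_catalog, info, seed=11, n_de=0)
    pc = simulate_positional_counts(small_catalog, truth, seed=11)
    return pc, info, truth


@pytest.fixture
def single_exon_plus() -> Transcript:
    return Transcript("tx1.t1", "gene1", "chr1", "+", ((0, 2000),))


@pytest.fixture
def two_exon_minus() -> Transcript:
    # 3' end at coordinate 100 (minus strand)
    return Transcript("tx2.t1", "gene2", "chr1", "-", ((100, 600), (800, 1200)))


def uniform_positional(lengths: dict[str, int], total: int, samples=("s1",), bin_width=25):
    """Deterministic, perfectly uniform coverage (equal count per full bin)."""
    from flylife.containers import PositionalCounts

    pc = PositionalCounts(bin_width=bin_width, samples=list(samples))
    for i, (tid, L) in enumerate(lengths.items()):
        n_bins = int(np.ceil(L / bin_width))
        arr = np.full((n_bins, len(samples)), total, dtype=np.int64)
        pc.counts[tid] = arr
        pc.gene_of[tid] = f"g{i+1}"
        pc.length_of[tid] = L
    return pc
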