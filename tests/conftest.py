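import numpy as np
import pytest

from lowhic.genome import ChromosomeSet, Enzyme, FragmentMap, make_bins
from lowhic.matrix import BALANCED, RAW, ContactMatrix


@pytest.fixture
def two_chrom_bins():
    """Two chromosomes of 100 kb + 60 kb at 50 kb bins (4 bins total)."""
    return make_bins(ChromosomeSet({"chr1": 100_000, "chr2": 60_000}), 50_000)


@pytest.fixture
def simple_fragments():
    """One 12 kb chromosome with fragments [0,3k), [3k,9k), [9k,12k)."""
    chroms = ChromosomeSet({"chr1": 12_000})
    return FragmentMap(
        chromosomes=chroms,
        enzyme=Enzyme("MboI", "GATC", 0),
        starts={"chr1": np.array([0, 3_000, 9_000])},
    )


def make_matrix(values, chrom_lengths=None, bin_size=None, state=RAW, mappable=None):
    """Build a ContactMatrix around a dense array; a single-chromosome bin
    table is derived from the array shape unless given explicitly."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if chrom_lengths is None:
        bin_size = bin_size or 50_000
        chrom_lengths = {"chr1": n * bin_size}
    bins = make_bins(ChromosomeSet(chrom_lengths), bin_size or 50_000)
    assert bins.n_bins == n
    return ContactMatrix(bins, values, mappable=mappable, state=state)


def decay_matrix(n, alpha=1.0, scale=1.0, bin_size=50_000, state=BALANCED):
    """Exact power-law decay matrix (observed == expected everywhere)."""
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return make_matrix(scale * (d + 1.0) ** (-alpha), bin_size=bin_size, state=state)
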