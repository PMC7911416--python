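import numpy as np
import pytest

from bincnv import (
    BinCounts,
    build_bin_grid,
    build_toy_genome,
    default_toy_genome,
)


@pytest.fixture(scope="session")
def toy_genome():
    """The standard ~188 Mb / 9,400-bin desk-scale genome."""
    return default_toy_genome(seed=0)


@pytest.fixture(scope="session")
def small_genome():
    """Five 4-Mb autosomes plus sex chromosomes: 1,400 bins, flat GC."""
    mb = 1_000_000
    names = ["chr1", "chr2", "chr3", "chr4", "chr5", "chrX", "chrY"]
    return build_toy_genome(
        7, [4 * mb] * 5 + [4 * mb, 4 * mb], gc_profile_spec=0.40, seed=1, names=names
    )


def make_counts(counts_per_chrom: dict[str, np.ndarray], bin_size: int = 20_000) -> BinCounts:
    """Helper: wrap per-chromosome count arrays in a BinCounts on a fresh grid."""
    sizes = {c: len(v) * bin_size for c, v in counts_per_chrom.items()}
    grid = build_bin_grid(sizes, bin_size=bin_size)
    counts = np.concatenate([np.asarray(counts_per_chrom[c]) for c in grid.chroms])
    return BinCounts(grid=grid, counts=counts, n_assigned=int(counts.sum()))


@pytest.fixture
def counts_factory():
    return make_counts
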