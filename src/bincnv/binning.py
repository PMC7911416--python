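"""Fixed-width bin grid construction and per-bin read counting.

Reads are allocated to 20-kb bins along each chromosome by their 5'-most
mapped coordinate; only uniquely mapped, non-duplicate reads are counted.
Internal coordinates are 0-based half-open; alignment input positions are
1-based, and serialized bin tables use 1-based inclusive columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

DEFAULT_BIN_SIZE = 20_000

MASK_EXCLUDED = "excluded-region"
MASK_GC = "gc-extreme"
MASK_ZERO_REF = "zero-reference"


@dataclass
class BinGrid:
    """Ordered tiling of the genome into fixed-width bins.

    All arrays are parallel, one entry per bin, concatenated in chromosome
    order.  Trailing partial bins are dropped at construction: variable-width
    bins would bias both CV and copy number.
    """

    chroms: list[str]                 # chromosome order
    chrom: np.ndarray                 # per-bin chromosome name
    start: np.ndarray                 # 0-based inclusive
    end: np.ndarray                   # 0-based exclusive
    gc: np.ndarray                    # per-bin GC fraction (NaN if unknown)
    mask: np.ndarray                  # bool, True = excluded from statistics
    mask_reason: np.ndarray           # "" or reason string
    bin_size: int = DEFAULT_BIN_SIZE
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.gc)
                == len(self.mask) == len(self.mask_reason)):
            raise ValueError("grid arrays have unequal lengths")
        if np.any(self.mask & (self.mask_reason == "")):
            raise ValueError("masked bin without a reason")
        self._offsets = {}
        self._nbins = {}
        for c in self.chroms:
            idx = np.flatnonzero(self.chrom == c)
            self._offsets[c] = int(idx[0]) if idx.size else 0
            self._nbins[c] = int(idx.size)

    def __len__(self) -> int:
        return len(self.chrom)

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._nbins[chrom])

    def n_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            self.bin_size == other.bin_size
            and list(self.chroms) == list(other.chroms)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
        )


@dataclass
class BinCounts:
    """Per-bin unique-read counts on a :class:`BinGrid`.

    ``n_assigned`` is the number of reads counted into bins; reads lost to
    dropped partial bins, unknown chromosomes, or the unique/duplicate filter
    are tallied separately so that the totals are conserved.
    """

    grid: BinGrid
    counts: np.ndarray
    n_assigned: int
    n_off_grid: int = 0
    n_partial: int = 0
    n_filtered: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.grid):
            raise ValueError("counts length does not match grid")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if int(self.counts.sum()) != self.n_assigned:
            raise ValueError("sum of counts does not equal n_assigned")


def _overlapping_bins(start: int, end: int, bin_size: int, n_bins: int) -> tuple[int, int]:
    """Index range [lo, hi) of full bins overlapping 0-based half-open [start, end)."""
    lo = max(0, start // bin_size)
    hi = min(n_bins, -(-end // bin_size))
    return lo, hi


def build_bin_grid(
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc: dict[str, np.ndarray] | None = None,
    excluded: dict[str, list[tuple[int, int]]] | None = None,
    centromeres: dict[str, tuple[int, int]] | None = None,
) -> BinGrid:
    """Tile each chromosome into ``floor(L / bin_size)`` full bins.

    Any overlap with an excluded interval masks the whole bin.  A chromosome
    shorter than one bin yields zero bins with a warning.
    """
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1000 bp")
    excluded = excluded or {}
    chroms = list(chrom_sizes)
    chrom_col, starts, ends, gcs = [], [], [], []
    mask_parts, reason_parts = [], []
    for c in chroms:
        L = chrom_sizes[c]
        nb = L // bin_size
        if nb == 0:
            warnings.warn(f"chromosome {c} shorter than one bin; zero bins emitted")
            continue
        chrom_col.extend([c] * nb)
        s = np.arange(nb, dtype=np.int64) * bin_size
        starts.append(s)
        ends.append(s + bin_size)
        if gc is not None and c in gc:
            g = np.asarray(gc[c], dtype=float)
            if len(g) != nb:
                raise ValueError(f"GC track of {c} has {len(g)} bins, grid has {nb}")
            gcs.append(g)
        else:
            gcs.append(np.full(nb, np.nan))
        m = np.zeros(nb, dtype=bool)
        for es, ee in excluded.get(c, []):
            lo, hi = _overlapping_bins(es, ee, bin_size, nb)
            m[lo:hi] = True
        mask_parts.append(m)
        reason_parts.append(np.where(m, MASK_EXCLUDED, ""))
    return BinGrid(
        chroms=[c for c in chroms if chrom_sizes[c] >= bin_size],
        chrom=np.array(chrom_col, dtype=object),
        start=np.concatenate(starts) if starts else np.array([], dtype=np.int64),
        end=np.concatenate(ends) if ends else np.array([], dtype=np.int64),
        gc=np.concatenate(gcs) if gcs else np.array([]),
        mask=np.concatenate(mask_parts) if mask_parts else np.array([], dtype=bool),
        mask_reason=np.concatenate(reason_parts).astype(object)
        if reason_parts
        else np.array([], dtype=object),
        bin_size=bin_size,
        centromeres=dict(centromeres or {}),
    )


def grid_from_genome(genome: GenomeModel) -> BinGrid:
    """Build the grid for a :class:`GenomeModel`, masking its excluded
    regions and centromeres."""
    return build_bin_grid(
        genome.lengths,
        bin_size=genome.bin_size,
        gc=genome.gc,
        excluded={c: genome.excluded_with_centromeres(c) for c in genome.chroms},
        centromeres=genome.centromeres,
    )


def count_reads(alignments: pd.DataFrame, grid: BinGrid) -> BinCounts:
    """Count uniquely mapped, non-duplicate reads into grid bins.

    ``alignments`` uses the simulator's TSV dialect: columns ``chrom``,
    ``pos`` (1-based 5' coordinate), ``strand``, ``status`` in
    {unique, multi, unmapped} and ``duplicate`` (0/1).  Reads failing the
    unique/non-duplicate filter, landing on chromosomes absent from the grid,
    or falling in a dropped trailing partial bin are tallied but not counted.
    """
    if len(alignments) == 0:
        raise ValueError("empty alignment table")
    n_rows = len(alignments)
    keep = (alignments["status"].to_numpy() == "unique") & (
        alignments["duplicate"].to_numpy().astype(int) == 0
    )
    n_filtered = int(n_rows - keep.sum())
    sub = alignments.loc[keep]
    counts = np.zeros(len(grid), dtype=np.int64)
    n_off_grid = 0
    n_partial = 0
    n_assigned = 0
    known = set(grid.chroms)
    for chrom, part in sub.groupby("chrom", sort=False):
        if chrom not in known:
            n_off_grid += len(part)
            warnings.warn(f"{len(part)} reads on unknown chromosome {chrom}")
            continue
        nb = grid.n_bins(chrom)
        idx = (part["pos"].to_numpy().astype(np.int64) - 1) // grid.bin_size
        in_partial = idx >= nb
        n_partial += int(in_partial.sum())
        idx = idx[~in_partial]
        off = grid.chrom_slice(chrom).start
        np.add.at(counts, off + idx, 1)
        n_assigned += int(len(idx))
    return BinCounts(
        grid=grid,
        counts=counts,
        n_assigned=n_assigned,
        n_off_grid=n_off_grid,
        n_partial=n_partial,
        n_filtered=n_filtered,
    )


def mask_gc_extremes(grid: BinGrid, low: float = 0.28, high: float = 0.60) -> BinGrid:
    """Return a grid with bins of GC outside [low, high] additionally masked."""
    new_mask = grid.mask.copy()
    new_reason = grid.mask_reason.copy()
    extreme = (~np.isnan(grid.gc)) & ((grid.gc < low) | (grid.gc > high)) & ~grid.mask
    new_mask[extreme] = True
    new_reason[extreme] = MASK_GC
    return BinGrid(
        chroms=grid.chroms,
        chrom=grid.chrom,
        start=grid.start,
        end=grid.end,
        gc=grid.gc,
        mask=new_mask,
        mask_reason=new_reason,
        bin_size=grid.bin_size,
        centromeres=grid.centromeres,
    )


# -- serialization ---------------------------------------------------------

def counts_to_tsv(bc: BinCounts, path: str, header_lines: list[str] | None = None) -> None:
    """Write counts as TSV: chrom, start1, end1, gc, mask, count (1-based inclusive)."""
    g = bc.grid
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("chrom\tstart1\tend1\tgc\tmask\tcount\n")
        for i in range(len(g)):
            fh.write(
                f"{g.chrom[i]}\t{g.start[i] + 1}\t{g.end[i]}\t"
                f"{'' if np.isnan(g.gc[i]) else format(g.gc[i], '.5f')}\t"
                f"{g.mask_reason[i]}\t{bc.counts[i]}\n"
            )


def counts_from_tsv(path: str, centromeres: dict[str, tuple[int, int]] | None = None) -> BinCounts:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"mask": str}, keep_default_na=False)
    starts = df["start1"].to_numpy(dtype=np.int64) - 1
    widths = df["end1"].to_numpy(dtype=np.int64) - starts
    if len(set(widths)) != 1:
        raise ValueError("bin table has variable bin widths")
    gc = pd.to_numeric(df["gc"], errors="coerce").to_numpy(dtype=float)
    reasons = df["mask"].to_numpy(dtype=object)
    chroms = list(dict.fromkeys(df["chrom"]))
    grid = BinGrid(
        chroms=chroms,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=starts,
        end=df["end1"].to_numpy(dtype=np.int64),
        gc=gc,
        mask=reasons != "",
        mask_reason=reasons,
        bin_size=int(widths[0]),
        centromeres=dict(centromeres or {}),
    )
    counts = df["count"].to_numpy(dtype=np.int64)
    return BinCounts(grid=grid, counts=counts, n_assigned=int(counts.sum()))
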