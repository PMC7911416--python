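"""Synthetic samples for low-pass CNV sequencing.

Two simulation tiers share one truth schema:

* **count tier** — Poisson read counts per 20-kb bin, proportional to local
  copy number with an optional quadratic GC-bias multiplier.  Fast; used by
  most tests and by the benchmark replicates.
* **read tier** — raw 45-bp reads (36-bp genomic insert + 9-bp adapter) with
  per-base qualities and an alignment-truth table, exercising trimming and
  sequencing QC.

Local copy number inside a mosaic CNV of fraction ``f`` carrying ``c``
copies is ``2(1-f) + c*f`` on a disomic background (the base copy replaces
2 on aneuploid chromosomes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinCounts, BinGrid, grid_from_genome
from .genome import SEX_COMPOSITIONS, GenomeModel

DEFAULT_ADAPTER = "AGATCGGAA"


@dataclass
class KaryotypeSpec:
    """Whole-chromosome composition of a simulated sample.

    ``sex`` is one of the documented compositions (XX, XY, XO, XXY, XXX,
    XYY); ``autosome_copies`` overrides the disomic default per chromosome,
    e.g. ``{"chr21": 3}`` for trisomy 21.
    """

    sex: str = "XX"
    autosome_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEX_COMPOSITIONS:
            raise ValueError(f"sex composition {self.sex!r} not in {SEX_COMPOSITIONS}")
        for c, n in self.autosome_copies.items():
            if n < 0:
                raise ValueError(f"negative copy number for {c}")

    def copy_of(self, chrom: str) -> int:
        if chrom == "chrX":
            return self.sex.count("X")
        if chrom == "chrY":
            return self.sex.count("Y")
        return self.autosome_copies.get(chrom, 2)

    @classmethod
    def parse(cls, text: str) -> "KaryotypeSpec":
        """Parse strings like ``46,XX``, ``47,XY,+21``, ``45,X`` or ``45,XO``."""
        tokens = [t.strip() for t in text.split(",") if t.strip()]
        if tokens and re.fullmatch(r"\d+", tokens[0]):
            tokens = tokens[1:]
        if not tokens:
            raise ValueError(f"cannot parse karyotype {text!r}")
        sex = tokens[0].upper()
        if sex == "X":
            sex = "XO"
        copies: dict[str, int] = {}
        for tok in tokens[1:]:
            m = re.fullmatch(r"([+-])(chr)?(\w+)", tok)
            if not m:
                raise ValueError(f"cannot parse karyotype token {tok!r}")
            chrom = f"chr{m.group(3)}"
            copies[chrom] = copies.get(chrom, 2) + (1 if m.group(1) == "+" else -1)
        return cls(sex=sex, autosome_copies=copies)


@dataclass
class CnvSpec:
    """A segmental copy-number variant to spike into a sample.

    Coordinates are 1-based inclusive, matching clinical microarray report
    style.  ``mosaic_fraction`` is the fraction of cells carrying the
    variant; 1.0 is a constitutional CNV.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str   # "del" | "dup"
    copies: int | None = None
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV start > end")
        if self.kind not in ("del", "dup"):
            raise ValueError(f"CNV kind {self.kind!r} must be del or dup")
        if self.copies is None:
            self.copies = 1 if self.kind == "del" else 3
        if self.kind == "del" and not self.copies < 2:
            raise ValueError("deletion copies must be < 2")
        if self.kind == "dup" and not self.copies > 2:
            raise ValueError("duplication copies must be > 2")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic fraction outside [0, 1]")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str) -> "CnvSpec":
        """Parse ``chrom:start-end:del|dup[:mosaicF]``."""
        parts = text.split(":")
        if len(parts) not in (3, 4):
            raise ValueError(f"cannot parse CNV spec {text!r}")
        m = re.fullmatch(r"(\d+)-(\d+)", parts[1].replace(",", ""))
        if m is None:
            raise ValueError(f"cannot parse CNV coordinates in {text!r}")
        frac = float(parts[3]) if len(parts) == 4 else 1.0
        return cls(
            chrom=parts[0],
            start=int(m.group(1)),
            end=int(m.group(2)),
            kind=parts[2],
            mosaic_fraction=frac,
        )


@dataclass
class SimConfig:
    """Read-model parameters, defaulting to the low-pass regime this
    pipeline targets: ~5 million raw 45-bp single-end reads per sample,
    each a 36-bp genomic insert followed by a 9-bp adapter, with a unique
    mapping ratio around 60-65%."""

    total_raw_reads: int = 5_000_000
    raw_read_length: int = 45
    genomic_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    p_unique: float = 0.62
    p_duplicate: float = 0.02
    gc_bias: tuple[float, float] = (0.0, 0.0)  # linear, quadratic in (gc - 0.4)
    mcc_fraction: float = 0.0
    q_high_prob: float = 0.94   # fraction of bases drawn from the high-quality state
    q_high: int = 37
    q_low: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_unique, self.p_duplicate, self.mcc_fraction, self.q_high_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.raw_read_length < self.genomic_length:
            raise ValueError("raw read shorter than genomic insert")
        if len(self.adapter) != self.raw_read_length - self.genomic_length:
            raise ValueError("adapter length must equal raw length - genomic length")

    def bias(self, gc: np.ndarray) -> np.ndarray:
        a1, a2 = self.gc_bias
        d = np.asarray(gc, dtype=float) - 0.40
        return np.maximum(0.0, 1.0 + a1 * d + a2 * d * d)


@dataclass
class SimTruth:
    """Ground truth bundled with a simulated sample."""

    karyotype: KaryotypeSpec
    cnvs: list[CnvSpec]
    expected_cn: np.ndarray  # per grid bin
    depth_per_bin: float
    mcc_fraction: float
    seed: int

    def cnv_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.chrom,
                "start1": c.start,
                "end1": c.end,
                "kind": c.kind,
                "copies": c.copies,
                "mosaic_fraction": c.mosaic_fraction,
            }
            for c in self.cnvs
        ]
        return pd.DataFrame(rows, columns=["chrom", "start1", "end1", "kind", "copies", "mosaic_fraction"])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# coordinates: 1-based inclusive\n")
            fh.write(f"# sex: {self.karyotype.sex}\n")
            fh.write(f"# autosome_copies: {self.karyotype.autosome_copies}\n")
            fh.write(f"# mcc_fraction: {self.mcc_fraction}\n")
            fh.write(f"# seed: {self.seed}\n")
            self.cnv_table().to_csv(fh, sep="\t", index=False)


def _check_no_overlap(cnvs: list[CnvSpec]) -> None:
    by_chrom: dict[str, list[CnvSpec]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda c: c.start)
        for a, b in zip(items, items[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping CNV specs on {chrom}")


def expected_cn_per_bin(
    grid: BinGrid, karyotype: KaryotypeSpec, cnvs: list[CnvSpec]
) -> np.ndarray:
    """Expected copy number per bin, with fractional overlap at CNV edges."""
    _check_no_overlap(list(cnvs))
    cn = np.empty(len(grid), dtype=float)
    for chrom in grid.chroms:
        cn[grid.chrom_slice(chrom)] = float(karyotype.copy_of(chrom))
    for cnv in cnvs:
        if cnv.chrom not in grid.chroms:
            raise ValueError(f"CNV chromosome {cnv.chrom} not on grid")
        sl = grid.chrom_slice(cnv.chrom)
        starts = grid.start[sl]
        ends = grid.end[sl]
        s0, e0 = cnv.start - 1, cnv.end  # to 0-based half-open
        ov = np.clip(np.minimum(ends, e0) - np.maximum(starts, s0), 0, None) / grid.bin_size
        base = cn[sl]
        f = cnv.mosaic_fraction
        local = base * (1.0 - f) + cnv.copies * f
        cn[sl] = base * (1.0 - ov) + local * ov
    return cn


def simulate_bin_counts(
    genome: GenomeModel,
    karyotype: KaryotypeSpec | None = None,
    cnvs: list[CnvSpec] | None = None,
    depth_per_bin: float = 30.0,
    config: SimConfig | None = None,
) -> tuple[BinCounts, SimTruth]:
    """Count-tier sample: ``count_i ~ Poisson(depth * cn_i/2 * bias(gc_i))``.

    Masked bins still receive counts — discarding them is the pipeline's
    job, not the genome's.  Bit-reproducible for a fixed ``config.seed``.
    """
    if depth_per_bin <= 0:
        raise ValueError("depth_per_bin must be > 0")
    karyotype = karyotype or KaryotypeSpec()
    cnvs = list(cnvs or [])
    config = config or SimConfig()
    grid = grid_from_genome(genome)
    cn = expected_cn_per_bin(grid, karyotype, cnvs)
    lam = depth_per_bin * (cn / 2.0) * config.bias(grid.gc)
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(lam)
    bc = BinCounts(grid=grid, counts=counts, n_assigned=int(counts.sum()))
    truth = SimTruth(
        karyotype=karyotype,
        cnvs=cnvs,
        expected_cn=cn,
        depth_per_bin=depth_per_bin,
        mcc_fraction=config.mcc_fraction,
        seed=config.seed,
    )
    return bc, truth


_QUAL_OFFSET = 33


def simulate_reads(
    genome: GenomeModel,
    karyotype: KaryotypeSpec | None = None,
    cnvs: list[CnvSpec] | None = None,
    config: SimConfig | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, SimTruth]:
    """Read-tier sample.

    Returns ``(reads, truth_table, truth)`` where ``reads`` is a list of
    (read_id, sequence, quality) FASTQ records and ``truth_table`` is the
    alignment-truth TSV dialect (read_id, chrom, pos, strand, status,
    duplicate).  Multi-mapped and unmapped reads carry no position;
    duplicates re-emit a previously drawn unique read's mapping.
    """
    karyotype = karyotype or KaryotypeSpec()
    cnvs = list(cnvs or [])
    config = config or SimConfig()
    grid = grid_from_genome(genome)
    cn = expected_cn_per_bin(grid, karyotype, cnvs)
    weights = (cn / 2.0) * config.bias(grid.gc)
    if weights.sum() <= 0:
        raise ValueError("degenerate genome: zero total sampling weight")
    p_bin = weights / weights.sum()
    rng = np.random.default_rng(config.seed)

    n = config.total_raw_reads
    status = np.where(
        rng.random(n) < config.p_unique,
        "unique",
        np.where(rng.random(n) < 0.5, "multi", "unmapped"),
    ).astype(object)
    dup = (rng.random(n) < config.p_duplicate) & (status == "unique")

    bins = rng.choice(len(grid), size=n, p=p_bin)
    offsets = rng.integers(0, grid.bin_size - config.genomic_length, size=n)
    pos = grid.start[bins] + offsets + 1  # 1-based 5' coordinate
    chrom = grid.chrom[bins].copy()
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)

    # duplicates re-emit an earlier unique read's mapping
    unique_idx = np.flatnonzero((status == "unique") & ~dup)
    dup_idx = np.flatnonzero(dup)
    if unique_idx.size == 0:
        dup[:] = False
        dup_idx = np.array([], dtype=int)
    if dup_idx.size:
        src = rng.choice(unique_idx, size=dup_idx.size)
        chrom[dup_idx] = chrom[src]
        pos[dup_idx] = pos[src]
        strand[dup_idx] = strand[src]

    unmapped = status != "unique"
    chrom[unmapped] = "."
    pos = np.where(unmapped, 0, pos)

    # sequences: GC probability from the source bin; adapter suffix appended
    gc_bin = np.nan_to_num(grid.gc[bins], nan=0.40)
    L = config.genomic_length
    is_gc = rng.random((n, L)) < gc_bin[:, None]
    which = rng.random((n, L)) < 0.5
    bases = np.where(is_gc, np.where(which, "G", "C"), np.where(which, "A", "T"))
    hi = rng.random((n, config.raw_read_length)) < config.q_high_prob
    quals = np.where(
        hi, chr(config.q_high + _QUAL_OFFSET), chr(config.q_low + _QUAL_OFFSET)
    )

    reads = []
    ids = [f"r{i:07d}" for i in range(n)]
    for i in range(n):
        seq = "".join(bases[i]) + config.adapter
        reads.append((ids[i], seq, "".join(quals[i])))
    table = pd.DataFrame(
        {
            "read_id": ids,
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "strand": strand,
            "status": status,
            "duplicate": dup.astype(int),
        }
    )
    truth = SimTruth(
        karyotype=karyotype,
        cnvs=cnvs,
        expected_cn=cn,
        depth_per_bin=config.p_unique * n / max(len(grid), 1),
        mcc_fraction=config.mcc_fraction,
        seed=config.seed,
    )
    return reads, table, truth


def spike_mcc(
    fetal: BinCounts, maternal: BinCounts, fraction: float, seed: int = 0
) -> BinCounts:
    """Mix maternal counts into a fetal sample at the given fraction.

    Each bin draws ``Binomial(fetal_i, 1-f) + Binomial(maternal_i, f)`` so
    the expectation is the (1-f)/f mixture of the two samples.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    if not fetal.grid.same_grid(maternal.grid):
        raise ValueError("fetal and maternal samples are on different grids")
    rng = np.random.default_rng(seed)
    mixed = rng.binomial(fetal.counts, 1.0 - fraction) + rng.binomial(
        maternal.counts, fraction
    )
    return BinCounts(grid=fetal.grid, counts=mixed, n_assigned=int(mixed.sum()))


def write_fastq(reads, path: str) -> None:
    """Write (read_id, seq, qual) records as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str):
    """Yield (read_id, seq, qual) from a 4-line FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n").lstrip("@"), seq, qual


def write_alignment_tsv(table: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# positions: 1-based 5' coordinates; status in {unique, multi, unmapped}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_alignment_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
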