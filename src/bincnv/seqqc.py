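"""Adapter trimming and sequencing quality-control indicators.

The seven QC indicators reported per sample: unique-mapping ratio, read
redundancy, coefficient of variation of bin counts (genome-wide and per
chromosome), median read depth per bin, GC ratio of uniquely mapped reads,
and Q30 (fraction of bases with Phred quality >= 30, i.e. error probability
<= 1/1000).

Redundancy here is the fraction of *uniquely mapped* reads that are
duplicates — a read whose (chrom, 5' position, strand) was already seen, or
that carries the duplicate flag — beyond the first occurrence.  The
denominator choice (unique rather than all mapped reads) is a documented
convention and is echoed in the QC report header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinCounts
from .simulate import DEFAULT_ADAPTER

_QUAL_OFFSET = 33


@dataclass
class TrimSpec:
    raw_length: int = 45
    genomic_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    seed_length: int = 7  # exact-match prefix of the adapter used for search

    def __post_init__(self) -> None:
        if self.genomic_length + len(self.adapter) != self.raw_length:
            raise ValueError("genomic length + adapter length must equal raw length")
        if not 1 <= self.seed_length <= len(self.adapter):
            raise ValueError("seed length must be within the adapter")


@dataclass
class QcReport:
    unique_mapping_ratio: float
    redundancy_ratio: float
    cv_genome: float
    cv_per_chrom: dict[str, float] = field(default_factory=dict)
    median_read_depth: float = 0.0
    gc_ratio: float = float("nan")
    q30: float = float("nan")
    n_raw_reads: int = 0
    n_unique_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("unique_mapping_ratio", "redundancy_ratio"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_unique_reads > self.n_raw_reads:
            raise ValueError("more unique reads than raw reads")

    def to_tsv(self, path: str, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("# redundancy denominator: uniquely mapped reads\n")
            fh.write("metric\tvalue\n")
            fh.write(f"unique_mapping_ratio\t{self.unique_mapping_ratio:.4f}\n")
            fh.write(f"redundancy_ratio\t{self.redundancy_ratio:.4f}\n")
            fh.write(f"cv_genome\t{self.cv_genome:.4f}\n")
            for chrom, cv in self.cv_per_chrom.items():
                fh.write(f"cv_{chrom}\t{cv:.4f}\n")
            fh.write(f"median_read_depth\t{self.median_read_depth:.1f}\n")
            fh.write(f"gc_ratio\t{self.gc_ratio:.4f}\n")
            fh.write(f"q30\t{self.q30:.4f}\n")
            fh.write(f"n_raw_reads\t{self.n_raw_reads}\n")
            fh.write(f"n_unique_reads\t{self.n_unique_reads}\n")


def trim_adapter(seq: str, spec: TrimSpec | None = None) -> tuple[str, bool]:
    """Remove the adapter suffix from a raw read.

    Returns ``(trimmed, found)``: the prefix before the first exact
    occurrence of the adapter's seed, or the read unchanged with
    ``found=False`` when no adapter is present.  A read that *is* the
    adapter trims to the empty string.
    """
    if not seq:
        raise ValueError("empty read")
    spec = spec or TrimSpec()
    idx = seq.find(spec.adapter[: spec.seed_length])
    if idx < 0:
        return seq, False
    return seq[:idx], True


def q30_fraction(quality_strings) -> tuple[float, int]:
    """Fraction of all bases with Phred+33 quality >= 30.

    Records containing characters outside the printable Phred+33 range are
    rejected and counted; returns ``(fraction, n_rejected_records)``.
    """
    n_bases = 0
    n_q30 = 0
    n_rejected = 0
    for qual in quality_strings:
        codes = np.frombuffer(qual.encode("ascii", errors="replace"), dtype=np.uint8)
        if codes.size == 0 or codes.min() < 33 or codes.max() > 126:
            n_rejected += 1
            continue
        n_bases += codes.size
        n_q30 += int((codes >= 30 + _QUAL_OFFSET).sum())
    if n_bases == 0:
        raise ValueError("no bases")
    return n_q30 / n_bases, n_rejected


def mapping_stats(alignments: pd.DataFrame) -> tuple[float, float]:
    """Unique-mapping ratio and redundancy ratio from an alignment table.

    unique_mapping_ratio = unique reads / all reads.
    redundancy_ratio = duplicate unique reads / unique reads, where a
    duplicate is flagged or shares (chrom, pos, strand) with an earlier
    unique read.  Both are invariant to input row order.
    """
    if len(alignments) == 0:
        raise ValueError("empty alignment table")
    unique = alignments[alignments["status"] == "unique"]
    n_unique = len(unique)
    if n_unique == 0:
        return 0.0, 0.0
    flagged = unique["duplicate"].to_numpy().astype(bool)
    positional = unique.duplicated(subset=["chrom", "pos", "strand"]).to_numpy()
    # a flagged read sitting at a first-seen position still counts once:
    # total occurrences beyond the first at each site, plus flagged firsts
    n_dup = int((flagged | positional).sum())
    return n_unique / len(alignments), n_dup / n_unique


def coverage_cv(bin_counts: BinCounts, scope: str = "genome") -> float:
    """Coefficient of variation (population SD / mean) of unmasked bin counts.

    ``scope`` is "genome" or a chromosome name.
    """
    grid = bin_counts.grid
    if scope == "genome":
        sel = ~grid.mask
    else:
        sel = np.zeros(len(grid), dtype=bool)
        sel[grid.chrom_slice(scope)] = True
        sel &= ~grid.mask
    vals = bin_counts.counts[sel].astype(float)
    if vals.size < 2:
        raise ValueError("fewer than 2 unmasked bins in scope")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("no coverage")
    return float(vals.std(ddof=0) / mean)


def gc_ratio(sequences) -> float:
    """(G+C)/(A+C+G+T) over the given sequences; ambiguous bases excluded."""
    gc = 0
    acgt = 0
    for seq in sequences:
        s = seq.upper()
        for base in s:
            if base in "GC":
                gc += 1
                acgt += 1
            elif base in "AT":
                acgt += 1
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return gc / acgt


def median_depth(bin_counts: BinCounts) -> float:
    """Median unique-read count over unmasked bins."""
    vals = bin_counts.counts[~bin_counts.grid.mask]
    if vals.size == 0:
        raise ValueError("no unmasked bins")
    return float(np.median(vals))


def qc_report(
    alignments: pd.DataFrame,
    bin_counts: BinCounts,
    trimmed_unique_seqs=None,
    quality_strings=None,
) -> QcReport:
    """Assemble the full QC indicator panel for one sample."""
    umr, red = mapping_stats(alignments)
    n_raw = len(alignments)
    n_unique = int((alignments["status"] == "unique").sum())
    cv_chrom = {}
    for chrom in bin_counts.grid.chroms:
        try:
            cv_chrom[chrom] = coverage_cv(bin_counts, chrom)
        except ValueError:
            cv_chrom[chrom] = float("nan")
    gc = gc_ratio(trimmed_unique_seqs) if trimmed_unique_seqs is not None else float("nan")
    q30 = q30_fraction(quality_strings)[0] if quality_strings is not None else float("nan")
    return QcReport(
        unique_mapping_ratio=umr,
        redundancy_ratio=red,
        cv_genome=coverage_cv(bin_counts, "genome"),
        cv_per_chrom=cv_chrom,
        median_read_depth=median_depth(bin_counts),
        gc_ratio=gc,
        q30=q30,
        n_raw_reads=n_raw,
        n_unique_reads=n_unique,
    )
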