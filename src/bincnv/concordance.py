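"""Concordance of called CNVs against microarray-defined truth intervals,
and the maternal-cell-contamination (MCC) acceptance gate.

The primary concordance statistic is benchmarked against the truth: the
percentage of the truth interval covered by same-side calls.  Because the
exact benchmarking formula used in clinical comparisons is rarely stated,
the reciprocal overlap of the best single matching call is reported
alongside.  Samples are gated on MCC: contamination below 5% is acceptable
for clinical interpretation, at or above it the sample fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import CnvCall

MCC_THRESHOLD_PERCENT = 5.0


@dataclass
class TruthInterval:
    """A microarray-defined CNV interval (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    state: str  # "del" | "dup"
    copies: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("truth interval start > end")
        if self.state not in ("del", "dup"):
            raise ValueError("truth state must be del or dup")
        if self.copies is None:
            self.copies = 1 if self.state == "del" else 3

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConcordanceRecord:
    label: str
    truth: TruthInterval
    matched_call: CnvCall | None
    concordance_percent: float
    reciprocal_overlap_percent: float
    state_agreement: bool
    cn_agreement: bool
    warning: str = ""


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals; returns disjoint sorted intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_concordance(
    calls: list[CnvCall], truths: list[TruthInterval]
) -> list[ConcordanceRecord]:
    """Score each truth interval against overlapping same-side calls.

    concordance = 100 * |union of same-side call overlaps with truth| / |truth|.
    Reciprocal overlap (100 * |intersection| / |union|) is reported for the
    single best-overlapping call.  A truth interval with no overlapping call
    scores 0.
    """
    records: list[ConcordanceRecord] = []
    known_chroms = {c.chrom for c in calls}
    for truth in truths:
        same = [
            c
            for c in calls
            if c.chrom == truth.chrom
            and c.side == truth.state
            and c.start <= truth.end
            and c.end >= truth.start
        ]
        warning = ""
        if truth.chrom not in known_chroms and not same:
            warning = f"no calls on {truth.chrom}"
        overlaps = [
            (max(c.start, truth.start), min(c.end, truth.end)) for c in same
        ]
        covered = sum(e - s + 1 for s, e in _merge_intervals(overlaps))
        conc = 100.0 * covered / truth.length
        best: CnvCall | None = None
        recip = 0.0
        if same:
            best = max(
                same,
                key=lambda c: min(c.end, truth.end) - max(c.start, truth.start) + 1,
            )
            inter = min(best.end, truth.end) - max(best.start, truth.start) + 1
            union = (
                max(best.end, truth.end) - min(best.start, truth.start) + 1
            )
            recip = 100.0 * inter / union
        cn_ok = best is not None and round(best.mean_cn) == truth.copies
        records.append(
            ConcordanceRecord(
                label=truth.label,
                truth=truth,
                matched_call=best,
                concordance_percent=conc,
                reciprocal_overlap_percent=recip,
                state_agreement=best is not None,
                cn_agreement=bool(cn_ok),
                warning=warning,
            )
        )
    return records


def mcc_gate(estimated_percent: float, threshold: float = MCC_THRESHOLD_PERCENT) -> bool:
    """Pass iff estimated contamination is strictly below the threshold."""
    return estimated_percent < threshold


@dataclass
class MccResult:
    percent: float
    passed: bool
    loci_used: list[str] = field(default_factory=list)
    uninformative: bool = False


def estimate_mcc(
    maternal_genotypes: dict[str, set],
    sample_peaks: dict[str, dict],
    fetal_genotypes: dict[str, set] | None = None,
    threshold: float = MCC_THRESHOLD_PERCENT,
    pass_when_uninformative: bool = True,
) -> MccResult:
    """Estimate maternal contamination from STR peak-height tables.

    A locus is informative when the mother carries an allele absent from
    the fetal genotype.  Per informative locus the contamination fraction
    is ``2 * h_maternal_specific / sum(heights)`` (the factor 2 converts a
    single-allele dosage into a genome-equivalent fraction); the MCC
    percentage is 100 x the median over informative loci.

    When no fetal genotypes are supplied, fetal alleles are inferred as the
    two tallest peaks per locus.  With no informative locus the estimate is
    flagged uninformative and the gate decision follows
    ``pass_when_uninformative``.
    """
    fractions: list[float] = []
    loci_used: list[str] = []
    for locus, peaks in sample_peaks.items():
        if locus not in maternal_genotypes:
            continue
        total = float(sum(peaks.values()))
        if total <= 0:
            continue
        if fetal_genotypes is not None and locus in fetal_genotypes:
            fetal = set(fetal_genotypes[locus])
        else:
            fetal = {
                a for a, _ in sorted(peaks.items(), key=lambda kv: -kv[1])[:2]
            }
        specific = set(maternal_genotypes[locus]) - fetal
        if not specific:
            continue
        h_spec = sum(peaks.get(a, 0.0) for a in specific)
        fractions.append(min(1.0, 2.0 * h_spec / total))
        loci_used.append(locus)
    if not fractions:
        return MccResult(
            percent=float("nan"),
            passed=pass_when_uninformative,
            loci_used=[],
            uninformative=True,
        )
    pct = 100.0 * float(np.median(fractions))
    return MccResult(percent=pct, passed=mcc_gate(pct, threshold), loci_used=loci_used)


# -- I/O -------------------------------------------------------------------

def read_truth_tsv(path: str) -> list[TruthInterval]:
    """Read truth intervals from TSV with columns chrom, start1, end1, kind
    (del/dup) and optional copies and label; 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            TruthInterval(
                chrom=row["chrom"],
                start=int(row["start1"]),
                end=int(row["end1"]),
                state=row["kind"],
                copies=int(row["copies"]) if "copies" in df.columns and not pd.isna(row["copies"]) else None,
                label=str(row["label"]) if "label" in df.columns else "",
            )
        )
    return out


def records_to_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "label": r.label,
                "chrom": r.truth.chrom,
                "truth_start1": r.truth.start,
                "truth_end1": r.truth.end,
                "truth_state": r.truth.state,
                "concordance_percent": round(r.concordance_percent, 2),
                "reciprocal_overlap_percent": round(r.reciprocal_overlap_percent, 2),
                "state_agreement": int(r.state_agreement),
                "cn_agreement": int(r.cn_agreement),
                "warning": r.warning,
            }
        )
    return pd.DataFrame(rows)
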