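"""End-to-end sample analysis: counts -> profile -> calls -> result."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .binning import BinCounts, mask_gc_extremes
from .calling import (
    SEX_PATTERNS,
    SampleResult,
    call_whole_chromosome,
    name_cnv,
    segment,
)
from .concordance import mcc_gate
from .config import PipelineConfig
from .genome import GenomeModel
from .profile import chromosome_cn, counts_to_profile, smooth
from .seqqc import coverage_cv, median_depth


def call_sample(
    bin_counts: BinCounts,
    config: PipelineConfig | None = None,
    genome: GenomeModel | None = None,
    mcc_percent: float | None = None,
) -> SampleResult:
    """Run GC correction, normalization, smoothing, segmentation and
    whole-chromosome calling on one sample's bin counts.

    ``genome`` is only needed for cytoband naming; the grid carried by
    ``bin_counts`` supplies everything else.  ``mcc_percent``, when known,
    is checked against the contamination gate and a failing sample is
    reported with FAIL status (calls are still produced for review).
    """
    config = config or PipelineConfig()
    bc = BinCounts(
        grid=mask_gc_extremes(bin_counts.grid, config.gc_mask_low, config.gc_mask_high),
        counts=bin_counts.counts,
        n_assigned=bin_counts.n_assigned,
        n_off_grid=bin_counts.n_off_grid,
        n_partial=bin_counts.n_partial,
        n_filtered=bin_counts.n_filtered,
    )
    profile = counts_to_profile(bc, gc_correction=config.gc_correction)
    smoothed = smooth(profile, config.smooth_window)
    thresholds = config.thresholds()
    whole, karyotype, sex = call_whole_chromosome(smoothed, thresholds)
    # sex chromosomes are segmented on a ploidy-normalized scale: CN is
    # rescaled so the sex-inferred expected copy number maps to 2, and a
    # sex chromosome expected absent (e.g. chrY in a female) is skipped
    seg_profile = smoothed
    if sex is not None and any(c in smoothed.grid.chroms for c in ("chrX", "chrY")):
        expected = dict(zip(("chrX", "chrY"), SEX_PATTERNS[sex]))
        cn = smoothed.cn.copy()
        raw = smoothed.raw_cn.copy()
        for chrom, exp_cn in expected.items():
            if chrom not in smoothed.grid.chroms:
                continue
            sl = smoothed.grid.chrom_slice(chrom)
            if exp_cn == 0:
                cn[sl] = np.nan
                raw[sl] = np.nan
            else:
                cn[sl] = cn[sl] * 2.0 / exp_cn
                raw[sl] = raw[sl] * 2.0 / exp_cn
        seg_profile = replace(smoothed, cn=cn, raw_cn=raw)
    calls = segment(
        seg_profile, thresholds, min_bins=config.min_segment_bins,
        gap_bins=config.gap_bins, min_z=config.seg_min_z,
    )
    # a whole-chromosome event is reported once: segments on an aneuploid
    # chromosome whose side matches the whole-chromosome call are the same
    # event seen piecewise (the masked centromere splits the run)
    whole_side = {c.chrom: ("dup" if c.direction == "gain" else "del") for c in whole}
    segmental = [c for c in calls if whole_side.get(c.chrom) != c.side]
    for c in segmental:
        c.name = name_cnv(c, genome)
    chrom_cn = {c: chromosome_cn(profile, c) for c in profile.grid.chroms}
    arm_cn = {}
    for c in profile.grid.chroms:
        if c in profile.grid.centromeres:
            for arm in ("p", "q"):
                try:
                    arm_cn[f"{c}{arm}"] = chromosome_cn(profile, c, arm)
                except ValueError:
                    pass
    status = "PASS"
    mcc_ok = None
    if mcc_percent is not None:
        mcc_ok = mcc_gate(mcc_percent, config.mcc_threshold)
        if not mcc_ok:
            status = "FAIL"
    if median_depth(bc) < config.min_median_depth:
        status = "FAIL"
    qc = {
        "cv_genome": coverage_cv(bc, "genome"),
        "median_read_depth": median_depth(bc),
    }
    return SampleResult(
        karyotype=karyotype,
        sex=sex,
        whole_chrom_calls=whole,
        cnv_calls=segmental,
        chromosome_cn=chrom_cn,
        arm_cn=arm_cn,
        qc=qc,
        mcc_percent=mcc_percent,
        mcc_pass=mcc_ok,
        status=status,
    )
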