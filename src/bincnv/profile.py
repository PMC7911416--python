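"""Normalization of bin counts to a copy-number profile.

The pipeline scales corrected bin counts so that the autosomal median maps
to copy number 2 (the within-sample disomic baseline), after an optional
stratified-median GC correction.  Expected behaviour: CN ~ 1 for a
heterozygous deletion or monosomy, CN ~ 3 for a duplication or trisomy, and
intermediate values for mosaics.

No reference panel is used: the baseline is the sample's own autosomal
median, with a one-pass re-estimation that drops bins whose provisional CN
falls outside the disomy band — this keeps the baseline honest when a large
CNV or whole-chromosome aneuploidy is present.  A panel-of-normals hook can
be layered on top but is not required at low-pass depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import BinCounts, BinGrid
from .genome import SEX_CHROMS


@dataclass
class CopyNumberProfile:
    """Per-bin copy number on a grid; masked bins carry NaN.

    ``raw_cn`` preserves the unsmoothed values so that smoothing affects
    segment *detection* while segment quantification stays on raw CN.
    """

    grid: BinGrid
    cn: np.ndarray
    raw_cn: np.ndarray
    baseline: float
    gc_factors: dict[float, float] = field(default_factory=dict)
    window: int = 1

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        with np.errstate(invalid="ignore"):
            if np.any(self.cn[~np.isnan(self.cn)] < 0):
                raise ValueError("negative copy number")

    def to_tsv(self, path: str, header_lines=None) -> None:
        g = self.grid
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("# coordinates: 1-based inclusive\n")
            fh.write(f"# baseline: {self.baseline:.6g}\n")
            fh.write(f"# smoothing_window: {self.window}\n")
            fh.write("chrom\tstart1\tend1\tcn\tmasked\n")
            for i in range(len(g)):
                cn = "" if np.isnan(self.cn[i]) else format(self.cn[i], ".4f")
                fh.write(f"{g.chrom[i]}\t{g.start[i] + 1}\t{g.end[i]}\t{cn}\t{int(g.mask[i])}\n")


def gc_correct(
    bin_counts: BinCounts,
    stratum_width: float = 0.01,
    min_bins_per_stratum: int = 10,
    enabled: bool = True,
) -> tuple[np.ndarray, dict[float, float]]:
    """Stratified-median GC correction.

    Bins are grouped into GC strata of the given width; each count is
    divided by (stratum median / global median) over unmasked bins.  Strata
    with too few bins borrow the nearest populated stratum's factor.
    Returns ``(corrected_counts, {stratum_midpoint: factor})``.
    """
    counts = bin_counts.counts.astype(float)
    if not enabled:
        return counts.copy(), {}
    grid = bin_counts.grid
    ok = ~grid.mask & ~np.isnan(grid.gc)
    if ok.sum() < 50:
        raise ValueError("need >= 50 unmasked bins with GC for correction")
    global_median = float(np.median(counts[ok]))
    if global_median == 0:
        raise ValueError("no coverage")
    stratum = np.floor(np.nan_to_num(grid.gc, nan=-1.0) / stratum_width).astype(int)
    populated: dict[int, float] = {}
    sparse: list[int] = []
    for s in np.unique(stratum[ok]):
        vals = counts[ok & (stratum == s)]
        if vals.size >= min_bins_per_stratum:
            populated[s] = float(np.median(vals)) / global_median
        else:
            sparse.append(int(s))
    factors: dict[int, float] = dict(populated)
    if not populated:
        # everything in one (or only sparse) strata: identity correction
        factors = {int(s): 1.0 for s in np.unique(stratum[ok])}
    else:
        keys = np.array(sorted(populated))
        for s in sparse:
            nearest = int(keys[np.argmin(np.abs(keys - s))])
            factors[s] = populated[nearest]
    if len(factors) == 1:
        factors = {k: 1.0 for k in factors}
    corrected = counts.copy()
    for s, f in factors.items():
        if f > 0:
            sel = stratum == s
            corrected[sel] = counts[sel] / f
    mid = stratum_width / 2
    return corrected, {round(s * stratum_width + mid, 6): f for s, f in factors.items()}


def normalize_to_cn(
    grid: BinGrid,
    corrected: np.ndarray,
    gc_factors: dict[float, float] | None = None,
    reestimate: bool = True,
    disomy_band: tuple[float, float] = (1.8, 2.2),
) -> CopyNumberProfile:
    """Scale corrected counts to copy number: ``CN_i = 2 c_i / m``.

    ``m`` is the median corrected count over unmasked *autosomal* bins; sex
    chromosomes are excluded so male samples do not depress the baseline.
    With ``reestimate`` (default), ``m`` is recomputed once over bins whose
    provisional CN lies inside the disomy band, which immunizes the
    baseline against large CNVs.
    """
    corrected = np.asarray(corrected, dtype=float)
    autosomal = ~np.isin(grid.chrom.astype(str), SEX_CHROMS)
    ok = autosomal & ~grid.mask
    if ok.sum() < 100:
        raise ValueError("need >= 100 unmasked autosomal bins")
    m = float(np.median(corrected[ok]))
    if m == 0:
        raise ValueError("insufficient coverage")
    if reestimate:
        provisional = 2.0 * corrected / m
        inband = ok & (provisional > disomy_band[0]) & (provisional < disomy_band[1])
        if inband.sum() >= 100:
            m = float(np.median(corrected[inband]))
    cn = 2.0 * corrected / m
    cn[grid.mask] = np.nan
    return CopyNumberProfile(
        grid=grid, cn=cn, raw_cn=cn.copy(), baseline=m, gc_factors=dict(gc_factors or {})
    )


def counts_to_profile(
    bin_counts: BinCounts, gc_correction: bool = True, reestimate: bool = True
) -> CopyNumberProfile:
    """Convenience: GC-correct and normalize in one step."""
    try:
        corrected, factors = gc_correct(bin_counts, enabled=gc_correction)
    except ValueError:
        if gc_correction and np.all(np.isnan(bin_counts.grid.gc)):
            corrected, factors = bin_counts.counts.astype(float), {}
        else:
            raise
    return normalize_to_cn(bin_counts.grid, corrected, factors, reestimate=reestimate)


def smooth(profile: CopyNumberProfile, window: int = 5) -> CopyNumberProfile:
    """Running median over consecutive *unmasked* bins, per chromosome.

    Centered window; truncated at chromosome ends.  ``window=1`` is the
    identity.  The unsmoothed values remain available as ``raw_cn``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return replace(profile, window=1)
    cn = profile.cn.copy()
    for chrom in profile.grid.chroms:
        sl = profile.grid.chrom_slice(chrom)
        vals = profile.cn[sl]
        idx = np.flatnonzero(~np.isnan(vals))
        if idx.size == 0:
            continue
        sm = (
            pd.Series(vals[idx])
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        out = vals.copy()
        out[idx] = sm
        cn[sl] = out
    return CopyNumberProfile(
        grid=profile.grid,
        cn=cn,
        raw_cn=profile.raw_cn,
        baseline=profile.baseline,
        gc_factors=profile.gc_factors,
        window=window,
    )


def chromosome_cn(profile: CopyNumberProfile, chrom: str, arm: str | None = None) -> float:
    """Mean raw CN over unmasked bins of a chromosome or one arm.

    Arms split at the centromere interval carried by the grid: "p" is
    everything before the centromere start, "q" everything after its end.
    """
    sl = profile.grid.chrom_slice(chrom)
    vals = profile.raw_cn[sl]
    starts = profile.grid.start[sl]
    ends = profile.grid.end[sl]
    sel = ~np.isnan(vals)
    if arm is not None:
        if chrom not in profile.grid.centromeres:
            raise ValueError(f"no centromere recorded for {chrom}")
        cen_s, cen_e = profile.grid.centromeres[chrom]
        if arm == "p":
            sel &= ends <= cen_s
        elif arm == "q":
            sel &= starts >= cen_e
        else:
            raise ValueError("arm must be 'p' or 'q'")
    if not sel.any():
        raise ValueError(f"no unmasked bins on {chrom}{arm or ''}")
    return float(vals[sel].mean())
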