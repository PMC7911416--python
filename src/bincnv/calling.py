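"""CNV segmentation, classification and ISCN-style naming.

Copy-number states follow the clinical thresholds used for low-pass CNV
sequencing: duplication CN > 2.8, deletion CN < 1.2, disomy 1.8 < CN < 2.2,
mosaic trisomy 2.2 < CN < 2.8 and mosaic monosomy 1.2 < CN < 1.8.  Values
landing exactly on a breakpoint are assigned to the adjacent mosaic band
and flagged "boundary", since the defining inequalities are strict on both
sides.

Segmentation is deliberately simple, matching what a human reader does with
a per-chromosome CN plot: maximal runs of consecutive unmasked bins on the
same side of the disomy band, with short gaps bridged and short runs
discarded.  Segment mean CN is computed from the *unsmoothed* profile so
smoothing influences detection, not quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .profile import CopyNumberProfile, chromosome_cn

STATE_DEL = "deletion"
STATE_DUP = "duplication"
STATE_DISOMY = "disomy"
STATE_MOSAIC_TRI = "mosaic trisomy"
STATE_MOSAIC_MONO = "mosaic monosomy"

#: deletion-side and duplication-side state groups
LOSS_STATES = (STATE_DEL, STATE_MOSAIC_MONO)
GAIN_STATES = (STATE_DUP, STATE_MOSAIC_TRI)

#: sex composition -> (expected chrX CN, expected chrY CN)
SEX_PATTERNS = {
    "XX": (2.0, 0.0),
    "XY": (1.0, 1.0),
    "XO": (1.0, 0.0),
    "XXY": (2.0, 1.0),
    "XXX": (3.0, 0.0),
    "XYY": (1.0, 2.0),
}

#: human reference autosome count used when rendering karyotype strings
HUMAN_AUTOSOME_COUNT = 44


@dataclass
class ClassificationThresholds:
    dup_min: float = 2.8
    del_max: float = 1.2
    disomy_low: float = 1.8
    disomy_high: float = 2.2

    def __post_init__(self) -> None:
        if not self.del_max < self.disomy_low < self.disomy_high < self.dup_min:
            raise ValueError("thresholds must satisfy del_max < disomy band < dup_min")


def classify_cn(
    cn: float, thresholds: ClassificationThresholds | None = None
) -> tuple[str, bool]:
    """Classify a copy-number value; returns ``(state, boundary_flag)``.

    Total on [0, inf).  Exact-breakpoint values go to the adjacent mosaic
    band with the boundary flag set.
    """
    t = thresholds or ClassificationThresholds()
    if cn < 0 or np.isnan(cn):
        raise ValueError(f"invalid copy number {cn}")
    if cn == t.del_max or cn == t.disomy_low:
        return STATE_MOSAIC_MONO, True
    if cn == t.disomy_high or cn == t.dup_min:
        return STATE_MOSAIC_TRI, True
    if cn < t.del_max:
        return STATE_DEL, False
    if cn < t.disomy_low:
        return STATE_MOSAIC_MONO, False
    if cn < t.disomy_high:
        return STATE_DISOMY, False
    if cn < t.dup_min:
        return STATE_MOSAIC_TRI, False
    return STATE_DUP, False


def estimate_mosaic_fraction(mean_cn: float, state: str) -> float | None:
    """Invert CN = 2(1-f) + c*f for the mosaic states; None otherwise."""
    if state == STATE_MOSAIC_TRI:
        return float(np.clip(mean_cn - 2.0, 0.0, 1.0))
    if state == STATE_MOSAIC_MONO:
        return float(np.clip(2.0 - mean_cn, 0.0, 1.0))
    return None


@dataclass
class CnvCall:
    """A classified copy-number segment (report coordinates, 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    state: str
    mean_cn: float
    n_bins: int
    size_mb: float = 0.0
    mosaic_fraction: float | None = None
    boundary: bool = False
    cytoband_span: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.size_mb = round((self.end - self.start + 1) / 1e6, 2)
        if self.mosaic_fraction is None:
            self.mosaic_fraction = estimate_mosaic_fraction(self.mean_cn, self.state)

    @property
    def side(self) -> str:
        """'del' for loss-side states, 'dup' for gain-side states."""
        return "del" if self.state in LOSS_STATES else "dup"


def _edge_trim(votes: np.ndarray, margin: float = 1.0, stop_vote: float = 0.5) -> int:
    """Bins to cut from the front of a run given per-bin evidence votes.

    Scans from the edge up to (not past) the first decisively segment-like
    bin (vote > ``stop_vote``) and cuts at the most negative cumulative
    vote, provided the deficit exceeds ``margin`` (about one disomic bin's
    worth of evidence).  Returns 0 when the edge already looks like signal.
    """
    strong = np.flatnonzero(votes > stop_vote)
    limit = int(strong[0]) if strong.size else len(votes)
    if limit == 0:
        return 0
    prefix = np.cumsum(votes[:limit])
    k = int(np.argmin(prefix))
    return k + 1 if prefix[k] <= -margin else 0


def _bin_noise_sd(raw_cn: np.ndarray) -> float:
    """Robust per-bin CN noise SD from first differences of unmasked bins.

    Successive-difference MAD is insensitive to the piecewise-constant
    signal itself, so real CNVs do not inflate the estimate.  Returns 0 for
    noiseless (constructed) profiles.
    """
    vals = raw_cn[~np.isnan(raw_cn)]
    if vals.size < 3:
        return 0.0
    d = np.diff(vals)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def segment(
    profile: CopyNumberProfile,
    thresholds: ClassificationThresholds | None = None,
    min_bins: int = 5,
    gap_bins: int = 2,
    min_z: float = 4.0,
) -> list[CnvCall]:
    """Find maximal same-side out-of-band runs per chromosome.

    ``profile`` should be the smoothed profile; segment means come from its
    ``raw_cn``.  Runs separated by at most ``gap_bins`` masked or in-band
    bins are merged; runs with fewer than ``min_bins`` out-of-band member
    bins are discarded.  With 20-kb bins the default ``min_bins=5`` sets a
    0.1-Mb floor, matching the stated resolution of bin-level CNV-seq.

    ``min_z`` is a significance gate on the segment mean: a run is kept
    only when |mean CN - 2| exceeds ``min_z`` standard errors of the mean,
    with the per-bin noise SD estimated robustly from the profile itself.
    This suppresses the short spurious "mosaic" excursions that bin-level
    Poisson noise produces at low-pass depth; set ``min_z=0`` to disable.
    """
    t = thresholds or ClassificationThresholds()
    calls: list[CnvCall] = []
    g = profile.grid
    noise_sd = _bin_noise_sd(profile.raw_cn) if min_z > 0 else 0.0
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        cn = profile.cn[sl]
        side = np.zeros(len(cn), dtype=int)  # +1 gain side, -1 loss side, 0 in-band/masked
        with np.errstate(invalid="ignore"):
            side[cn <= t.disomy_low] = -1
            side[cn >= t.disomy_high] = 1
        side[np.isnan(cn)] = 0
        runs: list[tuple[int, list[int]]] = []  # (side, member bin indices)
        cur_side = 0
        members: list[int] = []
        gap = 0
        for i, s in enumerate(side):
            if cur_side == 0:
                if s != 0:
                    cur_side, members, gap = s, [i], 0
            elif s == cur_side:
                members.append(i)
                gap = 0
            elif s == 0:
                gap += 1
                if gap > gap_bins:
                    runs.append((cur_side, members))
                    cur_side, members, gap = 0, [], 0
            else:  # opposite side: close current run, open a new one
                runs.append((cur_side, members))
                cur_side, members, gap = s, [i], 0
        if cur_side != 0:
            runs.append((cur_side, members))
        raw_chrom = profile.raw_cn[sl]
        for _, mem in runs:
            if len(mem) < min_bins:
                continue
            # edge refinement on raw CN: the smoothing window bleeds the
            # CNV signal into flanking bins, so each end is cut where the
            # cumulative "disomy-like vs segment-like" vote over raw CN is
            # most negative (a CUSUM change-point on the run's edge)
            level = float(np.nanmedian(raw_chrom[mem]))
            raw_mem = raw_chrom[mem]
            # signed evidence per bin: positive = closer to the segment
            # level, negative = closer to disomy; the one-bin margin keeps
            # genuine CNV edge bins that merely dipped toward 2
            votes = np.nan_to_num(
                np.abs(raw_mem - 2.0) - np.abs(raw_mem - level), nan=0.0
            )
            lo = _edge_trim(votes)
            hi = len(mem) - 1 - _edge_trim(votes[::-1])
            if hi - lo + 1 < min_bins:
                continue
            mem = mem[lo : hi + 1]
            first, last = mem[0], mem[-1]
            # mean over the whole merged span (bridged in-band bins
            # included): averaging only the selected out-of-band bins would
            # bias the estimate away from 2 for pure-noise excursions
            span = profile.raw_cn[sl][first : last + 1]
            mean_cn = float(np.nanmean(span))
            state, boundary = classify_cn(max(mean_cn, 0.0), t)
            if state == STATE_DISOMY:
                continue  # noise excursion whose raw mean is in-band
            if noise_sd > 0 and abs(mean_cn - 2.0) < min_z * noise_sd / np.sqrt(len(mem)):
                continue  # not separable from bin-level noise
            calls.append(
                CnvCall(
                    chrom=chrom,
                    start=int(g.start[sl][first] + 1),
                    end=int(g.end[sl][last]),
                    state=state,
                    mean_cn=mean_cn,
                    n_bins=len(mem),
                    boundary=boundary,
                )
            )
    return calls


def _infer_sex(x_cn: float, y_cn: float, tol: float = 0.3) -> str | None:
    """Match X/Y copy number against the documented sex patterns."""
    best, best_d = None, np.inf
    for sex, (ex, ey) in SEX_PATTERNS.items():
        d = max(abs(x_cn - ex), abs(y_cn - ey))
        if d < best_d:
            best, best_d = sex, d
    return best if best_d <= tol else None


@dataclass
class WholeChromCall:
    chrom: str
    direction: str  # "gain" | "loss"
    mean_cn: float
    fraction_out_of_band: float


def call_whole_chromosome(
    profile: CopyNumberProfile,
    thresholds: ClassificationThresholds | None = None,
    min_fraction: float = 0.90,
    sex_masked: bool = True,
) -> tuple[list[WholeChromCall], str, str | None]:
    """Whole-chromosome aneuploidy calls plus the sample karyotype string.

    An autosome is called gained/lost when more than ``min_fraction`` of its
    unmasked bins lie outside the disomy band on the same side.  Sex
    composition is read from chrX/chrY copy number (Y below 0.2 is treated
    as absent); with ``sex_masked``, normal male/female samples render as
    "XN" so fetal sex is not disclosed.

    Returns ``(calls, karyotype_string, sex_composition_or_None)``.  The
    karyotype count uses the human reference complement (44 autosomes + sex
    chromosomes) regardless of how many chromosomes the analysis genome
    models, so result strings are comparable with clinical reports.
    """
    t = thresholds or ClassificationThresholds()
    g = profile.grid
    calls: list[WholeChromCall] = []
    for chrom in g.chroms:
        if chrom in ("chrX", "chrY"):
            continue
        sl = g.chrom_slice(chrom)
        cn = profile.raw_cn[sl]
        ok = ~np.isnan(cn)
        if ok.sum() == 0:
            continue
        vals = cn[ok]
        frac_gain = float((vals >= t.disomy_high).mean())
        frac_loss = float((vals <= t.disomy_low).mean())
        if frac_gain > min_fraction:
            calls.append(WholeChromCall(chrom, "gain", float(vals.mean()), frac_gain))
        elif frac_loss > min_fraction:
            calls.append(WholeChromCall(chrom, "loss", float(vals.mean()), frac_loss))

    sex: str | None = None
    x_cn = y_cn = None
    if "chrX" in g.chroms:
        x_cn = chromosome_cn(profile, "chrX")
        y_cn = chromosome_cn(profile, "chrY") if "chrY" in g.chroms else 0.0
        if y_cn < 0.2:
            y_cn = 0.0
        sex = _infer_sex(x_cn, y_cn)

    n_sex = len(sex.replace("O", "")) if sex else 2
    total = HUMAN_AUTOSOME_COUNT + n_sex
    total += sum(1 if c.direction == "gain" else -1 for c in calls)
    suffixes = "".join(
        f",{'+' if c.direction == 'gain' else '-'}{c.chrom.removeprefix('chr')}"
        for c in calls
    )
    if sex is None:
        sex_str = "X?"
    elif sex in ("XX", "XY") and sex_masked:
        sex_str = "XN"
    else:
        sex_str = sex
    if calls and sex_str == "XN":
        karyotype = f"{total}XN{suffixes}"  # clinical dialect: "47XN,+21"
    else:
        karyotype = f"{total},{sex_str}{suffixes}"
    return calls, karyotype, sex


def name_cnv(call: CnvCall, genome: GenomeModel | None = None) -> str:
    """ISCN-style name, e.g. ``5p15.33-p13.3(del, 31.90 Mb)``.

    Uses the cytoband containing each endpoint; a single-band segment
    prints the band once.  Without cytoband coverage, falls back to
    coordinate naming ``chrom:start-end(del, X Mb)``.
    """
    side = call.side
    size = f"{call.size_mb:.2f}"
    chrom_num = call.chrom.removeprefix("chr")
    band_start = band_end = None
    if genome is not None:
        band_start = genome.band_at(call.chrom, call.start - 1)
        band_end = genome.band_at(call.chrom, call.end - 1)
    if band_start is None or band_end is None:
        return f"{call.chrom}:{call.start}-{call.end}({side}, {size} Mb)"
    call.cytoband_span = band_start if band_start == band_end else f"{band_start}-{band_end}"
    if band_start == band_end:
        return f"{chrom_num}{band_start}({side}, {size} Mb)"
    return f"{chrom_num}{band_start}-{band_end}({side}, {size} Mb)"


@dataclass
class SampleResult:
    """End-to-end result for one sample."""

    karyotype: str
    sex: str | None
    whole_chrom_calls: list[WholeChromCall]
    cnv_calls: list[CnvCall]
    chromosome_cn: dict[str, float]
    arm_cn: dict[str, float] = field(default_factory=dict)
    qc: object | None = None
    mcc_percent: float | None = None
    mcc_pass: bool | None = None
    status: str = "PASS"

    def calls_table_rows(self):
        for c in self.cnv_calls:
            yield {
                "chrom": c.chrom,
                "start1": c.start,
                "end1": c.end,
                "state": c.state,
                "mean_cn": round(c.mean_cn, 3),
                "size_mb": c.size_mb,
                "n_bins": c.n_bins,
                "mosaic_fraction": "" if c.mosaic_fraction is None else round(c.mosaic_fraction, 3),
                "boundary": int(c.boundary),
                "name": c.name or "",
            }
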