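"""Genome models for fixed-bin copy-number analysis.

A :class:`GenomeModel` is the minimal description of a reference genome that
read-depth CNV calling needs: chromosome names and lengths, per-bin GC
fraction, regions to exclude from statistics (repetitive/unmappable DNA and
centromeres), and an optional cytoband table for ISCN-style naming.  Toy
genomes built here stand in for hg19 at desk scale; no real sequence is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SEX_CHROMS = ("chrX", "chrY")

#: Documented sex-chromosome compositions for karyotype simulation.
SEX_COMPOSITIONS = ("XX", "XY", "XO", "XXY", "XXX", "XYY")


@dataclass
class GenomeModel:
    """Chromosome-level reference model.

    Coordinates are internal 0-based half-open; conversion to the 1-based
    inclusive convention used in reports happens only at I/O boundaries.

    Attributes
    ----------
    chroms : list of str
        Chromosome names in karyotype order.
    lengths : dict
        Chromosome length in bp.
    bin_size : int
        Width of the bins at which ``gc`` is defined.
    gc : dict
        Per-chromosome array of GC fraction per full bin, values in [0, 1].
    excluded : dict
        Per-chromosome list of (start, end) intervals excluded from
        statistics (repetitive regions, blacklists).  Centromeres are kept
        separately but are also excluded.
    centromeres : dict
        Per-chromosome (start, end) centromere interval.
    cytobands : dict or None
        Per-chromosome list of (name, start, end) tiling the chromosome.
    """

    chroms: list[str]
    lengths: dict[str, int]
    bin_size: int
    gc: dict[str, np.ndarray]
    excluded: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    cytobands: dict[str, list[tuple[str, int, int]]] | None = None

    def __post_init__(self) -> None:
        for c in self.chroms:
            if self.lengths[c] <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
            g = np.asarray(self.gc[c], dtype=float)
            if np.any((g < 0) | (g > 1)):
                raise ValueError(f"GC fractions of {c} outside [0, 1]")
            self.gc[c] = g
            for s, e in self.excluded.get(c, []):
                if not (0 <= s < e <= self.lengths[c]):
                    raise ValueError(f"excluded interval {s}-{e} outside {c}")
            if c in self.centromeres:
                s, e = self.centromeres[c]
                if not (0 <= s < e <= self.lengths[c]):
                    raise ValueError(f"centromere {s}-{e} outside {c}")
        if self.cytobands is not None:
            for c, bands in self.cytobands.items():
                pos = 0
                for _, s, e in bands:
                    if s != pos or e <= s:
                        raise ValueError(f"cytobands of {c} do not tile the chromosome")
                    pos = e
                if pos != self.lengths[c]:
                    raise ValueError(f"cytobands of {c} do not cover the chromosome")

    # -- queries -----------------------------------------------------------

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chroms if c not in SEX_CHROMS]

    def n_bins(self, chrom: str) -> int:
        return self.lengths[chrom] // self.bin_size

    def excluded_with_centromeres(self, chrom: str) -> list[tuple[int, int]]:
        ivals = list(self.excluded.get(chrom, []))
        if chrom in self.centromeres:
            ivals.append(self.centromeres[chrom])
        return sorted(ivals)

    def band_at(self, chrom: str, pos: int) -> str | None:
        """Cytoband name containing 0-based position ``pos``, or None."""
        if self.cytobands is None or chrom not in self.cytobands:
            return None
        for name, s, e in self.cytobands[chrom]:
            if s <= pos < e:
                return name
        return None

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str) -> None:
        obj = {
            "chroms": self.chroms,
            "lengths": self.lengths,
            "bin_size": self.bin_size,
            "gc": {c: np.round(self.gc[c], 5).tolist() for c in self.chroms},
            "excluded": {c: list(map(list, v)) for c, v in self.excluded.items()},
            "centromeres": {c: list(v) for c, v in self.centromeres.items()},
            "cytobands": None
            if self.cytobands is None
            else {c: [[n, s, e] for n, s, e in v] for c, v in self.cytobands.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "GenomeModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            chroms=obj["chroms"],
            lengths={c: int(v) for c, v in obj["lengths"].items()},
            bin_size=int(obj["bin_size"]),
            gc={c: np.asarray(v, dtype=float) for c, v in obj["gc"].items()},
            excluded={c: [tuple(i) for i in v] for c, v in obj["excluded"].items()},
            centromeres={c: tuple(v) for c, v in obj["centromeres"].items()},
            cytobands=None
            if obj["cytobands"] is None
            else {c: [(n, int(s), int(e)) for n, s, e in v] for c, v in obj["cytobands"].items()},
        )


def _toy_cytobands(length: int, cen: tuple[int, int]) -> list[tuple[str, int, int]]:
    """Tile a toy chromosome with p/q bands split at the centromere midpoint.

    Band numbering follows ISCN direction: numbers increase away from the
    centromere, so ascending coordinates on the p arm run p3 -> p1.
    """
    mid = (cen[0] + cen[1]) // 2
    bands: list[tuple[str, int, int]] = []
    p_edges = np.linspace(0, mid, 4).astype(int)
    for i in range(3):
        bands.append((f"p{3 - i}", int(p_edges[i]), int(p_edges[i + 1])))
    q_edges = np.linspace(mid, length, 4).astype(int)
    for i in range(3):
        bands.append((f"q{i + 1}", int(q_edges[i]), int(q_edges[i + 1])))
    return bands


def build_toy_genome(
    n_chroms: int,
    lengths,
    gc_profile_spec=(0.40, 0.0),
    seed: int = 0,
    bin_size: int = 20_000,
    names=None,
) -> GenomeModel:
    """Build a deterministic toy genome for simulation.

    Parameters
    ----------
    n_chroms : int
        Number of chromosomes.
    lengths : sequence of int
        Chromosome lengths in bp; each must hold at least 10 bins.
    gc_profile_spec : float or (mean, sd)
        Per-bin GC model.  A scalar gives a flat profile; a pair draws
        independent normal GC per bin, clipped to [0.05, 0.95].
    seed : int
        Seeds the GC draw; the same seed reproduces the model exactly.
    names : sequence of str, optional
        Chromosome names; defaults to chr1..chrN.
    """
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have n_chroms entries")
    for L in lengths:
        if L < 10 * bin_size:
            raise ValueError(f"chromosome length {L} holds fewer than 10 bins")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chroms)]
    names = list(names)
    if np.isscalar(gc_profile_spec):
        gc_mean, gc_sd = float(gc_profile_spec), 0.0
    else:
        gc_mean, gc_sd = map(float, gc_profile_spec)

    rng = np.random.default_rng(seed)
    gc: dict[str, np.ndarray] = {}
    excluded: dict[str, list[tuple[int, int]]] = {}
    centromeres: dict[str, tuple[int, int]] = {}
    cytobands: dict[str, list[tuple[str, int, int]]] = {}
    for name, L in zip(names, lengths):
        nb = L // bin_size
        if gc_sd > 0:
            gc[name] = np.clip(rng.normal(gc_mean, gc_sd, nb), 0.05, 0.95)
        else:
            gc[name] = np.full(nb, gc_mean)
        # centromere at ~30% of the chromosome, one bin-aligned Mb wide
        cen_start = (int(0.30 * L) // bin_size) * bin_size
        cen = (cen_start, min(cen_start + 1_000_000, L))
        centromeres[name] = cen
        # one repetitive/excluded region per chromosome, on the p arm
        ex_start = (int(0.10 * L) // bin_size) * bin_size
        excluded[name] = [(ex_start, ex_start + 2 * bin_size)]
        cytobands[name] = _toy_cytobands(L, cen)
    return GenomeModel(
        chroms=names,
        lengths=dict(zip(names, lengths)),
        bin_size=bin_size,
        gc=gc,
        excluded=excluded,
        centromeres=centromeres,
        cytobands=cytobands,
    )


def default_toy_genome(seed: int = 0, gc_sd: float = 0.05) -> GenomeModel:
    """The standard desk-scale genome used by the CLI and the test-bed.

    Eight chromosomes (~188 Mb, 9,400 bins of 20 kb) sized so the largest
    benchmark CNV (31.8 Mb) fits inside the chr1 q arm while remaining a
    minority of autosomal bins, preserving the autosomal-median baseline.
    """
    mb = 1_000_000
    names = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr21", "chrX", "chrY"]
    lengths = [50 * mb, 36 * mb, 28 * mb, 22 * mb, 18 * mb, 12 * mb, 16 * mb, 6 * mb]
    return build_toy_genome(
        len(names), lengths, gc_profile_spec=(0.40, gc_sd), seed=seed, names=names
    )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    if not sizes:
        raise ValueError(f"no chromosomes in {path}")
    return sizes


def read_cytobands(path: str) -> dict[str, list[tuple[str, int, int]]]:
    """Read a UCSC cytoBand.txt layout: chrom, start(0-based), end, name, stain."""
    bands: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            bands.setdefault(chrom, []).append((name, start, end))
    for chrom in bands:
        bands[chrom].sort(key=lambda b: b[1])
    return bands
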