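"""Seeded desk-scale validation benchmarks.

These reproduce, on simulated samples, the headline validation numbers a
low-pass CNV-sequencing pipeline is expected to meet: truth-interval
recovery of at least 93% for segmental CNVs from sub-Mb to tens of Mb,
chromosome X copy number 1 in monosomy X, and chromosome 21 q-arm copy
number 3 in trisomy 21 — each across 10 replicate samples.
"""

from __future__ import annotations

import numpy as np

from .concordance import TruthInterval, interval_concordance
from .config import PipelineConfig
from .genome import default_toy_genome
from .pipeline import call_sample
from .profile import chromosome_cn, counts_to_profile
from .simulate import CnvSpec, KaryotypeSpec, SimConfig, simulate_bin_counts

#: benchmark CNV panel: (size Mb, host chromosome, 0-based start offset bp).
#: Sizes span the validated range 0.7-31.8 Mb; each runs as a deletion and
#: as a duplication on the default toy genome's q arms.
CNV_PANEL = [
    (0.7, "chr21", 6_200_000),
    (1.4, "chr5", 8_000_000),
    (2.6, "chr4", 8_000_000),
    (4.8, "chr3", 10_000_000),
    (17.3, "chr2", 16_000_000),
    (31.8, "chr1", 17_000_000),
]

N_REPLICATES = 10
DEPTH_PER_BIN = 30.0


def replicate_seed(base_seed: int, k: int) -> int:
    return (base_seed * 1000 + k) % (2**31)


def panel_concordances(base_seed: int = 1) -> list[float]:
    """Truth-interval coverage (%) for every replicate x panel CNV."""
    genome = default_toy_genome(seed=0)
    config = PipelineConfig()
    out: list[float] = []
    for size_mb, chrom, offset in CNV_PANEL:
        for kind in ("del", "dup"):
            cnv = CnvSpec(chrom, offset + 1, offset + int(size_mb * 1e6), kind)
            truth = TruthInterval(cnv.chrom, cnv.start, cnv.end, kind)
            for k in range(N_REPLICATES):
                bc, _ = simulate_bin_counts(
                    genome,
                    KaryotypeSpec("XX"),
                    [cnv],
                    depth_per_bin=DEPTH_PER_BIN,
                    config=SimConfig(seed=replicate_seed(base_seed, k)),
                )
                result = call_sample(bc, config)
                [rec] = interval_concordance(result.cnv_calls, [truth])
                out.append(rec.concordance_percent)
    return out


def monosomy_x_cn(base_seed: int = 1) -> list[float]:
    """Chromosome X CN across 10 simulated 45,X replicates."""
    genome = default_toy_genome(seed=0)
    out = []
    for k in range(N_REPLICATES):
        bc, _ = simulate_bin_counts(
            genome,
            KaryotypeSpec("XO"),
            depth_per_bin=DEPTH_PER_BIN,
            config=SimConfig(seed=replicate_seed(base_seed, k)),
        )
        profile = counts_to_profile(bc)
        out.append(chromosome_cn(profile, "chrX"))
    return out


def trisomy_21_q_cn(base_seed: int = 1) -> list[float]:
    """Chromosome 21 q-arm CN across 10 simulated trisomy-21 replicates."""
    genome = default_toy_genome(seed=0)
    out = []
    for k in range(N_REPLICATES):
        bc, _ = simulate_bin_counts(
            genome,
            KaryotypeSpec("XX", {"chr21": 3}),
            depth_per_bin=DEPTH_PER_BIN,
            config=SimConfig(seed=replicate_seed(base_seed, k)),
        )
        profile = counts_to_profile(bc)
        out.append(chromosome_cn(profile, "chr21", arm="q"))
    return out


def consensus_integer(values) -> int:
    """Integer consensus across replicates: the unanimous rounded value, or
    the rounded mean when replicates disagree."""
    rounded = {int(round(v)) for v in values}
    if len(rounded) == 1:
        return rounded.pop()
    return int(round(float(np.mean(values))))
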