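"""Classification thresholds, segmentation, karyotyping and naming."""

import numpy as np
import pytest

from bincnv import (
    ClassificationThresholds,
    CnvCall,
    CnvSpec,
    KaryotypeSpec,
    SimConfig,
    call_sample,
    call_whole_chromosome,
    classify_cn,
    estimate_mosaic_fraction,
    name_cnv,
    segment,
    simulate_bin_counts,
)
from bincnv.binning import build_bin_grid, grid_from_genome
from bincnv.profile import CopyNumberProfile, normalize_to_cn, smooth

MB = 1_000_000


class TestClassifyCn:
    @pytest.mark.parametrize(
        "cn,state",
        [
            (3.0, "duplication"),
            (2.81, "duplication"),
            (2.0, "disomy"),
            (1.81, "disomy"),
            (2.19, "disomy"),
            (2.5, "mosaic trisomy"),
            (0.9, "deletion"),
            (0.0, "deletion"),
            (1.5, "mosaic monosomy"),
        ],
    )
    def test_states(self, cn, state):
        got, boundary = classify_cn(cn)
        assert got == state and not boundary

    @pytest.mark.parametrize(
        "cn,state",
        [
            (1.2, "mosaic monosomy"),
            (1.8, "mosaic monosomy"),
            (2.2, "mosaic trisomy"),
            (2.8, "mosaic trisomy"),
        ],
    )
    def test_boundary_values_go_to_mosaic_band_flagged(self, cn, state):
        got, boundary = classify_cn(cn)
        assert got == state and boundary

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cn(-0.1)

    def test_total_and_piecewise_constant(self):
        # brute-force comparison against the interval definition
        t = ClassificationThresholds()
        for cn in np.linspace(0, 5, 1001):
            state, _ = classify_cn(float(cn), t)
            if cn < 1.2:
                expected = "deletion"
            elif cn <= 1.8:
                expected = "mosaic monosomy"
            elif cn < 2.2:
                expected = "disomy"
            elif cn <= 2.8:
                expected = "mosaic trisomy"
            else:
                expected = "duplication"
            assert state == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(dup_min=2.0, disomy_high=2.5)


class TestMosaicFraction:
    @pytest.mark.parametrize(
        "cn,state,f",
        [
            (2.4, "mosaic trisomy", 0.4),
            (1.5, "mosaic monosomy", 0.5),
        ],
    )
    def test_inversion(self, cn, state, f):
        assert estimate_mosaic_fraction(cn, state) == pytest.approx(f)

    def test_not_reported_for_disomy(self):
        assert estimate_mosaic_fraction(2.0, "disomy") is None


def _noiseless_profile(values_per_chrom: dict[str, np.ndarray]) -> CopyNumberProfile:
    sizes = {c: len(v) * 20_000 for c, v in values_per_chrom.items()}
    grid = build_bin_grid(sizes, bin_size=20_000)
    cn = np.concatenate([np.asarray(values_per_chrom[c], dtype=float) for c in grid.chroms])
    return CopyNumberProfile(grid=grid, cn=cn, raw_cn=cn.copy(), baseline=1.0)


class TestSegment:
    def test_flat_profile_no_segments(self):
        p = _noiseless_profile({"chr1": np.full(300, 2.0)})
        assert segment(p) == []

    def test_240_bin_deletion_recovered_within_one_bin(self):
        vals = np.full(600, 2.0)
        vals[100:340] = 1.0
        p = _noiseless_profile({"chr1": vals})
        calls = segment(p)
        assert len(calls) == 1
        c = calls[0]
        assert c.state == "deletion" and c.mean_cn == pytest.approx(1.0)
        assert abs((c.start - 1) // 20_000 - 100) <= 1
        assert abs(c.end // 20_000 - 340) <= 1

    def test_short_excursion_discarded(self):
        vals = np.full(300, 2.0)
        vals[50:53] = 3.0
        p = _noiseless_profile({"chr1": vals})
        assert segment(p, min_bins=5) == []

    def test_gap_merging(self):
        vals = np.full(300, 2.0)
        vals[100:110] = 3.0
        vals[112:120] = 3.0  # 2-bin in-band gap: merged
        p = _noiseless_profile({"chr1": vals})
        calls = segment(p, gap_bins=2)
        assert len(calls) == 1 and calls[0].n_bins == 18

    def test_segments_never_overlap(self):
        rng = np.random.default_rng(3)
        vals = 2.0 + rng.normal(0, 0.4, 2000)
        p = _noiseless_profile({"chr1": vals})
        calls = sorted(segment(p, min_z=0.0), key=lambda c: c.start)
        for a, b in zip(calls, calls[1:]):
            assert a.end < b.start

    def test_size_mb_rounding(self):
        c = CnvCall("chr1", 1, 31_900_000, "deletion", 1.0, 1595)
        assert c.size_mb == 31.90


class TestWholeChromosome:
    def _profile_for(self, karyotype: KaryotypeSpec, genome):
        grid = grid_from_genome(genome)
        cn = np.concatenate(
            [np.full(grid.n_bins(c), float(karyotype.copy_of(c))) for c in grid.chroms]
        )
        cn[grid.mask] = np.nan
        return CopyNumberProfile(grid=grid, cn=cn, raw_cn=cn.copy(), baseline=1.0)

    @pytest.mark.parametrize(
        "sex,extra,expected",
        [
            ("XX", {"chr21": 3}, "47XN,+21"),
            ("XO", {}, "45,XO"),
            ("XX", {}, "46,XN"),
            ("XY", {}, "46,XN"),
            ("XXY", {}, "47,XXY"),
            ("XXX", {}, "47,XXX"),
            ("XYY", {}, "47,XYY"),
            ("XX", {"chr18": 3}, "47XN,+18"),
        ],
    )
    def test_karyotype_strings(self, sex, extra, expected, toy_genome):
        import bincnv.genome as genome_mod

        g = toy_genome
        if "chr18" in extra:
            g = genome_mod.build_toy_genome(
                4, [30 * MB, 25 * MB, 20 * MB, 15 * MB],
                names=["chr1", "chr18", "chrX", "chrY"], seed=0,
            )
        k = KaryotypeSpec(sex, extra)
        profile = self._profile_for(k, g)
        calls, karyotype, inferred_sex = call_whole_chromosome(profile)
        assert karyotype == expected
        assert inferred_sex == sex

    def test_trisomy_detected_as_gain(self, toy_genome):
        profile = self._profile_for(KaryotypeSpec("XX", {"chr21": 3}), toy_genome)
        calls, _, _ = call_whole_chromosome(profile)
        assert len(calls) == 1
        assert calls[0].chrom == "chr21" and calls[0].direction == "gain"

    def test_ambiguous_sex_flagged(self, toy_genome):
        profile = self._profile_for(KaryotypeSpec("XX"), toy_genome)
        sl = profile.grid.chrom_slice("chrX")
        profile.raw_cn[sl] = 1.5  # halfway between XX and XO
        _, karyotype, sex = call_whole_chromosome(profile)
        assert sex is None and "X?" in karyotype


class TestNameCnv:
    def test_multi_band_deletion_pattern(self, toy_genome):
        # chr1 q arm: q1 starts at 15.5 Mb (centromere midpoint)
        call = CnvCall("chr1", 17_000_001, 48_900_000, "deletion", 1.0, 1595)
        name = name_cnv(call, toy_genome)
        assert name == "1q1-q3(del, 31.90 Mb)"

    def test_single_band_duplication(self, toy_genome):
        call = CnvCall("chr2", 30_000_001, 30_730_000, "duplication", 3.0, 36)
        name = name_cnv(call, toy_genome)
        assert name.endswith("(dup, 0.73 Mb)")
        assert name.count("q") == 1  # band printed once

    def test_mosaic_states_use_del_dup_sides(self, toy_genome):
        call = CnvCall("chr2", 30_000_001, 30_730_000, "mosaic monosomy", 1.5, 36)
        assert "(del," in name_cnv(call, toy_genome)

    def test_coordinate_fallback_without_cytobands(self, small_genome):
        g = small_genome
        import dataclasses

        bare = dataclasses.replace(g, cytobands=None)
        call = CnvCall("chr1", 1_000_001, 2_000_000, "deletion", 1.0, 50)
        assert name_cnv(call, bare) == "chr1:1000001-2000000(del, 1.00 Mb)"
        assert name_cnv(call, None).startswith("chr1:")


class TestRoundTrip:
    def test_noiseless_boundaries_within_two_bins(self, toy_genome):
        grid = grid_from_genome(toy_genome)
        from bincnv.simulate import expected_cn_per_bin

        cnv = CnvSpec("chr3", 10_000_001, 14_800_000, "del")
        cn = expected_cn_per_bin(grid, KaryotypeSpec("XX"), [cnv])
        cn_masked = cn.copy()
        cn_masked[grid.mask] = np.nan
        p = CopyNumberProfile(grid=grid, cn=cn_masked, raw_cn=cn_masked.copy(), baseline=1.0)
        calls = [c for c in segment(smooth(p, 5)) if c.chrom == "chr3"]
        assert len(calls) == 1
        c = calls[0]
        assert c.state == "deletion"
        assert abs(c.start - cnv.start) <= 2 * 20_000
        assert abs(c.end - cnv.end) <= 2 * 20_000

    def test_noisy_recovery_rate(self, toy_genome):
        # >=90% of 50 replicates within +/-3 bins at depth 30 (1-Mb CNV)
        cnv = CnvSpec("chr4", 8_000_001, 9_000_000, "dup")
        hits = 0
        for rep in range(50):
            bc, _ = simulate_bin_counts(
                toy_genome, KaryotypeSpec("XX"), [cnv], depth_per_bin=30,
                config=SimConfig(seed=2000 + rep),
            )
            res = call_sample(bc)
            match = [
                c
                for c in res.cnv_calls
                if c.chrom == "chr4" and c.side == "dup"
                and c.start <= cnv.end and c.end >= cnv.start
            ]
            if len(match) == 1:
                c = match[0]
                if abs(c.start - cnv.start) <= 3 * 20_000 and abs(c.end - cnv.end) <= 3 * 20_000:
                    hits += 1
        assert hits >= 45
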