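"""Simulator: genome construction, count-tier and read-tier samples, MCC."""

import numpy as np
import pytest

from bincnv import (
    CnvSpec,
    KaryotypeSpec,
    SimConfig,
    build_toy_genome,
    simulate_bin_counts,
    simulate_reads,
    spike_mcc,
)
from bincnv.binning import grid_from_genome
from bincnv.simulate import expected_cn_per_bin

MB = 1_000_000


class TestToyGenome:
    def test_flat_gc_profile(self):
        g = build_toy_genome(2, [2 * MB, 2 * MB], gc_profile_spec=0.40, seed=0)
        for c in g.chroms:
            assert np.all(g.gc[c] == 0.40)

    def test_same_seed_is_deterministic(self):
        a = build_toy_genome(2, [2 * MB, 3 * MB], gc_profile_spec=(0.4, 0.05), seed=7)
        b = build_toy_genome(2, [2 * MB, 3 * MB], gc_profile_spec=(0.4, 0.05), seed=7)
        for c in a.chroms:
            assert np.array_equal(a.gc[c], b.gc[c])
        assert a.excluded == b.excluded and a.centromeres == b.centromeres

    def test_gc_sd_matches_generating_distribution(self):
        g = build_toy_genome(1, [30 * MB], gc_profile_spec=(0.40, 0.05), seed=3)
        gc = g.gc["chr1"]
        assert len(gc) >= 1000
        assert abs(gc.std() - 0.05) < 0.01

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_toy_genome(1, [5 * 20_000], gc_profile_spec=0.4)

    def test_annotations_present(self):
        g = build_toy_genome(2, [2 * MB, 2 * MB], seed=0)
        for c in g.chroms:
            assert g.excluded[c] and c in g.centromeres
            # cytobands tile the chromosome
            assert g.cytobands[c][0][1] == 0
            assert g.cytobands[c][-1][2] == g.lengths[c]


class TestBinCountSimulation:
    def test_disomic_mean_equals_depth(self, small_genome):
        bc, _ = simulate_bin_counts(
            small_genome, KaryotypeSpec("XX"), depth_per_bin=50, config=SimConfig(seed=1)
        )
        sl = bc.grid.chrom_slice("chr1")
        assert abs(bc.counts[sl].mean() - 50) < 1.5

    def test_trisomic_mean_scales_by_1_5(self):
        # Monte-Carlo over >= 1e4 bins: Poisson mean scaling
        g = build_toy_genome(2, [210 * MB, 60 * MB], gc_profile_spec=0.4, seed=0)
        bc, _ = simulate_bin_counts(
            g, KaryotypeSpec("XX", {"chr1": 3}), depth_per_bin=30, config=SimConfig(seed=2)
        )
        tri = bc.counts[bc.grid.chrom_slice("chr1")]
        dis = bc.counts[bc.grid.chrom_slice("chr2")]
        assert len(tri) >= 10_000
        assert abs(tri.mean() - 45) < 0.5
        assert abs(dis.mean() - 30) < 0.5

    def test_mosaic_expected_cn_closed_form(self, small_genome):
        cnv = CnvSpec("chr2", 1 * MB + 1, 3 * MB, "dup", copies=3, mosaic_fraction=0.4)
        grid = grid_from_genome(small_genome)
        cn = expected_cn_per_bin(grid, KaryotypeSpec("XX"), [cnv])
        sl = grid.chrom_slice("chr2")
        inside = cn[sl][(grid.start[sl] >= 1 * MB) & (grid.end[sl] <= 3 * MB)]
        assert np.allclose(inside, 2 * (1 - 0.4) + 3 * 0.4)  # = 2.4

    def test_mosaic_recovery_at_depth(self, small_genome):
        # 2(1-f)+c*f recovered within 0.05 at depth 100 over a >=200-bin CNV
        f = 0.3
        cnv = CnvSpec("chr1", 1, 4 * MB, "dup", copies=3, mosaic_fraction=f)
        bc, truth = simulate_bin_counts(
            small_genome, KaryotypeSpec("XX"), [cnv], depth_per_bin=100, config=SimConfig(seed=5)
        )
        sl = bc.grid.chrom_slice("chr1")
        assert sl.stop - sl.start >= 200
        est_cn = 2 * bc.counts[sl].mean() / 100
        assert abs(est_cn - (2 * (1 - f) + 3 * f)) < 0.05

    def test_seed_bit_reproducible(self, small_genome):
        a, _ = simulate_bin_counts(small_genome, depth_per_bin=30, config=SimConfig(seed=9))
        b, _ = simulate_bin_counts(small_genome, depth_per_bin=30, config=SimConfig(seed=9))
        assert np.array_equal(a.counts, b.counts)

    def test_total_expected_count_conserved(self, small_genome):
        depth = 100
        bc, truth = simulate_bin_counts(
            small_genome, KaryotypeSpec("XO"), depth_per_bin=depth, config=SimConfig(seed=4)
        )
        expected_total = depth * (truth.expected_cn / 2).sum()
        # Poisson total: sd = sqrt(expected_total)
        assert abs(bc.counts.sum() - expected_total) < 5 * np.sqrt(expected_total)

    def test_overlapping_cnvs_rejected(self, small_genome):
        cnvs = [
            CnvSpec("chr1", 1, 2 * MB, "del"),
            CnvSpec("chr1", 1 * MB, 3 * MB, "dup"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_bin_counts(small_genome, KaryotypeSpec("XX"), cnvs, depth_per_bin=10)

    def test_masked_bins_still_receive_counts(self, small_genome):
        bc, _ = simulate_bin_counts(small_genome, depth_per_bin=50, config=SimConfig(seed=6))
        assert bc.counts[bc.grid.mask].sum() > 0


class TestReadSimulation:
    def test_raw_reads_are_45_bp(self, small_genome):
        reads, table, _ = simulate_reads(
            small_genome, config=SimConfig(total_raw_reads=500, seed=1)
        )
        assert len(reads) == 500
        assert all(len(seq) == 45 and len(qual) == 45 for _, seq, qual in reads)

    def test_all_unique_no_duplicates(self, small_genome):
        _, table, _ = simulate_reads(
            small_genome,
            config=SimConfig(total_raw_reads=2000, p_unique=1.0, p_duplicate=0.0, seed=2),
        )
        assert (table["status"] == "unique").all()
        assert (table["duplicate"] == 0).all()

    def test_duplicate_fraction_matches_probability(self, small_genome):
        n = 100_000
        _, table, _ = simulate_reads(
            small_genome,
            config=SimConfig(total_raw_reads=n, p_unique=1.0, p_duplicate=0.05, seed=3),
        )
        frac = table["duplicate"].mean()
        assert abs(frac - 0.05) < 0.005

    def test_unmapped_reads_carry_no_position(self, small_genome):
        _, table, _ = simulate_reads(
            small_genome, config=SimConfig(total_raw_reads=3000, p_unique=0.5, seed=4)
        )
        bad = table[table["status"] != "unique"]
        assert (bad["pos"] == 0).all() and (bad["chrom"] == ".").all()

    def test_adapter_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="adapter"):
            SimConfig(adapter="ACGT")  # 4 != 45 - 36


class TestSpikeMcc:
    @pytest.fixture()
    def pair(self, small_genome):
        fetal, _ = simulate_bin_counts(
            small_genome, KaryotypeSpec("XO"), depth_per_bin=200, config=SimConfig(seed=11)
        )
        maternal, _ = simulate_bin_counts(
            small_genome, KaryotypeSpec("XX"), depth_per_bin=200, config=SimConfig(seed=12)
        )
        return fetal, maternal

    def test_fraction_zero_keeps_fetal(self, pair):
        fetal, maternal = pair
        mixed = spike_mcc(fetal, maternal, 0.0, seed=1)
        assert np.array_equal(mixed.counts, fetal.counts)

    def test_fraction_one_is_maternal(self, pair):
        fetal, maternal = pair
        mixed = spike_mcc(fetal, maternal, 1.0, seed=1)
        assert np.array_equal(mixed.counts, maternal.counts)

    def test_xo_plus_xx_at_half_gives_x_cn_1_5(self, pair):
        fetal, maternal = pair
        mixed = spike_mcc(fetal, maternal, 0.5, seed=2)
        x = mixed.counts[mixed.grid.chrom_slice("chrX")]
        # expected chrX CN 1.5 -> mean count 0.75 * depth
        assert abs(2 * x.mean() / 200 - 1.5) < 0.05

    def test_mismatched_grids_rejected(self, pair, small_genome, toy_genome):
        fetal, _ = pair
        other, _ = simulate_bin_counts(toy_genome, depth_per_bin=10, config=SimConfig(seed=1))
        with pytest.raises(ValueError, match="grid"):
            spike_mcc(fetal, other, 0.1)
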