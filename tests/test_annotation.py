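"""Annotation-driven bead classification, comparison utilities, contact maps,
and the synthetic annotation fixture generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromodyn.annotation import (
    BIN_BP,
    ContactMap,
    classify_beads_dhs,
    classify_beads_hmm,
    contact_decay_exponent,
    contact_map_from_trajectories,
    ellipsoid_for_territory,
    genomic_bins,
    n_bins,
    nearest_tu_distance_correlation,
    rank_quintile_compare,
    read_bed,
    read_bedgraph,
    synthetic_annotation_fixture,
)
from chromodyn.params import BeadClass, ConfigurationError


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestClassifyDHS:
    def test_precedence_and_default(self):
        length = 5 * BIN_BP
        dhs = bed([("chr1", 100, 200, "d0"),          # bin 0
                   ("chr1", 3100, 3200, "d1")])       # bin 1
        ac = bed([("chr1", 3100, 3300, "a0"),          # bin 1 (loses to DHS)
                  ("chr1", 7000, 7100, "a1")])        # bin 2
        classes = classify_beads_dhs(dhs, ac, "chr1", length)
        assert classes.tolist() == [0, 0, 1, 2, 2]

    def test_one_bp_overlap_counts(self):
        dhs = bed([("chr1", BIN_BP - 1, BIN_BP + 1, "d")])  # bins 0 and 1
        classes = classify_beads_dhs(dhs, bed([]), "chr1", 3 * BIN_BP)
        assert classes.tolist() == [0, 0, 2]

    def test_empty_tracks_all_heterochromatin(self):
        classes = classify_beads_dhs(bed([]), bed([]), "chr1", 4 * BIN_BP)
        assert np.all(classes == BeadClass.HETEROCHROMATIN)

    def test_bead_counts_match_published_chromosome_sizes(self):
        # hg19 HSA14 (107,349,540 bp) -> 35,784 beads of 3 kbp;
        # HSA22 (51,304,566 bp) -> 17,102 beads
        assert n_bins(107_349_540) == 35_784
        assert n_bins(51_304_566) == 17_102

    def test_bins_tile_contiguously_with_short_last_bin(self):
        _, starts, ends = genomic_bins("chr1", 2 * BIN_BP + 500)
        assert starts.tolist() == [0, BIN_BP, 2 * BIN_BP]
        assert ends.tolist() == [BIN_BP, 2 * BIN_BP, 2 * BIN_BP + 500]


class TestClassifyHMM:
    STATE_MAP = {"Tss": BeadClass.TU, "Enh": BeadClass.EUCHROMATIN,
                 "Quies": BeadClass.HETEROCHROMATIN}

    def test_majority_overlap(self):
        track = bed([("chr1", 0, 1000, "Tss"), ("chr1", 1000, 3000, "Enh")])
        classes = classify_beads_hmm(track, self.STATE_MAP, "chr1", BIN_BP)
        assert classes.tolist() == [int(BeadClass.EUCHROMATIN)]

    def test_tie_breaks_to_lower_coordinate_interval(self):
        track = bed([("chr1", 0, 1500, "Tss"), ("chr1", 1500, 3000, "Enh")])
        classes = classify_beads_hmm(track, self.STATE_MAP, "chr1", BIN_BP)
        assert classes.tolist() == [int(BeadClass.TU)]

    def test_unmapped_state_is_error_listing_label(self):
        track = bed([("chr1", 0, 500, "Mystery")])
        with pytest.raises(ConfigurationError, match="Mystery"):
            classify_beads_hmm(track, self.STATE_MAP, "chr1", BIN_BP)

    def test_round_trip_from_known_class_vector(self):
        # a track generated from a known class vector is recovered exactly
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 40)
        names = {0: "Tss", 1: "Enh", 2: "Quies"}
        rows = [("chr1", i * BIN_BP, (i + 1) * BIN_BP, names[c])
                for i, c in enumerate(truth)]
        classes = classify_beads_hmm(bed(rows), self.STATE_MAP, "chr1",
                                     40 * BIN_BP)
        assert classes.tolist() == truth.tolist()


class TestEllipsoid:
    def test_published_territory_size(self):
        a, b, c = ellipsoid_for_territory(35_784, 0.14, (2, 1, 1))
        assert c == pytest.approx(25.2, abs=0.1)
        assert a == pytest.approx(50.4, abs=0.2)
        assert b == pytest.approx(c)

    def test_volume_round_trip_and_scaling(self):
        import math

        n = 12_000
        phi = 0.1
        a, b, c = ellipsoid_for_territory(n, phi, (1.5, 1.2, 1.0))
        vol = 4 / 3 * math.pi * a * b * c
        assert n * (math.pi / 6) / vol == pytest.approx(phi, rel=1e-12)
        a2, _, _ = ellipsoid_for_territory(2 * n, phi, (1.5, 1.2, 1.0))
        assert a2 / a == pytest.approx(2 ** (1 / 3), rel=1e-12)

    def test_invalid_volume_fraction(self):
        with pytest.raises(ConfigurationError):
            ellipsoid_for_territory(100, 0.6)


class TestRankQuintileCompare:
    def test_identical_rankings(self):
        x = np.arange(100.0)
        heat, rho, _ = rank_quintile_compare(x, x * 3.0 + 1.0)
        assert rho == pytest.approx(1.0)
        off_diag = heat - np.diag(np.diag(heat))
        assert off_diag.sum() == 0 and heat.sum() == 100

    def test_reversed_rankings(self):
        x = np.arange(50.0)
        _, rho, _ = rank_quintile_compare(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_quintile_marginals_balanced(self):
        rng = np.random.default_rng(1)
        heat, _, _ = rank_quintile_compare(rng.random(1000), rng.random(1000))
        assert heat.sum() == 1000
        np.testing.assert_array_equal(heat.sum(axis=0), 200)
        np.testing.assert_array_equal(heat.sum(axis=1), 200)

    def test_patch_mode_averages_within_patches(self):
        #   TU TU | het | EU EU EU | het | TU
        classes = np.array([0, 0, 2, 1, 1, 1, 2, 0], dtype=np.int8)
        sim = np.array([1.0, 3.0, 9., 4.0, 5.0, 6.0, 9., 8.0])
        expt = np.array([2.0, 2.0, 9., 7.0, 7.0, 7.0, 9., 8.0])
        heat, rho, _ = rank_quintile_compare(sim, expt, mode="patch",
                                             bead_classes=classes)
        # three patches: means (2, 5, 8) vs (2, 7, 8) -> perfectly concordant
        assert heat.sum() == 3
        assert rho == pytest.approx(1.0)

    def test_tu_only_mode(self):
        classes = np.array([0, 1, 0, 1, 0, 1, 0], dtype=np.int8)
        sim = np.array([1.0, 9, 2.0, 9, 3.0, 9, 4.0])
        expt = np.array([4.0, 0, 3.0, 0, 2.0, 0, 1.0])
        _, rho, _ = rank_quintile_compare(sim, expt, mode="tu_only",
                                          bead_classes=classes)
        assert rho == pytest.approx(-1.0)

    def test_copula_fixture_recovers_target_rank_correlation(self):
        # full-pipeline oracle at the published chromosome scale
        fx = synthetic_annotation_fixture(35_784 * BIN_BP, target_rank_corr=0.4,
                                          seed=4)
        _, rho, p = rank_quintile_compare(fx.activity, fx.signal)
        assert rho == pytest.approx(0.4, abs=0.01)
        assert p < 1e-12


class TestNearestTUDistance:
    def test_monotone_decreasing_activity_gives_minus_one(self):
        pos = np.array([0, 10, 30, 70, 150])
        dist = np.array([10, 10, 20, 40, 80])
        activity = 1.0 / (1.0 + dist)
        r, p = nearest_tu_distance_correlation(activity, pos)
        assert r == pytest.approx(-1.0)

    def test_degenerate_equal_spacing_flagged(self):
        pos = np.arange(0, 50, 10)
        r, p = nearest_tu_distance_correlation(np.full(5, 0.5), pos)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_tus(self):
        with pytest.raises(ConfigurationError):
            nearest_tu_distance_correlation(np.array([1.0, 2.0]),
                                            np.array([0, 5]))


class TestContactMaps:
    def test_straight_chain_only_near_diagonal(self):
        n = 100
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 1.0
        frames = [(0.0, pos, None)]
        cmap = contact_map_from_trajectories([frames], n_beads=n,
                                             contact_cutoff=3.5)
        assert cmap.counts.sum() > 0
        nb = cmap.n_bins
        for d in range(2, nb):
            assert np.diagonal(cmap.counts, offset=d).sum() == 0
        # symmetry and non-negative integer counts
        np.testing.assert_array_equal(cmap.counts, cmap.counts.T)
        assert (cmap.counts >= 0).all()

    def test_power_law_decay_exponent_recovered(self):
        # constructed map with P(s) exactly s^-1 -> fitted exponent -1.00
        nb = 60
        counts = np.zeros((nb, nb))
        for d in range(1, nb):
            counts[np.arange(nb - d), np.arange(d, nb)] = 1e6 / d
            counts[np.arange(d, nb), np.arange(nb - d)] = 1e6 / d
        cmap = ContactMap(30_000, counts)
        exponent = contact_decay_exponent(cmap, 30_000, 1_500_000)
        assert exponent == pytest.approx(-1.0, abs=0.02)

    def test_flat_decay_gives_zero(self):
        nb = 60
        counts = np.full((nb, nb), 50.0)
        cmap = ContactMap(30_000, counts)
        assert contact_decay_exponent(cmap) == pytest.approx(0.0, abs=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ConfigurationError):
            contact_map_from_trajectories([[]], n_beads=10)


class TestSyntheticFixture:
    def test_density_and_file_round_trip(self, tmp_path):
        # 10,000 beads: block-level fluctuation of the TU fraction ~0.004
        fx = synthetic_annotation_fixture(10_000 * BIN_BP, tu_density=0.039,
                                          patchiness=3.0, seed=1)
        frac_tu = (fx.classes == BeadClass.TU).mean()
        assert frac_tu == pytest.approx(0.039, abs=0.015)
        paths = fx.write(tmp_path)
        dhs = read_bed(paths["dhs.bed"])
        sig = read_bedgraph(paths["signal.bedgraph"])
        # classification of the generated tracks recovers the truth exactly
        classes = classify_beads_dhs(dhs, read_bed(paths["h3k27ac.bed"]),
                                     fx.chrom, fx.length)
        np.testing.assert_array_equal(classes, fx.classes)
        np.testing.assert_allclose(sig["value"].to_numpy(),
                                   np.round(fx.signal, 6))

    def test_perfect_rank_correlation_end_to_end(self):
        fx = synthetic_annotation_fixture(500 * BIN_BP, target_rank_corr=1.0,
                                          seed=2)
        _, rho, _ = rank_quintile_compare(fx.activity, fx.signal)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic_annotation_fixture(100 * BIN_BP, tu_density=0.5)
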