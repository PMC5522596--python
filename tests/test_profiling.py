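"""DHS orientation and asymmetry rules, profile matrices, k-means
categories and expression binning."""

import numpy as np
import pandas as pd
import pytest

from enhancermap.intervals import Genome, GenomicInterval, SignalTrack
from enhancermap.partition import GeneModel
from enhancermap.profiling import (
    build_matrix,
    expression_bins,
    gene_metaprofile,
    kmeans_categories,
    orient_dhs,
)


def k9_track(up, down, dhs=(10_000, 10_400), flank=300, span=50_000):
    """Track with constant values on the two 300-bp flanks of a DHS."""
    return SignalTrack({"chr1": [
        (dhs[0] - flank, dhs[0], up),
        (dhs[1], dhs[1] + flank, down),
    ]}), GenomicInterval("chr1", *dhs)


class TestOrientDhs:
    @pytest.mark.parametrize(
        "up,down,orientation,eligible,asymmetric",
        [
            (0.2, 1.0, "keep", True, True),    # fold 5, downstream 3'
            (0.4, 0.6, "keep", True, False),   # eligible but fold 1.5
            (0.3, 0.4, "keep", False, False),  # below the 0.5 RPM floor
            (1.0, 0.2, "flip", True, True),    # upstream side is 3'
            (0.0, 0.8, "keep", True, True),    # zero flank counts asymmetric
        ],
    )
    def test_rule_table(self, up, down, orientation, eligible, asymmetric):
        track, dhs = k9_track(up, down)
        (o,) = orient_dhs([dhs], track)
        assert o.orientation == orientation
        assert o.eligible is eligible
        assert o.asymmetric is asymmetric

    def test_tie_keeps_and_flags(self):
        track, dhs = k9_track(0.7, 0.7)
        (o,) = orient_dhs([dhs], track)
        assert o.orientation == "keep"
        assert o.tie

    def test_chromosome_edge_clips_and_flags(self):
        track = SignalTrack({"chr1": [(0, 600, 1.0)]})
        dhs = GenomicInterval("chr1", 100, 400)
        genome = Genome({"chr1": 500})
        (o,) = orient_dhs([dhs], track, genome=genome)
        assert o.clipped

    def test_orientation_is_involution(self):
        """Flipping a flipped row restores the original row."""
        track = SignalTrack({"chr1": [(9000, 9700, 3.0), (10_400, 10_500, 0.5)]})
        dhs = GenomicInterval("chr1", 10_000, 10_400)
        mat_plus = build_matrix([dhs], track, flank_bp=600, body_bins=10, flank_bin_bp=20)
        dhs_minus = GenomicInterval("chr1", 10_000, 10_400, strand="-")
        mat_minus = build_matrix([dhs_minus], track, flank_bp=600, body_bins=10, flank_bin_bp=20)
        assert np.allclose(mat_minus.values[0][::-1], mat_plus.values[0])


class TestBuildMatrix:
    def test_constant_track_constant_row(self):
        track = SignalTrack({"chr1": [(0, 50_000, 1.5)]})
        mat = build_matrix(
            [GenomicInterval("chr1", 10_000, 11_000)], track,
            flank_bp=1000, body_bins=20, flank_bin_bp=20,
        )
        assert np.allclose(mat.values, 1.5)

    def test_planted_peak_lands_in_expected_bin(self):
        """A narrow peak 300 bp downstream of the feature appears as a spike
        in the corresponding flank bin of the mean profile."""
        feature = GenomicInterval("chr1", 10_000, 10_500)
        track = SignalTrack({"chr1": [(10_800, 10_820, 9.0)]})
        mat = build_matrix([feature], track, flank_bp=1000, body_bins=10, flank_bin_bp=20)
        profile = mat.mean_profile
        n_flank = mat.n_flank_bins
        spike_bin = n_flank + mat.n_body_bins + 300 // 20
        assert profile.argmax() == spike_bin
        assert profile[spike_bin] == pytest.approx(9.0)

    def test_short_feature_interpolated_to_width(self):
        track = SignalTrack({"chr1": [(10_000, 10_005, 2.0)]})
        mat = build_matrix(
            [GenomicInterval("chr1", 10_000, 10_005)], track,
            flank_bp=100, body_bins=50, flank_bin_bp=20,
        )
        assert mat.values.shape[1] == 5 + 50 + 5
        body = mat.values[0][5:55]
        assert np.allclose(body, 2.0)


class TestKmeansCategories:
    def test_planted_shapes_separate(self):
        rng = np.random.default_rng(5)
        left = np.tile(np.r_[np.ones(20) * 4, np.zeros(20)], (30, 1))
        right = np.tile(np.r_[np.zeros(20), np.ones(20) * 4], (30, 1))
        values = np.vstack([left, right]) + rng.normal(0, 0.05, (60, 40))
        from enhancermap.profiling import ProfileMatrix

        mat = ProfileMatrix(values=values, row_ids=[str(i) for i in range(60)],
                            n_flank_bins=10, n_body_bins=20)
        labels, profiles = kmeans_categories(mat, k=2, seed=0)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(8)
        from enhancermap.profiling import ProfileMatrix

        mat = ProfileMatrix(values=rng.random((20, 12)),
                            row_ids=[str(i) for i in range(20)],
                            n_flank_bins=3, n_body_bins=6)
        a, _ = kmeans_categories(mat, k=4, seed=1)
        b, _ = kmeans_categories(mat, k=4, seed=1)
        assert np.array_equal(a, b)

    def test_k_exceeding_rows_rejected(self):
        from enhancermap.profiling import ProfileMatrix

        mat = ProfileMatrix(values=np.ones((3, 5)), row_ids=["a", "b", "c"],
                            n_flank_bins=1, n_body_bins=3)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_categories(mat, k=4)

    def test_size_weighted_category_means_conserve_global_mean(self):
        rng = np.random.default_rng(21)
        from enhancermap.profiling import ProfileMatrix

        mat = ProfileMatrix(values=rng.random((40, 16)),
                            row_ids=[str(i) for i in range(40)],
                            n_flank_bins=4, n_body_bins=8)
        labels, profiles = kmeans_categories(mat, k=4, seed=2)
        weighted = sum(
            (labels == c).sum() * profiles[c] for c in np.unique(labels)
        ) / len(labels)
        assert np.allclose(weighted, mat.mean_profile)


class TestExpressionBins:
    def test_small_example(self):
        expr = pd.DataFrame(
            {"rpkm": [0.5, 2, 3, 4, 5, 6, 7]},
            index=[f"g{i}" for i in range(7)],
        )
        bins, thresholds = expression_bins(expr, "rpkm")
        assert bins.loc["g0"] == 0
        assert sorted(bins[bins > 0]) == [1, 2, 3, 4, 5, 6]
        assert len(thresholds) == 5

    def test_all_below_one_rpkm_rejected(self):
        expr = pd.DataFrame({"rpkm": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match=">= 1 RPKM"):
            expression_bins(expr, "rpkm")

    def test_equal_count_property(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame({"rpkm": rng.uniform(1, 100, size=121)})
        bins, _ = expression_bins(expr, "rpkm")
        counts = bins[bins > 0].value_counts()
        assert counts.max() - counts.min() <= 1


class TestGeneMetaprofile:
    def test_constant_track_flat_profiles(self):
        genes = [
            GeneModel(f"g{i}", "chr1", 10_000 + i * 5000, 12_000 + i * 5000,
                      "+" if i % 2 else "-")
            for i in range(4)
        ]
        track = SignalTrack({"chr1": [(0, 60_000, 2.0)]})
        bins = pd.Series([0, 0, 1, 1], index=[g.gene_id for g in genes])
        profiles = gene_metaprofile(genes, track, bins, flank_bp=500,
                                    body_bins=10, flank_bin_bp=50)
        for profile in profiles.values():
            assert np.allclose(profile, 2.0)

    def test_tss_peak_scales_with_bin(self):
        """Promoter peaks growing with expression bin produce monotone
        profile maxima across bins."""
        genes, steps, assignments = [], [], {}
        for i in range(6):
            s = 10_000 + i * 5000
            genes.append(GeneModel(f"g{i}", "chr1", s, s + 2000, "+"))
            steps.append((s, s + 200, float(i + 1)))
            assignments[f"g{i}"] = i % 3
        track = SignalTrack({"chr1": steps})
        bins = pd.Series(assignments)
        profiles = gene_metaprofile(genes, track, bins, flank_bp=500,
                                    body_bins=10, flank_bin_bp=50)
        maxima = [profiles[b].max() for b in sorted(profiles)]
        assert maxima == sorted(maxima)

    def test_empty_bin_yields_nan_profile(self):
        genes = [GeneModel("g0", "chr1", 10_000, 12_000, "+")]
        track = SignalTrack({"chr1": [(0, 20_000, 1.0)]})
        bins = pd.Series({"g0": 0, "ghost": 3}).drop("ghost")
        bins.loc["missing_bin_placeholder"] = 3
        with pytest.warns(UserWarning, match="no profiled genes"):
            profiles = gene_metaprofile(genes, track, bins, flank_bp=500,
                                        body_bins=10, flank_bin_bp=50)
        assert np.isnan(profiles[3]).all()
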