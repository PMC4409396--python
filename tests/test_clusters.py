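import numpy as np
import pandas as pd
import pytest

from palmquant import (
    FWHM_FACTOR,
    CandidateMask,
    build_candidate_mask,
    cluster_diameter_fwhm,
    extract_clusters,
    gaussianity_score,
    nn_prefilter,
    render_superres,
    summarize_cell,
)
from oracles import bin_index_bruteforce, nn_keep_bruteforce


def tracks_frame(xy):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"track_id": np.arange(len(xy)), "x_nm": xy[:, 0], "y_nm": xy[:, 1]})


class TestRenderSuperres:
    def test_empty_input(self):
        img = render_superres(np.empty((0, 2)), 10.0)
        assert img.counts.sum() == 0

    def test_single_point_in_origin_bin(self):
        img = render_superres([[0.0, 0.0]], 10.0)
        assert img.counts[0, 0] == 1 and img.counts.sum() == 1

    def test_bin_indices_match_direct_recomputation(self, rng):
        xy = rng.uniform(-500, 1500, size=(500, 2))
        b = 10.0
        img = render_superres(xy, b)
        counts = np.zeros_like(img.counts)
        for x, y in xy:
            ix, iy = bin_index_bruteforce(x, y, img.origin[0], img.origin[1], b)
            counts[iy, ix] += 1
        np.testing.assert_array_equal(img.counts, counts)
        assert img.counts.sum() == 500 and img.n_dropped == 0

    def test_out_of_extent_dropped_and_counted(self):
        img = render_superres([[5.0, 5.0], [250.0, 5.0]], 10.0, extent=(0, 100, 0, 100))
        assert img.counts.sum() == 1 and img.n_dropped == 1


class TestNNPrefilter:
    def test_line_example(self):
        pts = np.array([[0.0, 0.0], [40.0, 0.0], [200.0, 0.0]])
        kept = nn_prefilter(pts, 50.0)
        np.testing.assert_array_equal(kept, pts[:2])

    def test_sole_localization_discarded(self):
        assert len(nn_prefilter(np.array([[1.0, 2.0]]), 50.0)) == 0

    def test_infinite_threshold_keeps_everything(self, rng):
        pts = rng.uniform(0, 1e5, size=(20, 2))
        np.testing.assert_array_equal(nn_prefilter(pts, np.inf), pts)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        pts = rng.uniform(0, 600, size=(n, 2))
        keep = nn_prefilter(pts, 50.0, return_mask=True)
        assert sorted(np.flatnonzero(keep)) == nn_keep_bruteforce(pts, 50.0)

    def test_threshold_monotonicity(self, rng):
        pts = rng.uniform(0, 800, size=(300, 2))
        kept = [nn_prefilter(pts, t, return_mask=True).sum() for t in (10, 30, 50, 100, 500)]
        assert kept == sorted(kept)


class TestCandidateMask:
    def test_empty_input_empty_mask(self):
        img = render_superres(np.empty((0, 2)), 10.0, extent=(0, 500, 0, 500))
        mask = build_candidate_mask(np.empty((0, 2)), img)
        assert mask.n_labels == 0 and not mask.labels.any()

    def test_two_separated_blobs_two_labels(self, rng):
        a = rng.normal([300.0, 300.0], 20.0, size=(200, 2))
        b = rng.normal([800.0, 300.0], 20.0, size=(200, 2))
        xy = np.vstack([a, b])
        img = render_superres(xy, 10.0)
        mask = build_candidate_mask(xy, img, smoothing_sigma_nm=20.0, density_multiplier=2.0)
        assert mask.n_labels == 2
        # independent flood-fill oracle on the thresholded grid
        from skimage.measure import label as sk_label

        n_oracle = sk_label(mask.labels > 0, connectivity=2).max()
        assert mask.n_labels == n_oracle
        # the two blob centres receive different labels
        la = mask.label_at(np.array([[300.0, 300.0]]))[0]
        lb = mask.label_at(np.array([[800.0, 300.0]]))[0]
        assert la != lb and la > 0 and lb > 0

    def test_label_count_invariant_under_bin_translation(self, rng):
        xy = np.vstack([
            rng.normal([250.0, 250.0], 15.0, size=(150, 2)),
            rng.normal([600.0, 500.0], 15.0, size=(150, 2)),
        ])
        shift = np.array([70.0, -30.0])  # integer number of 10 nm bins
        m1 = build_candidate_mask(xy, render_superres(xy, 10.0))
        m2 = build_candidate_mask(xy + shift, render_superres(xy + shift, 10.0))
        assert m1.n_labels == m2.n_labels
        np.testing.assert_array_equal(m1.labels, m2.labels)


class TestExtractClusters:
    def _mask_with_two_boxes(self):
        labels = np.zeros((20, 40), dtype=int)
        labels[2:8, 2:8] = 1    # candidate 1
        labels[2:8, 22:28] = 2  # candidate 2
        return CandidateMask(labels, 2, 10.0, (0.0, 0.0))

    def test_small_candidate_rejected_three_kept(self):
        mask = self._mask_with_two_boxes()
        xy = [[40.0, 40.0], [45.0, 45.0],            # 2 tracks in candidate 1
              [240.0, 40.0], [245.0, 45.0], [250.0, 50.0]]  # 3 in candidate 2
        clusters, labels = extract_clusters(mask, tracks_frame(xy))
        assert [c.label for c in clusters] == [2]
        assert clusters[0].n_tracked_locs == 3
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 2])

    def test_empty_mask_all_unclustered(self):
        mask = CandidateMask(np.zeros((10, 10), dtype=int), 0, 10.0, (0.0, 0.0))
        clusters, labels = extract_clusters(mask, tracks_frame([[5.0, 5.0]] * 4))
        assert clusters == [] and (labels == 0).all()

    def test_assignment_matches_containment_oracle(self, rng):
        labels_grid = (rng.random((30, 30)) < 0.3).astype(int)
        from scipy import ndimage
        labels_grid, n = ndimage.label(labels_grid, structure=np.ones((3, 3)))
        mask = CandidateMask(labels_grid, n, 10.0, (-50.0, 20.0))
        xy = rng.uniform(-100, 400, size=(200, 2))
        _, assigned = extract_clusters(mask, tracks_frame(xy), min_locs=3)
        for (x, y), lab in zip(xy, assigned):
            ix, iy = bin_index_bruteforce(x, y, -50.0, 20.0, 10.0)
            expected = labels_grid[iy, ix] if 0 <= ix < 30 and 0 <= iy < 30 else 0
            assert lab == expected

    def test_min_locs_monotonicity(self, rng):
        xy = np.vstack([rng.normal([200 * k, 200.0], 12.0, size=(k + 2, 2)) for k in range(1, 6)])
        img = render_superres(xy, 10.0)
        mask = build_candidate_mask(xy, img, density_multiplier=1.0)
        tracks = tracks_frame(xy)
        counts = [len(extract_clusters(mask, tracks, min_locs=m)[0]) for m in (1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)


class TestDiameter:
    def test_degenerate_cloud_zero_diameter(self):
        sigma, diam = cluster_diameter_fwhm([[5.0, 5.0]] * 4)
        assert sigma == 0.0 and diam == 0.0

    def test_exact_constructed_sigma(self):
        # four points at (+-a, 0), (0, +-a) give pooled sigma = a / sqrt(2)
        a = 20.0 * np.sqrt(2.0)
        pts = [[a, 0.0], [-a, 0.0], [0.0, a], [0.0, -a]]
        sigma, diam = cluster_diameter_fwhm(pts)
        assert sigma == pytest.approx(20.0)
        assert diam == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 20.0)
        assert diam == pytest.approx(47.10, abs=0.01)

    def test_too_few_positions(self):
        with pytest.raises(ValueError):
            cluster_diameter_fwhm([[0.0, 0.0], [1.0, 1.0]])

    def test_large_sample_consistency(self, rng):
        sigma_true = 26.9
        pts = rng.normal(0.0, sigma_true, size=(10**4, 2))
        _, diam = cluster_diameter_fwhm(pts)
        assert diam == pytest.approx(FWHM_FACTOR * sigma_true, rel=0.02)

    def test_scale_equivariance_exact_for_power_of_two(self, rng):
        pts = rng.normal(0.0, 30.0, size=(50, 2))
        s1, d1 = cluster_diameter_fwhm(pts)
        s2, d2 = cluster_diameter_fwhm(2.0 * pts)
        assert s2 == 2.0 * s1 and d2 == 2.0 * d1


class TestGaussianity:
    def test_too_few_positions_missing(self, rng):
        assert np.isnan(gaussianity_score(rng.normal(size=(9, 2))))

    def test_ring_rejected(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 1000)
        ring = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        assert gaussianity_score(ring) < 0.01

    def test_null_calibration(self):
        """Scores are ~uniform for genuinely Gaussian clouds (type-I control)."""
        rng = np.random.default_rng(123)
        pvals = np.array([
            gaussianity_score(rng.normal(0, 25.0, size=(300, 2)), n_boot=99, seed=b)
            for b in range(150)
        ])
        assert np.mean(pvals < 0.05) <= 0.10
        assert 0.40 <= pvals.mean() <= 0.62
        assert np.mean(pvals < 0.5) == pytest.approx(0.5, abs=0.15)


class TestSummarize:
    def test_percentage_arithmetic(self):
        mask = CandidateMask(np.ones((50, 50), dtype=int), 1, 10.0, (0.0, 0.0))
        xy = [[10.0 * i + 5, 5.0] for i in range(3)]
        clusters, _ = extract_clusters(mask, tracks_frame(xy))
        summary = summarize_cell(clusters, n_total_tracks=10)
        assert summary.n_clusters == 1
        assert summary.percent_in_clusters == pytest.approx(30.0)

    def test_no_clusters_and_no_tracks(self):
        assert summarize_cell([], 10).percent_in_clusters == 0.0
        assert summarize_cell([], 10).n_clusters == 0
        assert np.isnan(summarize_cell([], 0).percent_in_clusters)
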