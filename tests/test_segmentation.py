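"""Feature binning, bisecting k-means and plaque ROI derivation."""

import itertools

import numpy as np
import pytest

from plaquescope.msi_io import MSIDataset
from plaquescope.segmentation import (
    ROI,
    background_roi,
    bisecting_kmeans,
    build_feature_matrix,
    derive_center_roi,
    extract_plaque_rois,
)


def normalized_dataset(values, n_cols=None):
    values = np.asarray(values, dtype=float)
    n_px, n_ch = values.shape
    coords = np.array([(0, c) for c in range(n_px)])
    axis = np.linspace(400, 2500, n_ch)
    ds = MSIDataset("lipid_neg", coords, 10.0, axis, values)
    ds.normalized = True  # values are treated as already normalized
    return ds


class TestBuildFeatureMatrix:
    def test_pairwise_sums(self):
        # 10 channels, width spanning 2 channels each -> 5 features
        vals = np.tile(np.arange(10.0), (3, 1))
        vals += np.random.default_rng(0).normal(0, 0.01, vals.shape)
        ds = normalized_dataset(vals)
        width = (2500 - 400) / 5 + 1e-9
        X, centers = build_feature_matrix(ds, width)
        assert X.shape == (3, 5)
        np.testing.assert_allclose(
            X[0], vals[0].reshape(5, 2).sum(axis=1), atol=0.1)

    def test_single_bin_of_normalized_data_is_degenerate(self):
        vals = np.full((4, 8), 0.125)  # every pixel sums to 1
        ds = normalized_dataset(vals)
        with pytest.raises(ValueError, match="narrower bins"):
            build_feature_matrix(ds, 2500 - 400)

    def test_invalid_width_rejected(self):
        ds = normalized_dataset(np.random.default_rng(1).random((3, 8)))
        with pytest.raises(ValueError):
            build_feature_matrix(ds, 0.0)
        with pytest.raises(ValueError):
            build_feature_matrix(ds, 1e7)

    def test_requires_normalization(self):
        ds = normalized_dataset(np.random.default_rng(2).random((3, 8)))
        ds.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            build_feature_matrix(ds, 100.0)

    def test_planted_species_feature_has_highest_variance(self, small_animal):
        from plaquescope.msi_io import tic_normalize

        ds = small_animal.datasets["peptide"]
        if not ds.normalized:
            ds, _ = tic_normalize(ds, inplace=True)
        X, centers = build_feature_matrix(ds, 5.0)
        best = centers[np.argmax(X.var(axis=0))]
        # the A-beta-like species at m/z 4330.9 dominates spatial variance
        assert abs(best - 4330.9) < 5.0


def brute_force_best_bipartition(X):
    """Exhaustive minimum-SSE 2-partition of <= 8 points."""
    n = len(X)
    best, best_sse = None, np.inf
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for part in (X[mask], X[~mask]):
            sse += ((part - part.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, mask
    return best, best_sse


class TestBisectingKmeans:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(10, 0.1, size=(12, 2))
        X = np.vstack([a, b])
        tree = bisecting_kmeans(X, 2, seed=1)
        leaves = tree.leaves
        assert len(leaves) == 2
        sets = sorted([sorted(l.indices.tolist()) for l in leaves])
        assert sets == [list(range(10)), list(range(10, 22))]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_minimum_sse_bipartition(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 2))
        tree = bisecting_kmeans(X, 2, seed=seed)
        got = {frozenset(l.indices.tolist()) for l in tree.leaves}
        mask, _ = brute_force_best_bipartition(X)
        want = {frozenset(np.flatnonzero(mask).tolist()),
                frozenset(np.flatnonzero(~mask).tolist())}
        assert got == want

    def test_identical_points_stop_early_with_warning(self):
        X = np.ones((5, 3))
        with pytest.warns(UserWarning, match="stopping early"):
            tree = bisecting_kmeans(X, 2, seed=0)
        assert len(tree.leaves) == 1

    def test_leaves_partition_and_sse_monotone(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        prev = np.inf
        for k in (2, 3, 4, 6):
            tree = bisecting_kmeans(X, k, seed=4)
            labels = tree.leaf_labels(len(X))  # raises if not a partition
            assert len(np.unique(labels)) == k
            sse = tree.total_sse()
            assert sse <= prev + 1e-9
            prev = sse

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        t1 = bisecting_kmeans(X, 4, seed=9)
        t2 = bisecting_kmeans(X, 4, seed=9)
        assert [sorted(l.indices.tolist()) for l in t1.leaves] == \
            [sorted(l.indices.tolist()) for l in t2.leaves]

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            bisecting_kmeans(np.zeros((5, 2)), 1)
        with pytest.raises(ValueError):
            bisecting_kmeans(np.zeros((2, 2)), 3)


def checkerboard_tree(grid, plaque_pixels):
    """Build a 2-leaf tree on a synthetic grid: plaque pixels vs the rest."""
    rows, cols = grid
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)])
    flat = {tuple(p) for p in plaque_pixels}
    X = np.array([[10.0, 0.0] if tuple(c) in flat else [0.0, 0.0]
                  for c in coords])
    X += np.random.default_rng(0).normal(0, 0.01, X.shape)
    tree = bisecting_kmeans(X, 2, seed=0)
    return tree, coords


class TestExtractPlaqueRois:
    def plaque_pixels(self):
        blobs = []
        for cr, cc in [(5, 5), (5, 20), (20, 8), (22, 22)]:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    blobs.append((cr + dr, cc + dc))
        return blobs

    def test_blobs_become_rois(self):
        tree, coords = checkerboard_tree((28, 28), self.plaque_pixels())
        rois, stats = extract_plaque_rois(tree, coords, (28, 28))
        assert len(rois) == 4
        assert all(len(r.pixels) == 9 for r in rois)

    def test_min_pixels_removes_speck(self):
        pixels = self.plaque_pixels() + [(14, 14)]  # 1-px speck
        tree, coords = checkerboard_tree((28, 28), pixels)
        rois, _ = extract_plaque_rois(tree, coords, (28, 28), min_pixels=2)
        centroids = {tuple(np.round(r.centroid).astype(int)) for r in rois}
        assert (14, 14) not in centroids

    def test_single_leaf_tree_explicit_selection_rejected(self):
        X = np.ones((16, 2))
        with pytest.warns(UserWarning):
            tree = bisecting_kmeans(X, 2, seed=0)
        coords = np.array([(r, c) for r in range(4) for c in range(4)])
        with pytest.raises(ValueError, match="single leaf"):
            extract_plaque_rois(tree, coords, (4, 4), selection=[0])

    def test_no_plaque_like_leaf_gives_empty_list_with_diagnostics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(36, 2)) + \
            np.repeat([[0, 0], [5, 5]], 18, axis=0)  # two big halves
        tree = bisecting_kmeans(X, 2, seed=0)
        coords = np.array([(r, c) for r in range(6) for c in range(6)])
        rois, stats = extract_plaque_rois(tree, coords, (6, 6))
        assert rois == []
        assert all({"n_components", "median_component_size"} <= set(s)
                   for s in stats.values())


class TestDeriveCenterRoi:
    def disk_roi(self, radius=10):
        pix = [(r, c) for r in range(-radius, radius + 1)
               for c in range(-radius, radius + 1)
               if r * r + c * c <= radius * radius]
        pix = np.array(pix) + radius
        return ROI("p", "whole_plaque", pix)

    def test_fraction_one_keeps_convex_roi(self):
        whole = self.disk_roi()
        center = derive_center_roi(whole, 1.0)
        assert len(center.pixels) >= 0.98 * len(whole.pixels)

    def test_fraction_half_quarters_area(self):
        whole = self.disk_roi(radius=14)
        center = derive_center_roi(whole, 0.5)
        ratio = len(center.pixels) / len(whole.pixels)
        assert 0.18 <= ratio <= 0.32  # 25% up to discretization

    def test_single_pixel_roi_is_its_own_center(self):
        whole = ROI("p", "whole_plaque", [(3, 3)])
        center = derive_center_roi(whole, 0.3)
        assert center.pixels.tolist() == [[3, 3]]

    def test_center_is_subset_of_whole(self):
        whole = self.disk_roi(radius=7)
        center = derive_center_roi(whole, 0.6)
        whole_set = {tuple(p) for p in whole.pixels}
        assert all(tuple(p) in whole_set for p in center.pixels)
        assert center.kind == "plaque_center"

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            derive_center_roi(self.disk_roi(), 0.0)


class TestBackgroundRoi:
    def test_margin_respected(self):
        roi = ROI("p", "whole_plaque", [(5, 5), (5, 6)])
        bg = background_roi([roi], (12, 12), margin=2)
        bg_set = {tuple(p) for p in bg.pixels}
        assert (5, 5) not in bg_set and (5, 7) not in bg_set and (5, 8) not in bg_set
        assert (0, 0) in bg_set
        assert bg.kind == "background"


class TestExportSegmentation:
    def test_writes_maps_and_roi_sets(self, tmp_path):
        import json

        from plaquescope.segmentation import export_segmentation

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (12, 2)),
                       rng.normal(5, 0.1, (4, 2))])
        tree = bisecting_kmeans(X, 2, seed=0)
        coords = np.array([(r, c) for r in range(4) for c in range(4)])
        roi = ROI("p1", "whole_plaque", coords[12:])
        export_segmentation(tree, coords, (4, 4), [roi], tmp_path / "seg")
        assert (tmp_path / "seg_labels.tiff").exists()
        assert (tmp_path / "seg_segmentation.png").exists()
        payload = json.loads((tmp_path / "seg_rois.json").read_text())
        assert payload["p1"] == roi.pixels.tolist()
        assert (tmp_path / "seg_rois.csv").read_text().startswith("roi_id")
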