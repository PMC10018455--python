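"""Bisecting k-means spatial segmentation and plaque ROI extraction.

Pixels are observations in a binned-spectrum feature space.  A binary tree is
grown by repeatedly 2-means-splitting the leaf with the largest within-
cluster sum of squares, the classic bisecting k-means used for MSI spatial
segmentation.  Plaque-like leaves -- those fragmenting into several small
connected components -- yield whole-plaque ROIs; a concentric subregion of
each (or its q-FTAA-positive core) is the plaque-center ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .msi_io import MSIDataset


@dataclass
class SegNode:
    """One node of the segmentation tree (pixel set in row order of X)."""

    node_id: int
    indices: np.ndarray  # observation indices in this cluster
    centroid: np.ndarray
    sse: float  # within-cluster sum of squares
    split_order: int | None = None  # None for leaves never split
    children: tuple[int, int] | None = None


@dataclass
class SegmentationTree:
    nodes: dict[int, SegNode] = field(default_factory=dict)
    root: int = 0

    @property
    def leaves(self) -> list[SegNode]:
        return [n for n in self.nodes.values() if n.children is None]

    def leaf_labels(self, n_obs: int) -> np.ndarray:
        """Per-observation leaf id; leaves must partition the observations."""
        labels = np.full(n_obs, -1, dtype=int)
        for leaf in self.leaves:
            if np.any(labels[leaf.indices] != -1):
                raise AssertionError("leaf pixel sets overlap")
            labels[leaf.indices] = leaf.node_id
        if np.any(labels == -1):
            raise AssertionError("leaves do not cover all observations")
        return labels

    def total_sse(self) -> float:
        return float(sum(n.sse for n in self.leaves))


@dataclass
class ROI:
    """A labeled pixel set on one dataset grid."""

    roi_id: str
    kind: str  # whole_plaque | plaque_center | background
    pixels: np.ndarray  # (n, 2) int (row, col)
    source_leaves: tuple[int, ...] = ()
    animal_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if self.kind not in ("whole_plaque", "plaque_center", "background"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if len(self.pixels) == 0:
            raise ValueError("ROI pixel set must be non-empty")

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


def build_feature_matrix(dataset: MSIDataset, channel_bin_width: float,
                         max_features: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate channels into contiguous m/z bins (sum within bin).

    Zero-variance features are dropped; if ``max_features`` is given, only
    the highest-variance features are kept.  Returns the pixels x features
    matrix and the bin-center m/z of each retained feature.  Requires a
    TIC-normalized dataset.
    """
    if not dataset.normalized:
        raise ValueError("dataset must be TIC-normalized before featurization")
    axis = dataset.mz_axis
    span = axis[-1] - axis[0]
    if channel_bin_width <= 0 or channel_bin_width > span:
        raise ValueError(
            f"bin width must lie in (0, {span:.1f}] Da for this axis")
    edges = np.arange(axis[0], axis[-1] + channel_bin_width, channel_bin_width)
    idx = np.searchsorted(axis, edges[1:-1], side="left")
    starts = np.concatenate([[0], idx])
    X = np.add.reduceat(dataset.intensities, starts, axis=1)
    centers = np.array([axis[s: e].mean() for s, e in
                        zip(starts, np.concatenate([starts[1:], [len(axis)]]))])
    var = X.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError(
            "all features have zero variance; use narrower bins")
    X, centers, var = X[:, keep], centers[keep], var[keep]
    if max_features is not None and X.shape[1] > max_features:
        order = np.argsort(var)[::-1][:max_features]
        order.sort()
        X, centers = X[:, order], centers[order]
    return np.ascontiguousarray(X, dtype=np.float64), centers


def _two_means(X: np.ndarray, indices: np.ndarray, seed: int,
               n_init: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-n_init 2-means on a subset; returns per-child indices, centroids."""
    from sklearn.cluster import KMeans

    sub = X[indices]
    # tiny clusters: more restarts so the split reaches the global minimum
    if len(sub) <= 32:
        n_init = max(n_init, 8 * len(sub))
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    assign = km.fit_predict(sub)
    left = indices[assign == 0]
    right = indices[assign == 1]
    return left, right, km.cluster_centers_[0], km.cluster_centers_[1]


def _node_sse(X: np.ndarray, indices: np.ndarray, centroid: np.ndarray) -> float:
    diff = X[indices] - centroid
    return float(np.einsum("ij,ij->", diff, diff))


def bisecting_kmeans(X: np.ndarray, n_leaves: int, seed: int = 0,
                     n_init: int = 10) -> SegmentationTree:
    """Hierarchical bisecting k-means segmentation tree.

    Iteratively splits the leaf with the largest within-cluster SSE by
    2-means (squared Euclidean, best of ``n_init`` restarts).  Deterministic
    for a fixed seed.  If no leaf can be split further (duplicate rows), the
    tree stops early with a warning and fewer leaves.
    """
    X = np.asarray(X, dtype=float)
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if X.shape[0] < n_leaves:
        raise ValueError("need at least n_leaves observations")

    all_idx = np.arange(X.shape[0])
    root = SegNode(0, all_idx, X.mean(axis=0), _node_sse(X, all_idx, X.mean(axis=0)))
    tree = SegmentationTree(nodes={0: root})
    next_id = 1
    rng = np.random.SeedSequence(seed)
    unsplittable: set[int] = set()

    for split_order in range(n_leaves - 1):
        candidates = [n for n in tree.leaves
                      if n.node_id not in unsplittable and len(n.indices) >= 2]
        candidates = [n for n in candidates
                      if len(np.unique(X[n.indices], axis=0)) >= 2]
        if not candidates:
            warnings.warn(
                f"stopping early with {len(tree.leaves)} leaves: no leaf "
                "contains two distinct points")
            break
        node = max(candidates, key=lambda n: n.sse)
        child_seed = int(rng.spawn(1)[0].generate_state(1)[0] % (2**31))
        left, right, c_left, c_right = _two_means(X, node.indices, child_seed,
                                                  n_init=n_init)
        if len(left) == 0 or len(right) == 0:
            unsplittable.add(node.node_id)
            continue
        node.children = (next_id, next_id + 1)
        node.split_order = split_order
        tree.nodes[next_id] = SegNode(next_id, left, c_left,
                                      _node_sse(X, left, c_left))
        tree.nodes[next_id + 1] = SegNode(next_id + 1, right, c_right,
                                          _node_sse(X, right, c_right))
        next_id += 2
        tree.leaf_labels(X.shape[0])  # partition invariant, asserted per split
    return tree


def leaf_component_stats(tree: SegmentationTree, pixel_coords: np.ndarray,
                         grid_shape: tuple[int, int]) -> dict[int, dict]:
    """Connected-component statistics (8-connectivity) per leaf."""
    stats = {}
    for leaf in tree.leaves:
        mask = np.zeros(grid_shape, dtype=bool)
        px = pixel_coords[leaf.indices]
        mask[px[:, 0], px[:, 1]] = True
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        stats[leaf.node_id] = {
            "n_pixels": int(len(leaf.indices)),
            "n_components": int(len(sizes)),
            "median_component_size": float(np.median(sizes)) if len(sizes) else 0.0,
        }
    return stats


def extract_plaque_rois(tree: SegmentationTree, pixel_coords: np.ndarray,
                        grid_shape: tuple[int, int],
                        selection: str | list[int] = "auto",
                        min_pixels: int = 4, *, animal_id: str = "",
                        genotype: str = "",
                        min_components: int = 3,
                        max_median_fraction: float = 0.05,
                        max_leaf_fraction: float = 0.10,
                        dilate: int = 0
                        ) -> tuple[list[ROI], dict]:
    """Whole-plaque ROIs from plaque-like segmentation leaves.

    In ``auto`` mode a leaf is plaque-like when its pixel set fragments into
    at least ``min_components`` 8-connected components whose median size is
    at least ``min_pixels`` (speckle-dominated leaves do not count) and
    below ``max_median_fraction`` of the grid, and the leaf itself covers at
    most ``max_leaf_fraction`` of the grid (anatomical background leaves are
    large).  Each 8-connected component of the union of selected leaves with
    >= ``min_pixels`` pixels becomes one whole-plaque ROI; everything else
    is background.  Returns the ROI list and per-leaf component diagnostics.
    """
    stats = leaf_component_stats(tree, pixel_coords, grid_shape)
    grid_px = grid_shape[0] * grid_shape[1]
    if selection == "auto":
        selected = [lid for lid, s in stats.items()
                    if s["n_components"] >= min_components
                    and (min_pixels <= s["median_component_size"]
                         < max_median_fraction * grid_px)
                    and s["n_pixels"] <= max_leaf_fraction * grid_px]
    else:
        leaf_ids = {n.node_id for n in tree.leaves}
        bad = set(selection) - leaf_ids
        if bad:
            raise ValueError(f"selection names non-leaf ids {sorted(bad)}")
        selected = list(selection)
        if len(leaf_ids) < 2:
            raise ValueError("tree has a single leaf: background only, no "
                             "plaque leaf to select")

    rois: list[ROI] = []
    if selected:
        mask = np.zeros(grid_shape, dtype=bool)
        for lid in selected:
            px = pixel_coords[tree.nodes[lid].indices]
            mask[px[:, 0], px[:, 1]] = True
        lab = cc_label(mask, connectivity=2)
        if dilate > 0:
            # capture the faint halo just outside each detected footprint;
            # expand_labels keeps neighbouring components from merging
            from skimage.segmentation import expand_labels
            lab = expand_labels(lab, distance=dilate)
        for comp in range(1, lab.max() + 1):
            pix = np.argwhere(lab == comp)
            if len(pix) < min_pixels:
                continue
            rois.append(ROI(roi_id=f"{animal_id}_p{len(rois) + 1}",
                            kind="whole_plaque", pixels=pix,
                            source_leaves=tuple(selected),
                            animal_id=animal_id, genotype=genotype))
    return rois, stats


def background_roi(rois: list[ROI], grid_shape: tuple[int, int],
                   margin: int = 3, *, animal_id: str = "",
                   genotype: str = "") -> ROI:
    """All pixels at least ``margin`` pixels away from every plaque ROI."""
    from scipy.ndimage import binary_dilation

    occupied = np.zeros(grid_shape, dtype=bool)
    for roi in rois:
        occupied |= roi.mask(grid_shape)
    if margin > 0:
        occupied = binary_dilation(occupied, iterations=margin)
    pix = np.argwhere(~occupied)
    return ROI(roi_id=f"{animal_id}_bg", kind="background", pixels=pix,
               animal_id=animal_id, genotype=genotype)


def derive_center_roi(whole: ROI, fraction: float = 0.5,
                      weights: np.ndarray | None = None) -> ROI:
    """Concentric plaque-center ROI.

    Pixels whose distance to the (optionally intensity-weighted) centroid is
    at most ``fraction`` times the equivalent radius (the radius of the
    circle with the ROI's area).  Never empty: the pixel nearest the centroid
    is always included.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    px = whole.pixels.astype(float)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = np.clip(w, 0, None)
        centroid = (px * w[:, None]).sum(axis=0) / w.sum() if w.sum() > 0 \
            else px.mean(axis=0)
    else:
        centroid = px.mean(axis=0)
    r_eq = np.sqrt(len(px) / np.pi)
    d = np.hypot(px[:, 0] - centroid[0], px[:, 1] - centroid[1])
    keep = d <= fraction * r_eq
    if not keep.any():
        keep = d == d.min()
    return ROI(roi_id=f"{whole.roi_id}_center", kind="plaque_center",
               pixels=whole.pixels[keep], source_leaves=whole.source_leaves,
               animal_id=whole.animal_id, genotype=whole.genotype)


def export_segmentation(tree: SegmentationTree, pixel_coords: np.ndarray,
                        grid_shape: tuple[int, int], rois: list[ROI],
                        prefix) -> None:
    """Write the leaf-label map (indexed PNG + label TIFF) and ROI sets
    (JSON pixel lists + BED-like CSV of roi_id, row, col)."""
    import json
    from pathlib import Path

    import tifffile
    from matplotlib import cm
    from PIL import Image

    prefix = Path(prefix)
    labels = tree.leaf_labels(len(pixel_coords))
    label_img = np.zeros(grid_shape, dtype=np.int32)
    label_img[pixel_coords[:, 0], pixel_coords[:, 1]] = labels
    tifffile.imwrite(f"{prefix}_labels.tiff", label_img)
    dense = np.unique(label_img, return_inverse=True)[1].reshape(grid_shape)
    img = Image.fromarray(dense.astype(np.uint8), mode="P")
    palette = (cm.tab20(np.linspace(0, 1, 20))[:, :3] * 255).astype(np.uint8)
    img.putpalette(palette.ravel().tolist())
    img.save(f"{prefix}_segmentation.png")
    json_payload = {r.roi_id: r.pixels.tolist() for r in rois}
    Path(f"{prefix}_rois.json").write_text(json.dumps(json_payload))
    with open(f"{prefix}_rois.csv", "w") as fh:
        fh.write("roi_id,row,col\n")
        for r in rois:
            for row, col in r.pixels:
                fh.write(f"{r.roi_id},{row},{col}\n")


def center_from_core_mask(whole: ROI, core_mask: np.ndarray) -> ROI:
    """Plaque-center ROI as the intersection with a q-FTAA core mask; falls
    back to the geometric center when the intersection is empty."""
    keep = core_mask[whole.pixels[:, 0], whole.pixels[:, 1]]
    if not keep.any():
        return derive_center_roi(whole, 0.5)
    return ROI(roi_id=f"{whole.roi_id}_center", kind="plaque_center",
               pixels=whole.pixels[keep], source_leaves=whole.source_leaves,
               animal_id=whole.animal_id, genotype=whole.genotype)
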