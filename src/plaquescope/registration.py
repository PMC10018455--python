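"""Landmark-based registration of fluorescence microscopy onto the MSI grid,
LCO thresholding and mask overlap scoring.

All four modalities come from one physical section, so only affine scan-
geometry differences need correcting; a least-squares affine fitted to
landmark pairs is deterministic and exactly testable.  Masks derived from the
two LCO channels (h-FTAA: all amyloid; q-FTAA: mature cores) validate
MSI-segmentation features and can define plaque-center ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class AffineTransform:
    """2-D affine mapping source (x, y) to target coordinates.

    ``matrix`` is the 2x3 row-major matrix [[a, b, tx], [c, d, ty]]:
    target = A @ source + t.
    """

    matrix: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        a = self.linear
        if abs(np.linalg.det(a)) < 1e-12:
            raise ValueError("singular transform has no inverse")
        inv = np.linalg.inv(a)
        return AffineTransform(np.hstack([inv, -(inv @ self.translation)[:, None]]))

    def to_json(self) -> list[float]:
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_json(cls, values) -> "AffineTransform":
        return cls(np.asarray(values, dtype=float).reshape(2, 3))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def affine_from_landmarks(pairs) -> tuple[AffineTransform, float]:
    """Least-squares affine from ``[(source_xy, target_xy), ...]`` pairs.

    Returns the transform and the RMS of the residuals.  Requires at least
    three non-collinear source points.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {len(pairs)}")
    src = np.asarray([p[0] for p in pairs], dtype=float)
    dst = np.asarray([p[1] for p in pairs], dtype=float)
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmark source points are collinear (degenerate fit)")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    transform = AffineTransform(coef.T)
    residuals = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, rms


def resample_to_grid(image, transform: AffineTransform,
                     grid_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Resample each fluorescence channel onto the MSI grid.

    ``transform`` maps fluorescence (x, y) to MSI (x, y) = (col, row).
    Bilinear interpolation; pixels mapping outside the source field of view
    are NaN (missing), not zero.
    """
    inv = transform.inverse()  # MSI -> fluorescence
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    msi_xy = np.stack([cc.ravel(), rr.ravel()], axis=1)
    src_xy = inv.apply(msi_xy)
    # map_coordinates wants (row, col) = (y, x)
    coords = np.stack([src_xy[:, 1], src_xy[:, 0]])
    out = {}
    for name, channel in image.channels.items():
        vals = ndimage.map_coordinates(np.asarray(channel, dtype=float), coords,
                                       order=1, mode="constant", cval=np.nan)
        out[name] = vals.reshape(rows, cols)
    return out


def lco_masks(channels: dict[str, np.ndarray], method: str = "otsu",
              threshold: float | dict[str, float] | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (amyloid-positive, core-positive) masks from LCO channels.

    Amyloid-positive = h-FTAA above threshold; core-positive = q-FTAA above
    threshold.  ``core subset of amyloid`` is reported, not enforced.
    """
    if not channels or any(c.size == 0 for c in channels.values()):
        raise ValueError("channels must be non-empty")
    h = np.asarray(channels["hFTAA"], dtype=float)
    q = np.asarray(channels["qFTAA"], dtype=float)

    def thresh(img: np.ndarray, name: str) -> float:
        if method == "fixed":
            if threshold is None:
                raise ValueError("fixed method needs a threshold")
            return threshold[name] if isinstance(threshold, dict) else float(threshold)
        if method == "otsu":
            from skimage.filters import threshold_otsu
            finite = img[np.isfinite(img)]
            if finite.min() == finite.max():
                raise ValueError(
                    f"channel {name!r} is constant; Otsu is undefined -- "
                    "use method='fixed' with an explicit threshold")
            return float(threshold_otsu(finite))
        raise ValueError(f"unknown method {method!r}")

    amyloid = np.where(np.isfinite(h), h, -np.inf) > thresh(h, "hFTAA")
    core = np.where(np.isfinite(q), q, -np.inf) > thresh(q, "qFTAA")
    if np.any(core & ~amyloid):
        warnings.warn("core-positive pixels outside the amyloid-positive mask")
    return amyloid, core


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); two empty masks give 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        warnings.warn("both masks empty; Dice defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / total
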