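"""Seven-metric evaluation of binary mask pairs, distances in millimetres.

Region measures (Dice, Jaccard, false-positive/false-negative Dice) are
exact pixel-count arithmetic; contour measures (Hausdorff, directed and
symmetric mean absolute distance) use Euclidean nearest-point distances
between boundary-pixel centers scaled by the pixel spacing.

Identities that hold exactly: ``fpd + fnd + 2*dice == 2`` and
``jaccard == dice / (2 - dice)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ContourPointSet",
    "PairMetrics",
    "extract_contour",
    "region_metrics",
    "distance_metrics",
    "evaluate_pair",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dice", "jaccard", "hausdorff_mm", "mad_xy_mm", "mad_yx_mm", "smad_mm", "fpd", "fnd")


@dataclass(frozen=True)
class ContourPointSet:
    """Boundary-pixel centers of a mask, in mm, row-major order."""

    points: np.ndarray  # (n, 2) float, mm
    source_shape: tuple
    n: int


@dataclass(frozen=True)
class PairMetrics:
    dice: float
    jaccard: float
    hausdorff_mm: float
    mad_xy_mm: float
    mad_yx_mm: float
    smad_mm: float
    fpd: float
    fnd: float

    def as_dict(self):
        return asdict(self)


def _as_grid_spacing(m, spacing):
    if hasattr(m, "grid"):
        return np.asarray(m.grid).astype(bool), float(getattr(m, "spacing", spacing))
    return np.asarray(m).astype(bool), float(spacing)


def extract_contour(m, spacing=1.0) -> ContourPointSet:
    """Boundary point set of a mask.

    A foreground pixel is a boundary pixel if at least one 4-neighbor is
    background or it lies on the image border; its center coordinate
    (row, col) scaled by ``spacing`` contributes one point.
    """
    grid, sp = _as_grid_spacing(m, spacing)
    if not grid.any():
        raise ValueError("empty contour: mask has no foreground")
    interior = np.zeros_like(grid)
    interior[1:-1, 1:-1] = (
        grid[1:-1, 1:-1] & grid[:-2, 1:-1] & grid[2:, 1:-1] & grid[1:-1, :-2] & grid[1:-1, 2:]
    )
    boundary = grid & ~interior
    rr, cc = np.nonzero(boundary)
    pts = np.stack([rr, cc], axis=1).astype(float) * sp
    return ContourPointSet(pts, grid.shape, len(pts))


def region_metrics(a, b, spacing=1.0):
    """(dice, jaccard, fpd, fnd) from exact pixel-count arithmetic.

    Both-empty masks return (1, 1, 0, 0) by documented convention.
    """
    A, _ = _as_grid_spacing(a, spacing)
    B, _ = _as_grid_spacing(b, spacing)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na == 0 and nb == 0:
        logger.warning("region_metrics: both masks empty; returning perfect agreement")
        return 1.0, 1.0, 0.0, 0.0
    inter = int((A & B).sum())
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    jac = inter / union
    fpd = 2.0 * (na - inter) / (na + nb)  # |A ∩ ~B|
    fnd = 2.0 * (nb - inter) / (na + nb)  # |~A ∩ B|
    return dice, jac, fpd, fnd


def distance_metrics(X: ContourPointSet, Y: ContourPointSet):
    """(hausdorff, mad_xy, mad_yx, smad) in mm between two contours."""
    if X.n == 0 or Y.n == 0:
        raise ValueError("distance metrics undefined for an empty point set")
    dxy = cKDTree(Y.points).query(X.points)[0]  # d(x, Y) for each x
    dyx = cKDTree(X.points).query(Y.points)[0]
    hausdorff = max(float(dxy.max()), float(dyx.max()))
    mad_xy = float(dxy.mean())
    mad_yx = float(dyx.mean())
    smad = float((dxy.sum() + dyx.sum()) / (X.n + Y.n))
    return hausdorff, mad_xy, mad_yx, smad


def evaluate_pair(auto, manual, spacing=1.0) -> PairMetrics:
    """Full seven-metric record for a mask pair (auto = X/A, manual = Y/B)."""
    A, sp_a = _as_grid_spacing(auto, spacing)
    B, sp_b = _as_grid_spacing(manual, spacing)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if abs(sp_a - sp_b) > 1e-12:
        raise ValueError(f"spacing mismatch: {sp_a} vs {sp_b}")
    dice, jac, fpd, fnd = region_metrics(A, B)
    h, mad_xy, mad_yx, smad = distance_metrics(
        extract_contour(A, sp_a), extract_contour(B, sp_a)
    )
    return PairMetrics(dice, jac, h, mad_xy, mad_yx, smad, fpd, fnd)
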