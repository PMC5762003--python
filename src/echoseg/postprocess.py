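"""Morphological cleanup of probability maps into final binary masks.

Pipeline: threshold, flood-fill holes (background not reachable from the
image border, 4-connectivity), then keep the largest 8-connected
component.  The composition is idempotent and its output always has at
most one component and no holes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationMask",
    "binarize",
    "fill_holes",
    "keep_largest",
    "postprocess_probmap",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for components
_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity for holes


@dataclass
class SegmentationMask:
    grid: np.ndarray  # (H, W) bool
    spacing: float = 1.0  # mm / pixel
    provenance: str = "automatic"  # or "operator"

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)


def _as_grid(m):
    return m.grid if isinstance(m, SegmentationMask) else np.asarray(m).astype(bool)


def _like(m, grid):
    if isinstance(m, SegmentationMask):
        return SegmentationMask(grid, m.spacing, m.provenance)
    return grid


def binarize(p, threshold=0.5, spacing=1.0):
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    arr = p.grid if hasattr(p, "grid") else np.asarray(p)
    sp = getattr(p, "spacing", spacing)
    return SegmentationMask(arr >= threshold, sp, "automatic")


def fill_holes(m):
    """Foreground-fill background pixels unreachable from the image border.

    Reachability through background uses 4-connectivity; foreground is
    never removed, so the operation is monotone (only adds pixels).
    Cavities open to the border are left unfilled.
    """
    grid = _as_grid(m)
    return _like(m, ndimage.binary_fill_holes(grid, structure=_STRUCT4))


def keep_largest(m):
    """Retain only the largest 8-connected component.

    Empty input stays empty.  On an exact area tie the component containing
    the first foreground pixel in row-major scan order wins.
    """
    grid = _as_grid(m)
    labels, n = ndimage.label(grid, structure=_STRUCT8)
    if n <= 1:
        return _like(m, grid.copy())
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    # scipy labels components in row-major discovery order, so among ties
    # the smallest label is the first one encountered in scan order
    winner = 1 + int(np.flatnonzero(counts == best)[0])
    return _like(m, labels == winner)


def postprocess_probmap(p, threshold=0.5, spacing=1.0):
    """binarize -> fill_holes -> keep_largest; idempotent on its output."""
    mask = binarize(p, threshold, spacing)
    if not mask.grid.any():
        logger.warning("postprocess_probmap: all-background probability map")
        return mask
    return keep_largest(fill_holes(mask))
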