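"""Frame standardization, resizing, affine augmentation and mini-batching.

Coordinate convention: row-major grids, origin at the top-left pixel
center, 0-based indices.  Odd crop/pad remainders put the extra row/column
on the bottom/right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FRAME_SHAPE",
    "TRAIN_SHAPE",
    "FramePlacement",
    "standardize_frame",
    "unstandardize_frame",
    "resize_pair",
    "AffineRanges",
    "random_affine",
    "MiniBatch",
    "make_minibatches",
]

#: Standardized frame size (rows, cols) used before training/inference.
FRAME_SHAPE = (214, 262)
#: Network input size: the standardized frame linearly resized by 1/2.
TRAIN_SHAPE = (107, 131)


@dataclass(frozen=True)
class FramePlacement:
    """Record of the crop/pad applied by :func:`standardize_frame`.

    ``crop`` is the (row, col) offset of the crop window in the original
    grid (0 if the axis was padded); ``pad`` is the (row, col) offset of
    the original content inside the output (0 if the axis was cropped).
    """

    in_shape: tuple
    out_shape: tuple
    crop: tuple
    pad: tuple


def _split(delta: int) -> tuple[int, int]:
    """Split a size difference into (before, after) with the extra after."""
    return delta // 2, delta - delta // 2


def standardize_frame(grid, target_shape=FRAME_SHAPE, kind="image"):
    """Center-crop or symmetric zero-pad a 2-D grid to ``target_shape``.

    Returns ``(out, placement)``; the placement allows exact inverse
    mapping via :func:`unstandardize_frame`.  Masks stay binary (no
    interpolation is involved).
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {grid.shape}")
    H, W = grid.shape
    TH, TW = target_shape
    crop = [0, 0]
    pad = [0, 0]
    out = grid
    # rows
    if H > TH:
        b, _ = _split(H - TH)
        crop[0] = b
        out = out[b : b + TH, :]
    if W > TW:
        b, _ = _split(W - TW)
        crop[1] = b
        out = out[:, b : b + TW]
    h, w = out.shape
    pb_r, pa_r = _split(TH - h)
    pb_c, pa_c = _split(TW - w)
    if TH - h or TW - w:
        out = np.pad(out, ((pb_r, pa_r), (pb_c, pa_c)))
        pad = [pb_r, pb_c]
    placement = FramePlacement((H, W), (TH, TW), tuple(crop), tuple(pad))
    if kind == "mask":
        out = out.astype(bool)
    return out, placement


def unstandardize_frame(grid, placement: FramePlacement):
    """Map a standardized grid back to the original frame.

    Padded margins are stripped; regions removed by cropping are restored
    as zeros (their content is unknowable).
    """
    grid = np.asarray(grid)
    if grid.shape != tuple(placement.out_shape):
        raise ValueError(f"grid shape {grid.shape} != placement out_shape {placement.out_shape}")
    H, W = placement.in_shape
    TH, TW = placement.out_shape
    pr, pc = placement.pad
    inner = grid[pr : pr + min(H, TH), pc : pc + min(W, TW)]
    out = np.zeros((H, W), dtype=grid.dtype)
    cr, cc = placement.crop
    out[cr : cr + inner.shape[0], cc : cc + inner.shape[1]] = inner
    return out


def resize_pair(image, mask, target_shape=TRAIN_SHAPE, spacing=None):
    """Resize an image (bilinear) and its mask (nearest neighbor).

    The mask stays strictly binary.  If ``spacing`` is given, returns the
    rescaled spacing as a third element (per-axis mean size ratio).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    TH, TW = target_shape
    if TH <= 0 or TW <= 0:
        raise ValueError(f"target shape must be positive, got {target_shape}")
    H, W = image.shape
    if (H, W) == (TH, TW):
        out_im, out_mk = image.copy(), mask.astype(bool)
    else:
        # map output pixel centers into input index space
        ri = (np.arange(TH) + 0.5) * H / TH - 0.5
        ci = (np.arange(TW) + 0.5) * W / TW - 0.5
        rg, cg = np.meshgrid(ri, ci, indexing="ij")
        coords = np.stack([rg, cg])
        out_im = ndimage.map_coordinates(image.astype(np.float64), coords, order=1, mode="nearest")
        out_mk = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="nearest").astype(bool)
    if spacing is None:
        return out_im, out_mk
    new_spacing = spacing * 0.5 * (H / TH + W / TW)
    return out_im, out_mk, new_spacing


@dataclass(frozen=True)
class AffineRanges:
    """Uniform sampling ranges for the 6-DOF affine augmentation."""

    rotation_deg: tuple = (-10.0, 10.0)
    translation_frac: tuple = (-0.05, 0.05)  # of frame size, per axis
    scale: tuple = (0.9, 1.1)  # per axis
    shear_deg: tuple = (-5.0, 5.0)

    @classmethod
    def identity(cls):
        return cls((0.0, 0.0), (0.0, 0.0), (1.0, 1.0), (0.0, 0.0))


def random_affine(image, mask, ranges: AffineRanges = AffineRanges(), seed: int = 0):
    """Apply one random 6-DOF affine to an image/mask pair about the center.

    Degrees of freedom: rotation, two translations, two per-axis scales and
    a shear, each sampled uniformly from ``ranges``.  Image is bilinear,
    mask nearest neighbor; out-of-frame pixels are filled with 0.
    Deterministic per seed.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    rng = np.random.default_rng(seed)
    rot = np.deg2rad(rng.uniform(*ranges.rotation_deg))
    ty = rng.uniform(*ranges.translation_frac) * image.shape[0]
    tx = rng.uniform(*ranges.translation_frac) * image.shape[1]
    sy = rng.uniform(*ranges.scale)
    sx = rng.uniform(*ranges.scale)
    shear = np.deg2rad(rng.uniform(*ranges.shear_deg))
    if sy <= 0 or sx <= 0:
        raise ValueError(f"singular transform: scales must be > 0, got ({sy}, {sx})")

    c, s = np.cos(rot), np.sin(rot)
    rotm = np.array([[c, -s], [s, c]])
    shearm = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    scalem = np.diag([sy, sx])
    A = rotm @ shearm @ scalem  # output <- input direction
    center = (np.array(image.shape) - 1) / 2.0
    Ainv = np.linalg.inv(A)
    # forward map: y = A (x - center) + center + t  => x = Ainv (y - center - t) + center
    offset = center - Ainv @ (center + np.array([ty, tx]))
    out_im = ndimage.affine_transform(
        image.astype(np.float64), Ainv, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_mk = ndimage.affine_transform(
        mask.astype(np.uint8), Ainv, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)
    return out_im, out_mk


@dataclass
class MiniBatch:
    """Aligned stacks of images and binary labels with provenance ids."""

    images: np.ndarray  # (B, H, W)
    labels: np.ndarray  # (B, H, W) bool
    sample_ids: list  # [(image_id, operator_index), ...]


def expand_pool(dataset):
    """One training sample per (image, operator) pair."""
    pool = []
    for img in dataset:
        if not img.operator_masks:
            raise ValueError(f"image {img.image_id!r} has no operator masks")
        for k in range(len(img.operator_masks)):
            pool.append((img, k))
    return pool


def make_minibatches(dataset, batch_size=32, seed=0, epochs=1, sample_per_image=False):
    """Yield shuffled mini-batches of (image, operator-label) samples.

    The training pool holds one sample per (image, operator) pair (so 3
    samples per image with 3 operators) and is reshuffled each epoch with
    a seeded RNG; every sample appears exactly once per epoch.  With
    ``sample_per_image=True`` the pool instead holds one sample per image
    with a random operator drawn per epoch (documented alternative).
    """
    if not dataset:
        raise ValueError("empty dataset")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        if sample_per_image:
            pool = [(img, int(rng.integers(len(img.operator_masks)))) for img in dataset]
        else:
            pool = expand_pool(dataset)
        order = rng.permutation(len(pool))
        for start in range(0, len(pool), batch_size):
            idx = order[start : start + batch_size]
            imgs = np.stack([np.asarray(pool[i][0].image, dtype=np.float32) for i in idx])
            labs = np.stack([np.asarray(pool[i][0].operator_masks[pool[i][1]], dtype=bool) for i in idx])
            ids = [(pool[i][0].image_id, pool[i][1]) for i in idx]
            yield MiniBatch(imgs, labs, ids)
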