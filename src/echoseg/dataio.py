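"""Readers/writers: PNG + JSON sidecar (primary), minimal MetaImage, CSV.

Images are stored as 8- or 16-bit grayscale PNG with a JSON sidecar
``<name>.json`` holding ``{"spacing_mm": ..., "patient_id": ...,
"stage": ...}``; masks as single-channel PNG with values {0, 255}.
MetaImage (.mha, uncompressed, 2-D) is supported as a spacing-carrying
single-file alternative.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_dataset",
    "read_manifest",
    "write_results",
]

logger = logging.getLogger(__name__)

# ITU-R 601 luminance weights for RGB inputs
_RGB_WEIGHTS = np.array([0.299, 0.587, 0.114])

_MHA_TYPES = {"MET_UCHAR": np.uint8, "MET_USHORT": np.uint16, "MET_FLOAT": np.float32}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_mha(path: Path):
    header = {}
    with open(path, "rb") as f:
        while True:
            line = f.readline().decode("ascii").strip()
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementDataFile") != "LOCAL":
            raise ValueError("only LOCAL-data .mha files are supported")
        if header.get("CompressedData", "False").lower() == "true":
            raise ValueError("compressed .mha is not supported")
        dtype = _MHA_TYPES.get(header.get("ElementType"))
        if dtype is None:
            raise ValueError(f"unsupported ElementType {header.get('ElementType')!r}")
        dims = [int(v) for v in header["DimSize"].split()]
        if len(dims) != 2:
            raise ValueError(f"expected 2-D data, got DimSize {dims}")
        data = np.frombuffer(f.read(), dtype=dtype).reshape(dims[1], dims[0])
    spacing = 1.0
    if "ElementSpacing" in header:
        spacing = float(header["ElementSpacing"].split()[0])
    return data, spacing


def _write_mha(path: Path, grid: np.ndarray, spacing: float):
    if grid.dtype == np.bool_:
        grid = grid.astype(np.uint8) * 255
    type_name = {np.dtype(v): k for k, v in _MHA_TYPES.items()}.get(grid.dtype)
    if type_name is None:
        grid = grid.astype(np.float32)
        type_name = "MET_FLOAT"
    H, W = grid.shape
    header = (
        "ObjectType = Image\nNDims = 2\nBinaryData = True\n"
        "BinaryDataByteOrderMSB = False\nCompressedData = False\n"
        f"ElementSpacing = {spacing} {spacing}\nDimSize = {W} {H}\n"
        f"ElementType = {type_name}\nElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        f.write(np.ascontiguousarray(grid).tobytes())


def read_image(path):
    """Read a grayscale image and its pixel spacing.

    Returns ``(grid, spacing_mm)`` with intensities min-max normalized to
    [0, 1].  Spacing comes from the JSON sidecar or MetaImage header;
    missing spacing defaults to 1.0 mm with a warning.  RGB inputs are
    converted to luminance with a warning.
    """
    path = Path(path)
    if path.suffix == ".mha":
        data, spacing = _read_mha(path)
    else:
        data = iio.imread(path)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            spacing = float(json.loads(sidecar.read_text()).get("spacing_mm", 1.0))
        else:
            logger.warning("no spacing sidecar for %s; assuming 1.0 mm", path.name)
            spacing = 1.0
    if data.ndim == 3:
        if data.shape[2] == 4:
            data = data[:, :, :3]
        logger.warning("%s has %d channels; converting to luminance", path.name, data.shape[2])
        data = data @ _RGB_WEIGHTS
    if data.ndim != 2:
        raise ValueError(f"{path}: expected 2-D image data, got shape {data.shape}")
    data = data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi > lo:
        data = (data - lo) / (hi - lo)
    else:
        data = np.zeros_like(data)
    return data, spacing


def write_image(path, grid, spacing=1.0, patient_id="", stage="", bits=16):
    """Write a [0,1] image as PNG (8/16-bit) or .mha, plus sidecar for PNG."""
    path = Path(path)
    grid = np.asarray(grid, dtype=np.float64)
    if path.suffix == ".mha":
        _write_mha(path, grid.astype(np.float32), spacing)
        return
    if bits == 8:
        enc = np.clip(np.round(grid * 255), 0, 255).astype(np.uint8)
    else:
        enc = np.clip(np.round(grid * 65535), 0, 65535).astype(np.uint16)
    iio.imwrite(path, enc)
    _sidecar_path(path).write_text(
        json.dumps({"spacing_mm": spacing, "patient_id": patient_id, "stage": stage})
    )


def read_mask(path):
    """Read a binary mask PNG/.mha; returns ``(bool grid, spacing_mm)``."""
    grid, spacing = read_image(path)
    return grid >= 0.5, spacing


def write_mask(path, grid, spacing=1.0, **meta):
    """Write a binary mask as a {0, 255} single-channel PNG (or .mha)."""
    path = Path(path)
    grid = np.asarray(grid).astype(bool)
    if path.suffix == ".mha":
        _write_mha(path, grid, spacing)
        return
    iio.imwrite(path, grid.astype(np.uint8) * 255)
    _sidecar_path(path).write_text(json.dumps({"spacing_mm": spacing, **meta}))


def write_dataset(images, manifest: pd.DataFrame, out_dir):
    """Write a phantom dataset: images/, masks, and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "images").mkdir(exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    rows = []
    for img in images:
        ipath = out_dir / "images" / f"{img.image_id}.png"
        write_image(ipath, img.image, img.spacing, img.patient_id, img.stage)
        mpaths = []
        tpath = out_dir / "masks" / f"{img.image_id}_true.png"
        write_mask(tpath, img.true_mask, img.spacing)
        for k, om in enumerate(img.operator_masks):
            mp = out_dir / "masks" / f"{img.image_id}_op{k}.png"
            write_mask(mp, om, img.spacing)
            mpaths.append(str(mp.relative_to(out_dir)))
        rows.append(
            dict(
                patient_id=img.patient_id,
                image_id=img.image_id,
                stage=img.stage,
                spacing_mm=img.spacing,
                image_path=str(ipath.relative_to(out_dir)),
                true_mask_path=str(tpath.relative_to(out_dir)),
                operator_mask_paths=";".join(mpaths),
            )
        )
    mf = pd.DataFrame(rows)
    mf.to_csv(out_dir / "manifest.csv", index=False)
    return mf


def read_manifest(manifest_path):
    """Load a dataset written by :func:`write_dataset` back into memory."""
    from .phantom import AnnotatedImage

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    mf = pd.read_csv(manifest_path)
    images = []
    for _, row in mf.iterrows():
        grid, spacing = read_image(root / row["image_path"])
        true_mask, _ = read_mask(root / row["true_mask_path"])
        ops = []
        if isinstance(row.get("operator_mask_paths"), str) and row["operator_mask_paths"]:
            for p in row["operator_mask_paths"].split(";"):
                om, _ = read_mask(root / p)
                ops.append(om)
        images.append(
            AnnotatedImage(
                patient_id=str(row["patient_id"]),
                image_id=str(row["image_id"]),
                stage=str(row["stage"]),
                image=grid.astype(np.float32),
                spacing=float(row["spacing_mm"]),
                true_mask=true_mask,
                operator_masks=ops,
            )
        )
    return images, mf


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(out_dir, tables=None, masks=None, traces=None, checkpoints=None):
    """Write run outputs in a deterministic layout and return a manifest.

    Layout: ``masks/`` (PNG+sidecar), ``metrics.csv``/``agreement.json``
    (tables), ``loss_traces/`` (CSV), ``checkpoints/``.  The manifest lists
    every artifact with its SHA-256 content hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _record(p: Path):
        written.append({"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)})

    if masks:
        mdir = out_dir / "masks"
        mdir.mkdir(exist_ok=True)
        for image_id, mask in sorted(masks.items() if isinstance(masks, dict) else masks):
            grid = mask.grid if hasattr(mask, "grid") else mask
            sp = getattr(mask, "spacing", 1.0)
            p = mdir / f"{image_id}.png"
            write_mask(p, grid, sp, image_id=image_id)
            _record(p)
            _record(p.with_suffix(".json"))
    if tables:
        for name, tab in sorted(tables.items()):
            if isinstance(tab, pd.DataFrame):
                p = out_dir / f"{name}.csv"
                tab.to_csv(p, index=False)
            else:
                p = out_dir / f"{name}.json"
                p.write_text(json.dumps(tab, indent=2, sort_keys=True, default=float))
            _record(p)
    if traces:
        tdir = out_dir / "loss_traces"
        tdir.mkdir(exist_ok=True)
        for name, trace in sorted(traces.items()):
            p = tdir / f"{name}.csv"
            pd.DataFrame(trace).to_csv(p, index=False)
            _record(p)
    if checkpoints:
        from .network import save_checkpoint

        cdir = out_dir / "checkpoints"
        cdir.mkdir(exist_ok=True)
        for name, model in sorted(checkpoints.items()):
            p = cdir / f"{name}.npz"
            save_checkpoint(model, p)
            _record(p)
    manifest = pd.DataFrame(written, columns=["path", "sha256"])
    manifest.to_csv(out_dir / "run_manifest.csv", index=False)
    return manifest
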