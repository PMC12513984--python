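"""Image and sidecar I/O.

En-face pairs are stored as two single-channel 16-bit TIFFs plus a JSON
sidecar carrying the device metadata; binary deficit masks as 8-bit TIFFs
(0 = flow, 255 = deficit).  Intensities are normalized at load time by the
dtype maximum (65535 for 16-bit, 255 for 8-bit) — never by per-image
min/max, which would silently change the behaviour of the intensity-scale
sensitive Phansalkar threshold.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .binarize import FDMask
from .synthetic import EnFacePair

__all__ = [
    "load_image",
    "save_image_16bit",
    "save_enface_pair",
    "load_enface_pair",
    "save_mask",
    "load_mask",
]


def load_image(path) -> np.ndarray:
    """Load a grayscale raster and normalize it to [0, 1] by dtype maximum."""
    arr = tifffile.imread(str(path)) if str(path).lower().endswith(
        (".tif", ".tiff")
    ) else np.asarray(_load_pil(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError(f"{path}: float image must already be in [0, 1]")
    return arr


def _load_pil(path):
    from PIL import Image

    return Image.open(path).convert("I;16")


def save_image_16bit(img: np.ndarray, path) -> None:
    """Save a [0, 1] image as a 16-bit single-channel TIFF."""
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must be in [0, 1]")
    tifffile.imwrite(str(path), np.round(img * 65535).astype(np.uint16))


def save_enface_pair(pair: EnFacePair, out_dir, stem: str = "enface") -> dict:
    """Write flow/structural TIFFs plus a JSON sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "flow": out / f"{stem}_flow.tif",
        "structural": out / f"{stem}_structural.tif",
        "sidecar": out / f"{stem}_meta.json",
    }
    save_image_16bit(pair.flow, paths["flow"])
    save_image_16bit(pair.structural, paths["structural"])
    meta = dict(pair.meta)
    meta.setdefault("device", pair.device_name)
    meta.setdefault("pixel_size_um", pair.pixel_size_um)
    meta.setdefault("grid_px", pair.flow.shape[0])
    paths["sidecar"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def load_enface_pair(out_dir, stem: str = "enface") -> EnFacePair:
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}_meta.json").read_text())
    flow = load_image(out / f"{stem}_flow.tif")
    structural = load_image(out / f"{stem}_structural.tif")
    return EnFacePair(
        flow,
        structural,
        float(meta["pixel_size_um"]),
        device_name=str(meta.get("device", "")),
        meta=meta,
    )


def save_mask(mask: FDMask, path) -> None:
    """Write a deficit mask as 8-bit TIFF (0 = flow, 255 = deficit) + sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), np.where(mask.mask, 255, 0).astype(np.uint8))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"pixel_size_um": mask.pixel_size_um, "provenance": mask.provenance},
        indent=2, sort_keys=True, default=str,
    ))


def load_mask(path) -> FDMask:
    path = Path(path)
    arr = tifffile.imread(str(path))
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FDMask(
        arr > 0,
        float(meta.get("pixel_size_um", 1.0)),
        dict(meta.get("provenance", {})),
    )
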