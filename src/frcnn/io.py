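"""PNG dataset layout and image helpers for the command-line tools.

Datasets on disk are per-class folders of 8-bit PNGs plus a
``manifest.csv`` with columns ``filename,label``; loaders return pixel
values normalized to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .layers import TensorBatch
from .synth import CLASS_NAMES, normalize_pixels

__all__ = ["save_dataset", "load_dataset", "load_png", "save_png",
           "overlay_contour"]


def save_png(path, image: np.ndarray) -> None:
    """Write an [0,1]-scaled (H,W) or (H,W,C) array as an 8-bit PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_png(path, channels: int | None = None) -> np.ndarray:
    """Read a PNG into an (H,W,C) float array scaled to [0, 1]."""
    arr = np.asarray(Image.open(path), dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if channels is not None and arr.shape[2] != channels:
        if arr.shape[2] == 1:
            arr = np.repeat(arr, channels, axis=2)
        else:
            arr = arr[:, :, :channels]
    return arr


def save_dataset(batch: TensorBatch, out_dir) -> Path:
    """Write per-class PNG folders plus a filename,label manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {}
    for i in range(batch.n):
        label = int(batch.labels[i])
        name = CLASS_NAMES[label] if label < len(CLASS_NAMES) else str(label)
        (out / name).mkdir(exist_ok=True)
        counters[label] = counters.get(label, 0) + 1
        fname = f"{name}/{name}_{counters[label]:05d}.png"
        save_png(out / fname, batch.values[i])
        rows.append({"filename": fname, "label": label})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def load_dataset(data_dir) -> TensorBatch:
    """Read a manifest-described PNG dataset back into a TensorBatch."""
    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.csv")
    images = [load_png(data / row.filename) for row in manifest.itertuples()]
    batch = TensorBatch(np.stack(images),
                        manifest["label"].to_numpy(dtype=np.int64))
    return normalize_pixels(batch)


def overlay_contour(image: np.ndarray, mask: np.ndarray,
                    color=(1.0, 0.2, 0.2)) -> np.ndarray:
    """RGB copy of the image with the mask boundary drawn in ``color``."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    mask = np.asarray(mask, dtype=bool)
    interior = mask.copy()
    interior[1:-1, 1:-1] = (mask[1:-1, 1:-1] & mask[:-2, 1:-1] & mask[2:, 1:-1]
                            & mask[1:-1, :-2] & mask[1:-1, 2:])
    boundary = mask & ~interior
    out = img.copy()
    out[boundary] = color
    return out
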