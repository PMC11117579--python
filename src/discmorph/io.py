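"""Readers and writers for images, contours and masks.

Images: 8/16-bit PNG or JPEG (via Pillow) and DICOM (via pydicom, reading
PixelSpacing when present).  Contours: JSON ``{"vertices": [[row, col],
...]}`` or two-column CSV.  Masks are written as 0/255 PNG.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .preprocess import GrayImage, normalize_intensity

__all__ = [
    "load_image",
    "save_mask_png",
    "load_mask_png",
    "load_contour",
    "save_contour",
]


def load_image(path: str | Path, spacing_mm: Optional[Tuple[float, float]] = None) -> GrayImage:
    """Load a grayscale image, normalized to [0, 1].

    DICOM files (suffix .dcm, or files pydicom can parse) supply their own
    PixelSpacing unless one is passed explicitly.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        if spacing_mm is None and getattr(ds, "PixelSpacing", None) is not None:
            spacing_mm = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    else:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("I" if im.mode in ("I", "I;16") else "L"), dtype=float)
    return normalize_intensity(arr, spacing_mm)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    img.save(Path(path))


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG back into a boolean mask."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L")) > 127


def load_contour(path: str | Path) -> np.ndarray:
    """Load an ordered (row, col) vertex list from JSON or 2-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        verts = np.asarray(data["vertices"], dtype=float)
    else:
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r]
        if rows and not _is_number(rows[0][0]):
            rows = rows[1:]  # header
        verts = np.asarray([[float(r[0]), float(r[1])] for r in rows])
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError(f"{path}: expected >= 3 (row, col) vertices")
    return verts


def save_contour(vertices: np.ndarray, path: str | Path) -> None:
    """Write a vertex list as contour JSON."""
    data = {"vertices": np.asarray(vertices, dtype=float).tolist()}
    Path(path).write_text(json.dumps(data))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
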