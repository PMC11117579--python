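"""Image preparation: normalization, contour rasterization and K-means cropping.

Transverse disc images arrive with an outer intervertebral-disc (IVD) contour
that was traced manually on the scan.  Before nucleus segmentation the image
is cropped to that contour's bounding box and surrounding tissue is
suppressed: an intensity K-means separates background / annulus / nucleus
intensity populations, and everything outside the traced contour is zeroed so
only the disc itself (annulus fibrosus + nucleus pulposus) remains.

Coordinate convention used throughout the package: 0-based ``(row, col)``
with pixel centers at integer coordinates.  Contour vertices live in the same
frame and may be fractional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .errors import ContourError

__all__ = [
    "GrayImage",
    "normalize_intensity",
    "rasterize_contour",
    "kmeans_intensity",
    "kmeans_crop",
    "CropResult",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array, values in [0, 1].
    spacing_mm
        Optional physical pixel spacing ``(row_mm, col_mm)``.  Required only
        when areas are to be reported in mm².
    """

    pixels: np.ndarray
    spacing_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        object.__setattr__(self, "pixels", px)
        if self.spacing_mm is not None:
            sr, sc = self.spacing_mm
            if sr <= 0 or sc <= 0:
                raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def normalize_intensity(
    image: np.ndarray, spacing_mm: Optional[Tuple[float, float]] = None
) -> GrayImage:
    """Linearly rescale a raw intensity grid to [0, 1].

    Minimum maps to 0 and maximum to 1; a constant image maps to all zeros.
    Normalization makes intensity-difference thresholds (the region-growing
    ``maxdis``, cluster distances) scale-free across scanners.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return GrayImage(np.zeros_like(arr), spacing_mm)
    return GrayImage((arr - lo) / (hi - lo), spacing_mm)


def _check_simple_polygon(vertices: np.ndarray) -> None:
    poly = Polygon([(c, r) for r, c in vertices])
    if not poly.is_valid:
        raise ContourError("contour polygon is self-intersecting or degenerate")
    if poly.area <= 0:
        raise ContourError("contour encloses zero area")


def rasterize_contour(
    vertices: Sequence[Sequence[float]], shape: Tuple[int, int]
) -> np.ndarray:
    """Rasterize a closed polygon onto a pixel grid.

    A pixel belongs to the mask when its center ``(row, col)`` lies inside
    the polygon by the even-odd (ray crossing) rule.  The enclosed pixel
    count of the traced IVD contour defines CSA_IVD.

    Parameters
    ----------
    vertices
        Ordered ``(row, col)`` vertex list of a simple closed polygon (the
        closing edge from last back to first vertex is implicit).
    shape
        ``(n_rows, n_cols)`` of the target grid.

    Returns
    -------
    Boolean mask of the given shape.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ContourError("contour needs at least 3 (row, col) vertices")
    _check_simple_polygon(verts)

    nr, nc = shape
    mask = np.zeros((nr, nc), dtype=bool)
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), nr - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), nc - 1)
    if r1 < r0 or c1 < c0:
        return mask

    rows = np.arange(r0, r1 + 1, dtype=float)
    cols = np.arange(c0, c1 + 1, dtype=float)
    R = rows[:, None]  # broadcast over bbox
    C = cols[None, :]
    inside = np.zeros((rows.size, cols.size), dtype=bool)

    ra, ca = verts[:, 0], verts[:, 1]
    rb, cb = np.roll(ra, -1), np.roll(ca, -1)
    for y1, x1, y2, x2 in zip(ra, ca, rb, cb):
        if y1 == y2:
            continue  # horizontal edge never crossed by the strict test
        crosses = (y1 > R) != (y2 > R)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (R - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (C < x_at)

    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def kmeans_intensity(
    values: np.ndarray, k: int, seed: int, max_iter: int = 100
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lloyd K-means on scalar intensities with k-means++ seeding.

    Deterministic for a given seed; assignment ties go to the lowest cluster
    index.  Returns ``(centers, labels, inertia_trace)`` with centers sorted
    ascending so cluster indices are reproducible regardless of the seeding
    order.  The inertia trace (within-cluster sum of squares per Lloyd
    iteration) is non-increasing.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.size < k:
        raise ValueError("fewer points than clusters")

    rng = np.random.default_rng(seed)
    # k-means++ seeding
    centers = np.empty(k)
    centers[0] = x[rng.integers(x.size)]
    d2 = (x - centers[0]) ** 2
    for i in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[i:] = centers[0]
            break
        probs = d2 / total
        centers[i] = x[rng.choice(x.size, p=probs)]
        d2 = np.minimum(d2, (x - centers[i]) ** 2)

    trace = []
    labels = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        dist = np.abs(x[:, None] - centers[None, :])
        new_labels = np.argmin(dist, axis=1)  # argmin takes lowest index on ties
        inertia = float(((x - centers[new_labels]) ** 2).sum())
        trace.append(inertia)
        new_centers = centers.copy()
        for i in range(k):
            sel = new_labels == i
            if sel.any():
                new_centers[i] = x[sel].mean()
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            labels = new_labels
            break
        labels, centers = new_labels, new_centers

    order = np.argsort(centers, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centers[order], remap[labels], np.asarray(trace)


class CropResult(NamedTuple):
    """Disc-only image produced by :func:`kmeans_crop`.

    ``image`` is the cropped bounding-box image with pixels outside the
    traced contour zeroed; ``disc_mask`` is the rasterized contour inside the
    same bounding box; ``origin`` is the (row, col) offset of the box in the
    original frame; ``centers`` are the sorted K-means intensity centers.
    """

    image: GrayImage
    disc_mask: np.ndarray
    origin: Tuple[int, int]
    centers: np.ndarray


def kmeans_crop(
    image: GrayImage,
    contour: Sequence[Sequence[float]],
    k: int = 3,
    seed: int = 0,
) -> CropResult:
    """Crop the image to the traced IVD and suppress surrounding tissue.

    The image is cut to the contour's bounding box, an intensity K-means
    (default k=3: background / annulus / nucleus populations) is run on the
    box, and every pixel outside the rasterized contour is set to 0 so only
    the disc (AF + NP) remains.  The contour, not the clustering, is the
    authoritative exclusion boundary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    full_mask = rasterize_contour(contour, image.shape)
    if not full_mask.any():
        raise ContourError("contour rasterizes to an empty mask")
    rows = np.flatnonzero(full_mask.any(axis=1))
    cols = np.flatnonzero(full_mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    box = image.pixels[r0 : r1 + 1, c0 : c1 + 1]
    disc_mask = full_mask[r0 : r1 + 1, c0 : c1 + 1]

    centers, _, _ = kmeans_intensity(box.ravel(), k=k, seed=seed)
    cropped = np.where(disc_mask, box, 0.0)
    return CropResult(GrayImage(cropped, image.spacing_mm), disc_mask, (r0, c0), centers)
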