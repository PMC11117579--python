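"""Seeded region growing of the nucleus pulposus.

Starting from one or more seed pixels, the region repeatedly absorbs the
frontier pixel whose gray value is closest to the running mean of the region
(best-first growth), as long as that difference does not exceed the preset
threshold ``maxdis``.  After each acceptance the mean is updated
incrementally,

    mean2 = (mean1 * size + point) / (size + 1),

and the accepted pixel's 4-neighbors join the frontier.  Growth from a seed
ends when every frontier pixel differs from the mean by more than
``maxdis``; subsequent seeds continue growing the same region.  A seed near
the NP boundary (where the gray value is noticeably lower than at the NP
center) works better in practice than a central seed, so the automatic
seed proposal returns a point just inside the provisional NP boundary.

Intensities are assumed normalized to [0, 1], which makes ``maxdis`` values
such as 0.1 or 0.06 scale-free; 0.06 is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, erosion, opening

from .errors import SegmentationError
from .preprocess import GrayImage, kmeans_intensity

__all__ = [
    "RgConfig",
    "GrowthResult",
    "update_mean",
    "region_grow",
    "propose_seed",
    "propose_seeds",
    "morpho_cleanup",
]


@dataclass(frozen=True)
class RgConfig:
    """Region-growing settings: seeds, acceptance threshold, cleanup radius."""

    seeds: Tuple[Tuple[int, int], ...]
    maxdis: float = 0.06
    cleanup_radius: int = 2

    def __post_init__(self) -> None:
        if len(self.seeds) == 0:
            raise ValueError("at least one seed pixel is required")
        if self.maxdis < 0:
            raise ValueError("maxdis must be nonnegative")
        object.__setattr__(
            self, "seeds", tuple((int(r), int(c)) for r, c in self.seeds)
        )


@dataclass(frozen=True)
class GrowthResult:
    """Grown region plus the running-mean trace.

    ``mean_trace[i]`` is the region mean immediately after the (i+1)-th
    acceptance; it always equals the batch mean of the accepted gray values.
    """

    mask: np.ndarray
    mean: float
    size: int
    mean_trace: np.ndarray = field(repr=False)


def update_mean(mean1: float, size: int, point: float) -> float:
    """Incremental region mean after absorbing one pixel of value ``point``."""
    if size < 1:
        raise ValueError("size must be >= 1")
    return (mean1 * size + point) / (size + 1)


_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def region_grow(
    image: GrayImage, cfg: RgConfig, domain: Optional[np.ndarray] = None
) -> GrowthResult:
    """Best-first seeded region growing restricted to ``domain``.

    Each step scans the whole frontier (the "Seeds" stack) for the pixel
    minimizing ``|gray - region mean|`` (ties broken by smallest
    (row, col)); the pixel is accepted when the difference is <= ``maxdis``,
    otherwise growth pauses: the next seed restarts it.  The frontier is one
    persistent set across seed restarts, so a pixel rejected earlier is
    reconsidered when a later seed shifts the running mean; growth ends only
    when every frontier pixel exceeds ``maxdis`` and no seeds remain.  Seeds
    are processed in the given order, are always accepted, and accumulate
    into one region.  Restricting ``domain`` to the traced disc mask keeps
    the nucleus from leaking outside the IVD.
    """
    img = image.pixels
    if domain is None:
        domain = np.ones(img.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    for r, c in cfg.seeds:
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]) or not domain[r, c]:
            raise ValueError(f"seed {(r, c)} outside the image or growth domain")

    region = np.zeros(img.shape, dtype=bool)
    mean = 0.0
    size = 0
    trace: List[float] = []

    def accept(r: int, c: int) -> None:
        nonlocal mean, size
        region[r, c] = True
        mean = img[r, c] if size == 0 else update_mean(mean, size, img[r, c])
        size += 1
        trace.append(mean)

    frontier: dict = {}

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if (
                0 <= rr < img.shape[0]
                and 0 <= cc < img.shape[1]
                and domain[rr, cc]
                and not region[rr, cc]
            ):
                frontier[(rr, cc)] = img[rr, cc]

    for seed in cfg.seeds:
        if not region[seed]:
            frontier.pop(seed, None)
            accept(*seed)
            push_neighbors(*seed)
        while frontier:
            best = min(
                frontier.items(), key=lambda kv: (abs(kv[1] - mean), kv[0])
            )
            (r, c), val = best
            if abs(val - mean) > cfg.maxdis:
                break  # every remaining frontier pixel is at least this far
            del frontier[(r, c)]
            accept(r, c)
            push_neighbors(r, c)

    return GrowthResult(mask=region, mean=mean, size=size, mean_trace=np.asarray(trace))


def propose_seeds(
    image: GrayImage, disc_mask: np.ndarray, n_seeds: int = 5, seed: int = 0
) -> Tuple[Tuple[int, int], ...]:
    """Automatic seeds just inside the provisional nucleus boundary.

    Disc intensities are split by a k=3 intensity K-means; pixels above the
    midpoint of the two brightest centers form a provisional nucleus.  The
    largest 4-connected component is eroded once and ``n_seeds`` pixels are
    taken evenly spaced (in angular order around the blob centroid) on the
    eroded boundary — near, but inside, the NP outline.  Several seeds make
    the growth robust to a noisy cold start: a fresh seed restarts growth
    when the previous frontier went stale.
    """
    disc_mask = np.asarray(disc_mask, dtype=bool)
    values = image.pixels[disc_mask]
    if values.size < 3:
        raise SegmentationError("disc mask too small to propose a seed")
    centers, _, _ = kmeans_intensity(values, k=3, seed=seed)
    if centers[-1] - centers[0] < 1e-6:
        raise SegmentationError(
            "disc has no intensity contrast (no bright nucleus class)"
        )
    thr = 0.5 * (centers[-1] + centers[-2])
    provisional = disc_mask & (image.pixels >= thr)
    lab = cc_label(provisional, connectivity=1)
    if lab.max() == 0:
        raise SegmentationError(
            "no bright nucleus candidate found; provide a manual seed"
        )
    sizes = np.bincount(lab.ravel())[1:]
    blob = lab == (int(np.argmax(sizes)) + 1)
    eroded = erosion(blob, disk(1))
    if not eroded.any():
        eroded = blob
    boundary = eroded & ~erosion(eroded, disk(1))
    candidates = np.argwhere(boundary if boundary.any() else eroded)
    centroid = candidates.mean(axis=0)
    angles = np.arctan2(
        candidates[:, 0] - centroid[0], candidates[:, 1] - centroid[1]
    )
    ordered = candidates[np.lexsort((candidates[:, 1], candidates[:, 0], angles))]
    idx = np.unique(
        np.linspace(0, len(ordered) - 1, min(n_seeds, len(ordered))).astype(int)
    )
    return tuple((int(r), int(c)) for r, c in ordered[idx])


def propose_seed(image: GrayImage, disc_mask: np.ndarray, seed: int = 0) -> Tuple[int, int]:
    """First seed of :func:`propose_seeds` (single-seed convenience)."""
    return propose_seeds(image, disc_mask, n_seeds=1, seed=seed)[0]


def morpho_cleanup(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Closing, opening, largest 4-connected component, hole filling.

    The standard dilation/erosion ("expansion corrosion") cleanup applied to
    the grown region before contour extraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius > 0:
        el = disk(radius)
        mask = opening(closing(mask, el), el)
    lab = cc_label(mask, connectivity=1)
    if lab.max() == 0:
        raise SegmentationError("segmentation empty after morphological cleanup")
    sizes = np.bincount(lab.ravel())[1:]
    largest = lab == (int(np.argmax(sizes)) + 1)
    return binary_fill_holes(largest)
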