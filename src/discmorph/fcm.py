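"""Fuzzy C-means segmentation of the disc-only image.

FCM partitions the n disc-pixel intensities into c fuzzy clusters by
minimizing

    J(U, C) = sum_i sum_j u_ij^m * ||c_i - x_j||^2

subject to the per-object constraint sum_i u_ij = 1, where u_ij is the
membership of object j in cluster i and m > 1 is the fuzziness exponent.
The solver alternates the closed-form centroid update

    c_i = sum_j u_ij^m x_j / sum_j u_ij^m

with the membership update

    u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)),   d_ij = ||c_i - x_j||,

from a seeded random initialization, stopping when J or its change drops
below a tolerance.  Internally the membership matrix is stored
objects x clusters (rows sum to 1).

After clustering, the nucleus pulposus is taken as the cluster with the
brightest centroid (the NP is T2-hyperintense), and interference clusters
are removed by a morphological opening followed by keeping the largest
4-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening

from .errors import SegmentationError
from .preprocess import GrayImage

__all__ = [
    "FcmConfig",
    "FuzzyPartition",
    "init_membership",
    "update_centroids",
    "update_membership",
    "fcm_objective",
    "fcm_fit",
    "fcm_cluster",
    "select_np_cluster",
    "remove_interference",
]


@dataclass(frozen=True)
class FcmConfig:
    """FCM solver settings.

    ``c`` clusters (default 3: zeroed background / annulus / nucleus when
    run on the cropped disc-only image), fuzziness ``m`` (> 1, conventional
    default 2), tolerance ``tol`` applied to both the objective and its
    per-iteration change, and an iteration cap.
    """

    c: int = 3
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzziness exponent m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class FuzzyPartition:
    """Result of an FCM run.

    ``U`` is objects x clusters (each row sums to 1), ``centers`` holds the
    cluster centroids in intensity space, ``J`` the final objective,
    ``objective_trace`` the per-iteration objective values (non-increasing),
    and ``converged`` whether the tolerance was met before ``max_iter``.
    """

    U: np.ndarray
    centers: np.ndarray
    J: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray


def init_membership(n: int, c: int, seed: int) -> np.ndarray:
    """Random membership matrix, each object's memberships summing to 1."""
    if not n > c >= 2:
        raise ValueError("need n > c >= 2")
    rng = np.random.default_rng(seed)
    U = rng.random((n, c))
    return U / U.sum(axis=1, keepdims=True)


def _as_points(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def update_centroids(U: np.ndarray, X: np.ndarray, m: float) -> np.ndarray:
    """Membership-weighted centroids c_i = Σ u_ij^m x_j / Σ u_ij^m."""
    Xp = _as_points(X)
    W = np.asarray(U, dtype=float) ** m  # (n, c)
    denom = W.sum(axis=0)
    if np.any(denom == 0):
        raise SegmentationError("empty fuzzy cluster (all-zero membership column)")
    centers = (W.T @ Xp) / denom[:, None]
    return centers[:, 0] if np.asarray(X).ndim == 1 else centers


def _distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix d[j, i] = ||x_j - c_i||."""
    Xp = _as_points(X)
    Cp = _as_points(centers)
    diff = Xp[:, None, :] - Cp[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def update_membership(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """New membership matrix from the current centroids.

    Where a point coincides with a center (zero distance), it is crisply
    assigned to the first such center — the limiting behavior of the update.
    """
    if m <= 1:
        raise ValueError("fuzziness exponent m must be > 1")
    d = _distances(X, centers)  # (n, c)
    zero_rows = (d == 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
    if zero_rows.any():
        U[zero_rows] = 0.0
        first_zero = np.argmax(d[zero_rows] == 0, axis=1)
        U[np.flatnonzero(zero_rows), first_zero] = 1.0
    return U


def fcm_objective(U: np.ndarray, centers: np.ndarray, X: np.ndarray, m: float) -> float:
    """The FCM objective J = Σ_i Σ_j u_ij^m d_ij²."""
    d = _distances(X, centers)
    return float((np.asarray(U, dtype=float) ** m * d**2).sum())


def fcm_fit(X: np.ndarray, cfg: FcmConfig) -> FuzzyPartition:
    """Run the alternating FCM iteration on a set of data points.

    Each iteration updates centroids then memberships and records the
    objective; iteration stops when J < tol, |ΔJ| < tol, or ``max_iter`` is
    reached (the returned partition is then flagged unconverged rather than
    raising).
    """
    Xa = np.asarray(X, dtype=float)
    n = Xa.shape[0]
    if np.unique(Xa.reshape(n, -1), axis=0).shape[0] < cfg.c:
        raise SegmentationError("need at least c distinct data points")
    U = init_membership(n, cfg.c, cfg.seed)

    trace = []
    prev_J = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        centers = update_centroids(U, Xa, cfg.m)
        U = update_membership(Xa, centers, cfg.m)
        J = fcm_objective(U, centers, Xa, cfg.m)
        trace.append(J)
        if J < cfg.tol or abs(prev_J - J) < cfg.tol:
            converged = True
            break
        prev_J = J
    return FuzzyPartition(
        U=U,
        centers=np.asarray(centers),
        J=trace[-1],
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def fcm_cluster(
    image: GrayImage, cfg: FcmConfig, mask: Optional[np.ndarray] = None
) -> Tuple[FuzzyPartition, np.ndarray]:
    """Cluster image intensities; returns the partition and the pixel index.

    ``mask`` restricts clustering to the disc pixels (recommended: pass the
    rasterized IVD contour).  The second return value is the boolean mask of
    pixels the partition rows refer to, in row-major order.
    """
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    X = image.pixels[mask]
    part = fcm_fit(X, cfg)
    return part, mask


def select_np_cluster(
    partition: FuzzyPartition, disc_mask: np.ndarray
) -> np.ndarray:
    """Hard-assign pixels and return the mask of the brightest cluster.

    Each pixel goes to its maximum-membership cluster (ties to the lowest
    cluster index); the nucleus cluster is the one with the highest centroid
    intensity (again lowest index on ties).  The result is a boolean mask on
    the full grid, nonzero only inside ``disc_mask``.
    """
    labels = np.argmax(partition.U, axis=1)
    centers = np.asarray(partition.centers, dtype=float)
    brightness = centers if centers.ndim == 1 else centers[:, 0]
    np_cluster = int(np.argmax(brightness))
    mask = np.zeros(disc_mask.shape, dtype=bool)
    mask[disc_mask] = labels == np_cluster
    return mask


def remove_interference(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological opening then largest 4-connected component.

    Removes the small interference clusters that fuzzy clustering picks up
    in the blurred NP/AF transition band.  Raises when nothing survives.
    """
    mask = np.asarray(mask, dtype=bool)
    opened = opening(mask, disk(radius)) if radius > 0 else mask
    lab = cc_label(opened, connectivity=1)
    if lab.max() == 0:
        raise SegmentationError("segmentation empty after interference removal")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)
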