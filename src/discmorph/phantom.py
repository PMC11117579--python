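"""Synthetic transverse disc phantoms with known ground truth.

No public scan dataset accompanies the measurement protocol, so every
downstream stage is exercised on generated phantoms: an oval- or
kidney-shaped disc (the outer shape transitions from oval in the upper
lumbar spine to kidney-shaped in the lower lumbar spine), a darker annulus
fibrosus ring, a brighter central nucleus pulposus (hyperintense on
T2-weighted MRI), a blurred NP/AF boundary, and additive noise.  The
generator controls the true NP-to-CSA ratio, so segmentation accuracy can be
scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidSpecError
from .preprocess import GrayImage, rasterize_contour

__all__ = ["PhantomSpec", "Phantom", "boundary_curve", "generate_phantom"]

_N_BOUNDARY_PTS = 192


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic transverse disc image.

    Intensities are on a [0, 1] scale with ``intensity_np > intensity_af >
    intensity_background`` (the nucleus is T2-hyperintense).  The nucleus is
    a scaled copy of the outer disc boundary, re-scaled so the pixel-count
    NP-to-CSA ratio lands within 2 percentage points of ``np_target_ratio``.
    ``kidney_indent_depth`` produces a posterior concavity; 0 gives a pure
    ellipse.
    """

    image_height_px: int = 96
    image_width_px: int = 128
    disc_semi_axes_px: Tuple[float, float] = (42.0, 30.0)  # (a along cols, b along rows)
    shape_template: str = "oval"
    kidney_indent_depth: float = 0.0
    np_target_ratio: float = 0.40
    np_center_offset_px: Tuple[float, float] = (0.0, 0.0)  # (row, col)
    intensity_background: float = 0.10
    intensity_af: float = 0.35
    intensity_np: float = 0.75
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.02
    rng_seed: int = 0
    pixel_spacing_mm: Tuple[float, float] = (0.69, 0.69)

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        a, b = self.disc_semi_axes_px
        if a <= 0 or b <= 0:
            raise InvalidSpecError("semi-axes must be positive")
        if self.shape_template not in ("oval", "kidney"):
            raise InvalidSpecError(f"unknown shape template {self.shape_template!r}")
        if not 0.0 <= self.kidney_indent_depth < 1.0:
            raise InvalidSpecError("kidney_indent_depth must be in [0, 1)")
        if not 0.0 < self.np_target_ratio < 1.0:
            raise InvalidSpecError("np_target_ratio must be in (0, 1)")
        if not (
            self.intensity_np > self.intensity_af > self.intensity_background >= 0.0
        ) or self.intensity_np > 1.0:
            raise InvalidSpecError(
                "need 0 <= background < AF < NP <= 1 (T2: nucleus brightest)"
            )
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise InvalidSpecError("blur and noise parameters must be nonnegative")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise InvalidSpecError("pixel spacing must be positive")


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: image plus exact ground truth.

    ``true_ratio_percent`` is defined from the emitted masks, so it equals
    ``100 * |np_mask_true| / |ivd_mask_true|`` exactly.
    """

    spec: PhantomSpec
    image: GrayImage
    ivd_mask_true: np.ndarray
    np_mask_true: np.ndarray
    ivd_contour_true: np.ndarray  # (N, 2) closed (row, col) vertex list
    true_ratio_percent: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        n_ivd = int(self.ivd_mask_true.sum())
        n_np = int(self.np_mask_true.sum())
        if n_ivd == 0 or n_np == 0:
            raise InvalidSpecError("phantom masks are empty")
        if np.any(self.np_mask_true & ~self.ivd_mask_true):
            raise InvalidSpecError("NP mask leaks outside the IVD mask")
        object.__setattr__(self, "true_ratio_percent", 100.0 * n_np / n_ivd)


def boundary_curve(spec: PhantomSpec, theta: np.ndarray | float) -> np.ndarray:
    """Point(s) on the disc outline at polar angle ``theta``.

    Returns ``(x, y)`` offsets relative to the disc center, with x along
    image columns (anterior at theta=0) and y along rows.  The oval template
    is the ellipse ``(a cos θ, b sin θ)``.  The kidney template scales the
    posterior half (cos θ < 0) radially by ``1 − depth·cos²θ``, a smooth
    cosine-squared window peaking at θ=π that carves a single concave
    indentation.
    """
    th = np.asarray(theta, dtype=float)
    a, b = spec.disc_semi_axes_px
    factor = np.ones_like(th)
    if spec.shape_template == "kidney":
        post = np.cos(th) < 0
        factor = np.where(post, 1.0 - spec.kidney_indent_depth * np.cos(th) ** 2, 1.0)
    pts = np.stack([a * np.cos(th) * factor, b * np.sin(th) * factor], axis=-1)
    return pts


def _outline_vertices(spec: PhantomSpec, n: int = _N_BOUNDARY_PTS) -> np.ndarray:
    """Closed (row, col) outer contour centered in the image."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    xy = boundary_curve(spec, theta)
    cr = (spec.image_height_px - 1) / 2.0
    cc = (spec.image_width_px - 1) / 2.0
    return np.stack([cr + xy[:, 1], cc + xy[:, 0]], axis=1)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build a phantom image and its ground-truth masks.

    Painting order: background, annulus (disc minus nucleus), nucleus; then
    Gaussian blur of ``blur_sigma_px`` and additive Gaussian noise of sd
    ``noise_sd``, clipped to [0, 1].  The nucleus outline is a scaled copy of
    the outer curve, bisected on the scale factor until the pixel-count
    ratio is within 2 percentage points of ``np_target_ratio``.  Fully
    deterministic for a given ``rng_seed``.
    """
    shape = (spec.image_height_px, spec.image_width_px)
    outer = _outline_vertices(spec)
    ivd_mask = rasterize_contour(outer, shape)
    n_ivd = int(ivd_mask.sum())
    if n_ivd == 0:
        raise InvalidSpecError("disc rasterizes to an empty mask")

    cr = (spec.image_height_px - 1) / 2.0
    cc = (spec.image_width_px - 1) / 2.0
    dr, dc = spec.np_center_offset_px
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY_PTS, endpoint=False)
    xy = boundary_curve(spec, theta)

    def np_mask_at(scale: float) -> np.ndarray:
        verts = np.stack(
            [cr + dr + scale * xy[:, 1], cc + dc + scale * xy[:, 0]], axis=1
        )
        return rasterize_contour(verts, shape)

    # pixel-count ratio grows monotonically with scale; bisect to the target
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        ratio = np_mask_at(mid).sum() / n_ivd
        if ratio < spec.np_target_ratio:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    np_mask = np_mask_at(scale)
    achieved = 100.0 * np_mask.sum() / n_ivd
    if abs(achieved - 100.0 * spec.np_target_ratio) > 2.0:
        raise InvalidSpecError(
            f"could not reach np_target_ratio={spec.np_target_ratio:.3f}; "
            f"achieved {achieved:.1f}% (NP would cross the IVD boundary?)"
        )
    if np.any(np_mask & ~ivd_mask):
        raise InvalidSpecError("NP region crosses the IVD boundary (offset too large)")

    img = np.full(shape, spec.intensity_background, dtype=float)
    img[ivd_mask] = spec.intensity_af
    img[np_mask] = spec.intensity_np
    if spec.blur_sigma_px > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma_px)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    return Phantom(
        spec=spec,
        image=GrayImage(img, spec.pixel_spacing_mm),
        ivd_mask_true=ivd_mask,
        np_mask_true=np_mask,
        ivd_contour_true=outer,
    )
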