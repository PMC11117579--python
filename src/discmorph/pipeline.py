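"""End-to-end orchestration: image -> cropped disc -> NP mask -> ratio.

The measurement chain for one transverse disc image is:

1. normalize intensities to [0, 1];
2. rasterize the traced IVD contour (its pixel count is CSA_IVD) and crop
   to its bounding box, zeroing surrounding tissue (K-means crop);
3. segment the nucleus with fuzzy C-means and/or region growing;
4. remove interference / clean up morphologically;
5. optionally regularize the NP outline with the elliptic-Fourier fit;
6. compute CSA_NP and the NP-to-CSA ratio.

`measure_np` runs the chain for one image and method; `run_pipeline`
processes a manifest of images and writes masks, contours, a ratios table
and a JSON run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .contour import NpContour, extract_contour, fit_parametric_profile
from .errors import ContourError, SegmentationError
from .fcm import FcmConfig, fcm_fit, remove_interference, select_np_cluster
from .morphometry import RatioRecord, area, np_to_csa_ratio
from .preprocess import GrayImage, kmeans_crop, normalize_intensity, rasterize_contour
from .region_growing import RgConfig, morpho_cleanup, propose_seeds, region_grow

logger = logging.getLogger("discmorph")

__all__ = ["PipelineParams", "NpSegmentation", "measure_np", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the measurement chain."""

    kmeans_k: int = 3
    fcm_c: int = 3
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 100
    interference_radius: int = 2
    maxdis: float = 0.06
    n_seeds: int = 5
    cleanup_radius: int = 2
    refine: bool = True
    harmonics: int = 4


@dataclass(frozen=True)
class NpSegmentation:
    """Result of one method on one image: full-frame mask + measurement."""

    method: str
    np_mask: np.ndarray
    ivd_mask: np.ndarray
    record: RatioRecord
    contour: Optional[NpContour] = None


def _refine_mask(
    mask_bbox: np.ndarray,
    disc_mask: np.ndarray,
    params: PipelineParams,
    method: str,
) -> Tuple[np.ndarray, Optional[NpContour]]:
    """Elliptic-Fourier smoothing of the NP outline, re-rasterized.

    Falls back to the raw mask when the fit or rasterization degenerates.
    """
    try:
        raw = extract_contour(mask_bbox, source_method=method)
        fitted = fit_parametric_profile(raw, harmonics=params.harmonics)
        refined = rasterize_contour(fitted.vertices, mask_bbox.shape) & disc_mask
        if refined.any():
            return refined, fitted
    except (ContourError, SegmentationError):  # pragma: no cover - rare fallback
        pass
    return mask_bbox, None


def measure_np(
    image: GrayImage,
    ivd_contour: np.ndarray,
    method: str,
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    rg_seeds: Optional[Sequence[Tuple[int, int]]] = None,
    disc_level: str = "L4/L5",
    gender: str = "unknown",
    subject_id: str = "",
) -> NpSegmentation:
    """Measure the NP-to-CSA ratio of one image with one method.

    ``rg_seeds`` (full-frame (row, col) coordinates) overrides the automatic
    seed proposal for region growing.  Deterministic for a given ``seed``.
    """
    if method not in ("fcm", "rg"):
        raise ValueError("method must be 'fcm' or 'rg'")
    crop = kmeans_crop(image, ivd_contour, k=params.kmeans_k, seed=seed)
    disc_mask = crop.disc_mask
    r0, c0 = crop.origin

    if method == "fcm":
        cfg = FcmConfig(
            c=params.fcm_c,
            m=params.fcm_m,
            tol=params.fcm_tol,
            max_iter=params.fcm_max_iter,
            seed=seed + 1,
        )
        # cluster the whole disc-only image (zeroed surroundings included):
        # c=3 separates background / annulus / nucleus populations robustly
        part = fcm_fit(crop.image.pixels.ravel(), cfg)
        raw = select_np_cluster(part, np.ones(disc_mask.shape, dtype=bool))
        mask_bbox = remove_interference(raw & disc_mask, radius=params.interference_radius)
    else:
        if rg_seeds is None:
            seeds = propose_seeds(crop.image, disc_mask, n_seeds=params.n_seeds, seed=seed)
        else:
            seeds = tuple((int(r) - r0, int(c) - c0) for r, c in rg_seeds)
        cfg_rg = RgConfig(seeds=seeds, maxdis=params.maxdis, cleanup_radius=params.cleanup_radius)
        grown = region_grow(crop.image, cfg_rg, domain=disc_mask)
        mask_bbox = morpho_cleanup(grown.mask, radius=params.cleanup_radius)

    fitted = None
    if params.refine:
        mask_bbox, fitted = _refine_mask(mask_bbox, disc_mask, params, method)

    ivd_mask = np.zeros(image.shape, dtype=bool)
    ivd_mask[r0 : r0 + disc_mask.shape[0], c0 : c0 + disc_mask.shape[1]] = disc_mask
    np_mask = np.zeros(image.shape, dtype=bool)
    np_mask[r0 : r0 + disc_mask.shape[0], c0 : c0 + disc_mask.shape[1]] = mask_bbox

    csa_ivd = area(ivd_mask, image.spacing_mm)
    csa_np = area(np_mask, image.spacing_mm)
    record = RatioRecord(
        csa_np=csa_np,
        csa_ivd=csa_ivd,
        ratio_percent=np_to_csa_ratio(csa_np, csa_ivd),
        method=method,
        disc_level=disc_level,
        gender=gender,
        subject_id=subject_id,
    )
    return NpSegmentation(
        method=method, np_mask=np_mask, ivd_mask=ivd_mask, record=record, contour=fitted
    )


@dataclass(frozen=True)
class RunConfig:
    """Batch run: a manifest table plus shared parameters.

    The manifest needs columns ``image`` and ``contour`` (file paths) and
    may carry ``subject_id``, ``gender``, ``disc_level``, ``spacing_row_mm``,
    ``spacing_col_mm``.
    """

    manifest: pd.DataFrame
    out_dir: Path
    methods: Tuple[str, ...] = ("fcm", "rg")
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Process every manifest row; write masks, ratios.csv and a run log.

    Per-row failures are logged and skipped; the run fails only when no row
    succeeds.  Deterministic for a given global seed (row i uses seed
    ``cfg.seed + i``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    failures = []
    for i, row in cfg.manifest.reset_index(drop=True).iterrows():
        try:
            spacing = None
            if "spacing_row_mm" in row and pd.notna(row.get("spacing_row_mm")):
                spacing = (float(row["spacing_row_mm"]), float(row["spacing_col_mm"]))
            image = dio.load_image(row["image"], spacing_mm=spacing)
            contour = dio.load_contour(row["contour"])
            for method in cfg.methods:
                seg = measure_np(
                    image,
                    contour,
                    method,
                    params=cfg.params,
                    seed=cfg.seed + i,
                    disc_level=str(row.get("disc_level", "L4/L5")),
                    gender=str(row.get("gender", "unknown")),
                    subject_id=str(row.get("subject_id", f"row{i}")),
                )
                stem = f"{Path(str(row['image'])).stem}_{method}"
                dio.save_mask_png(seg.np_mask, out / f"{stem}_np.png")
                if seg.contour is not None:
                    dio.save_contour(seg.contour.vertices, out / f"{stem}_contour.json")
                records.append(dataclasses.asdict(seg.record))
        except Exception as exc:  # noqa: BLE001 - per-row isolation
            logger.warning("row %d failed: %s", i, exc)
            failures.append((i, str(exc)))
    if not records:
        raise RuntimeError(f"all {len(failures)} manifest rows failed: {failures[:3]}")
    table = pd.DataFrame(records)
    table.to_csv(out / "ratios.csv", index=False)
    log = {
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "params": dataclasses.asdict(cfg.params),
        "n_rows": int(len(cfg.manifest)),
        "n_records": len(records),
        "failures": failures,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return table
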