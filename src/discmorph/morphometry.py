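"""Cross-sectional areas and the NP-to-CSA ratio.

The target morphometric is the percentage of the disc's transverse
cross-sectional area occupied by the nucleus pulposus:

    Ratio = 100 * CSA_NP / CSA_IVD.

Areas are pixel counts scaled by the physical pixel spacing when available
(mm²), or raw pixel counts otherwise; the ratio is identical either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["RatioRecord", "area", "np_to_csa_ratio", "dice_coefficient"]

DISC_LEVELS = ("L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1")


@dataclass(frozen=True)
class RatioRecord:
    """One NP-to-CSA measurement: the unit of all statistical analyses."""

    csa_np: float
    csa_ivd: float
    ratio_percent: float
    method: str  # {"manual", "fcm", "rg"}
    disc_level: str = "L4/L5"
    gender: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.csa_ivd <= 0:
            raise ValueError("CSA_IVD must be positive")
        if self.csa_np > self.csa_ivd:
            raise ValueError("CSA_NP cannot exceed CSA_IVD")
        if abs(self.ratio_percent - 100.0 * self.csa_np / self.csa_ivd) > 1e-9:
            raise ValueError("ratio_percent inconsistent with the stored areas")


def area(mask: np.ndarray, spacing_mm: Optional[Tuple[float, float]] = None) -> float:
    """Area of a binary mask: pixel count, scaled to mm² when spacing given."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    if spacing_mm is None:
        return float(n)
    sr, sc = spacing_mm
    return n * sr * sc


def np_to_csa_ratio(csa_np: float, csa_ivd: float) -> float:
    """NP-to-CSA ratio in percent: 100 * CSA_NP / CSA_IVD.

    If method noise produced CSA_NP slightly above CSA_IVD (possible only
    when the growth domain restriction was disabled), the numerator is
    clipped to the denominator with a warning — anatomically the nucleus is
    contained in the disc.
    """
    if csa_ivd <= 0:
        raise ValueError("CSA_IVD must be positive")
    if csa_np > csa_ivd:
        warnings.warn(
            "CSA_NP exceeds CSA_IVD; clipping to 100% (nucleus must be "
            "contained in the disc)",
            stacklevel=2,
        )
        csa_np = csa_ivd
    return 100.0 * csa_np / csa_ivd


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return 2.0 * float((a & b).sum()) / float(denom)
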