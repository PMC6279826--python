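"""Pixel-level quality control for nailbed regions of interest.

Camera-flash reflections and leukonychia spots show up as near-white pixels
inside the nailbed ROI and bias the color summary toward higher lightness,
which translates directly into a hemoglobin error.  Two complementary rules
flag pixels whose color falls outside the expected nailbed range:

* bright-achromatic gate — L* above ``max_L`` *and* chroma sqrt(a*^2+b*^2)
  below ``min_chroma``.  Healthy and anemic nailbeds alike are strongly
  chromatic (red-dominant), so bright near-neutral pixels are artifacts.
* robust-outlier gate — per-channel robust z-score |x - median| /
  (1.4826 * MAD) above ``mad_k`` in any sRGB channel, computed over the full
  ROI.  This catches off-range pixels the absolute gate does not anticipate.

An ROI where fewer than ``min_retained_fraction`` of pixels survive is
unusable and must be excluded by the caller (the ROI-level analogue of
excluding obscured or discolored nailbeds from analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnusableROIError, ValidationError
from .imaging import srgb_to_lab

REASON_NONE = "none"
REASON_BRIGHT = "bright-achromatic"
REASON_OUTLIER = "robust-outlier"

# Gaussian-consistency factor for the median absolute deviation.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the two rejection rules.

    max_L / min_chroma define the bright-achromatic gate; ``mad_k`` is the
    robust z cutoff (multiples of scaled MAD); ``min_retained_fraction`` is
    the minimum surviving fraction for the ROI to stay usable.
    """

    max_L: float = 90.0
    min_chroma: float = 5.0
    mad_k: float = 3.5
    min_retained_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.min_retained_fraction <= 1.0):
            raise ValidationError(
                f"min_retained_fraction must be in (0, 1], got {self.min_retained_fraction}"
            )
        if self.mad_k <= 0:
            raise ValidationError(f"mad_k must be > 0, got {self.mad_k}")


@dataclass
class PixelMask:
    """Per-pixel keep/reject decision for one ROI."""

    keep: np.ndarray            # bool, one entry per ROI pixel
    rejection_reasons: np.ndarray  # str tags, same length
    min_retained_fraction: float

    @property
    def retained_fraction(self) -> float:
        return float(self.keep.mean())

    @property
    def usable(self) -> bool:
        return self.retained_fraction >= self.min_retained_fraction

    def reason_counts(self) -> dict:
        vals, counts = np.unique(self.rejection_reasons, return_counts=True)
        out = {REASON_BRIGHT: 0, REASON_OUTLIER: 0}
        out.update({str(v): int(c) for v, c in zip(vals, counts) if v != REASON_NONE})
        return out


@dataclass(frozen=True)
class ColorFeatures:
    """QC-filtered color summary of one ROI (or of a per-subject average)."""

    mean_rgb: tuple          # (R, G, B), 0-255 scale, float
    mean_lab: tuple          # (L*, a*, b*), per-pixel Lab averaged
    retained_fraction: float
    reason_counts: dict = field(default_factory=dict)


def qc_mask(roi_pixels: np.ndarray, params: QCParams | None = None) -> PixelMask:
    """Classify every ROI pixel as kept or rejected.

    Both rules are evaluated against the full ROI (the median/MAD are taken
    over all pixels, rejected ones included); the input block is not
    modified.  Pixels failing the bright-achromatic gate are tagged with that
    reason even if they also trip the robust gate.
    """
    params = params or QCParams()
    px = np.asarray(roi_pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise ValidationError(f"roi_pixels must be (n, 3), got shape {px.shape}")
    n = px.shape[0]
    if n < 25:
        raise ValidationError(f"qc_mask needs >= 25 pixels, got {n}")

    lab = srgb_to_lab(px)
    chroma = np.hypot(lab[:, 1], lab[:, 2])
    bright = (lab[:, 0] > params.max_L) & (chroma < params.min_chroma)

    med = np.median(px, axis=0)
    mad = np.median(np.abs(px - med), axis=0)
    scale = MAD_SCALE * mad
    dev = np.abs(px - med)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(scale > 0, dev / np.where(scale > 0, scale, 1.0),
                     np.where(dev > 0, np.inf, 0.0))
    outlier = (z > params.mad_k).any(axis=1)

    keep = ~(bright | outlier)
    reasons = np.full(n, REASON_NONE, dtype="<U24")
    reasons[outlier] = REASON_OUTLIER
    reasons[bright] = REASON_BRIGHT   # absolute gate takes precedence
    return PixelMask(keep=keep, rejection_reasons=reasons,
                     min_retained_fraction=params.min_retained_fraction)


def robust_roi_mean(roi_pixels: np.ndarray, mask: PixelMask) -> ColorFeatures:
    """Arithmetic mean color over kept pixels, in sRGB and per-pixel Lab.

    Raises :class:`UnusableROIError` when the mask marks the ROI unusable or
    no pixel survives.
    """
    px = np.asarray(roi_pixels, dtype=float)
    if px.shape[0] != mask.keep.shape[0]:
        raise ValidationError("mask length does not match pixel block")
    if not mask.usable:
        raise UnusableROIError(
            f"ROI unusable: retained fraction {mask.retained_fraction:.3f} "
            f"< {mask.min_retained_fraction}"
        )
    kept = px[mask.keep]
    if kept.shape[0] == 0:
        raise UnusableROIError("ROI unusable: zero pixels kept")
    mean_rgb = kept.mean(axis=0)
    mean_lab = srgb_to_lab(kept).mean(axis=0)
    return ColorFeatures(
        mean_rgb=tuple(float(v) for v in mean_rgb),
        mean_lab=tuple(float(v) for v in mean_lab),
        retained_fraction=mask.retained_fraction,
        reason_counts=mask.reason_counts(),
    )
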