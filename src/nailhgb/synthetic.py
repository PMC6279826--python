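"""Synthetic fingernail-bed photographs with known ground-truth hemoglobin.

No public dataset of annotated fingernail photos with paired CBC hemoglobin
exists, so the estimator is exercised end-to-end on images drawn from an
explicit forward model that reproduces the statistical structure the method
relies on:

* nailbed color monotonically coupled to blood Hgb — a linear per-channel
  model around a 12 g/dL reference, red-dominant, scaled so the physiologic
  5.9-16.8 g/dL range spans roughly 60 units of 8-bit red;
* surrounding-skin color driven by a melanin lightness L* that is
  statistically independent of Hgb;
* background-lux-coupled lighting gain and EXIF-style capture metadata
  (flash-on photos are lighting-normalized by the flash, flash-off photos
  are not, but their metadata encodes the ambient light);
* measurement variability on the Hgb scale, split into a per-subject offset
  and a per-session term so that personalized calibration has something to
  remove;
* injected artifacts (leukonychia spots, specular flash highlights) whose
  colors fall outside the quality-control expected range by construction.

The red channel is deliberately the only Hgb-carrying channel (green/blue
vary with imaging conditions, independent of Hgb): this makes the red mean a
sufficient statistic and gives the inverse regression well-defined
ground-truth coefficients, exposed by :func:`true_model_coefficients`.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging import CaptureMetadata, FingernailImage, ROI, lab_to_srgb, save_image

IMAGE_W = 640
IMAGE_H = 480
ROI_SIZE = 30  # 30x30 px = 900 px^2, ~10 mm^2 on the nail

# Fixed capture layout: thumb (finger 1) low, fingers 2-5 in a row, one skin
# patch top-left.  Coordinates are emitted with the image, never detected.
_NAILBED_XY = {1: (60, 300), 2: (180, 140), 3: (260, 140), 4: (340, 140), 5: (420, 140)}
_SKIN_XY = (60, 60)

DEFAULT_ROIS = tuple(
    [ROI(finger=f, kind="nailbed", x=x, y=y, w=ROI_SIZE, h=ROI_SIZE)
     for f, (x, y) in sorted(_NAILBED_XY.items())]
    + [ROI(finger=2, kind="skin", x=_SKIN_XY[0], y=_SKIN_XY[1], w=ROI_SIZE, h=ROI_SIZE)]
)

HGB_RANGE_GDL = (5.9, 16.8)  # observed physiologic range emulated by default


@dataclass(frozen=True)
class MetadataModel:
    """Mapping from ambient lux and flash flag to EXIF-style metadata.

    Flash-on photos sit near a fixed "normalized" exposure triple with mild
    auto-exposure jitter; flash-off photos couple ISO and exposure time
    inversely to lux.  The brightness value (APEX EV) tracks log2 lux in both
    modes, more weakly with flash.
    """

    lux_ref: float = 250.0
    bv_ref: float = 5.0
    flash_exposure_s: float = 1.0 / 60.0
    flash_iso: float = 64.0
    flash_bv_lux_slope: float = 0.3
    noflash_exposure_ref_s: float = 1.0 / 30.0
    noflash_iso_ref: float = 320.0
    noflash_lux_exponent: float = 0.5
    f_number: float = 2.2
    exposure_jitter: float = 0.02
    iso_jitter: float = 0.03
    bv_jitter: float = 0.05

    def sample(self, lux: float, flash: bool, rng: np.random.Generator) -> CaptureMetadata:
        rel = lux / self.lux_ref
        if flash:
            exposure = self.flash_exposure_s * (1 + rng.normal(0, self.exposure_jitter))
            iso = self.flash_iso * (1 + rng.normal(0, self.iso_jitter))
            bv = self.bv_ref + self.flash_bv_lux_slope * math.log2(rel) \
                + rng.normal(0, self.bv_jitter)
        else:
            exposure = self.noflash_exposure_ref_s * rel ** (-self.noflash_lux_exponent) \
                * (1 + rng.normal(0, self.exposure_jitter))
            iso = self.noflash_iso_ref * rel ** (-self.noflash_lux_exponent) \
                * (1 + rng.normal(0, self.iso_jitter))
            bv = self.bv_ref + math.log2(rel) + rng.normal(0, self.bv_jitter)
        return CaptureMetadata(
            flash_fired=bool(flash),
            exposure_time=float(max(exposure, 1e-5)),
            iso=float(max(iso, 1.0)),
            f_number=self.f_number,
            brightness_value=float(bv),
            lux=float(lux),
        )


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the color/metadata forward model.

    ``hgb_color_slope`` is the per-channel color change per g/dL around
    ``base_color_at_ref_hgb`` (the nailbed color at ``ref_hgb`` = 12 g/dL).
    ``hgb_offset_sd``/``hgb_session_sd`` inject measurement variability on
    the Hgb scale (the color is driven by an *effective* Hgb = true Hgb +
    subject offset + session term).  ``channel_jitter_sd`` adds per-session
    Hgb-independent variation to each channel.  Lighting gain applies to
    flash-off photos only, interpolated log-linearly in lux over
    ``lux_range`` onto ``lighting_gain_range``.
    """

    base_color_at_ref_hgb: tuple = (180.0, 98.0, 92.0)
    ref_hgb: float = 12.0
    hgb_color_slope: tuple = (5.5, 0.0, 0.0)
    pixel_noise_sd: float = 2.0
    channel_jitter_sd: tuple = (0.0, 3.0, 3.0)
    hgb_offset_sd: float = 1.1
    hgb_session_sd: float = 0.5
    lighting_gain_range: tuple = (0.9, 1.1)
    lux_range: tuple = (79.0, 790.0)
    skin_L_range: tuple = (30.0, 90.0)
    skin_ab: tuple = (13.0, 17.0)
    metadata_model: MetadataModel = field(default_factory=MetadataModel)

    def __post_init__(self):
        if self.pixel_noise_sd < 0:
            raise ValidationError("pixel_noise_sd must be >= 0")
        g0, g1 = self.lighting_gain_range
        if not (0 < g0 <= g1 <= 2):
            raise ValidationError("lighting_gain_range must lie within (0, 2]")
        if self.hgb_color_slope[0] == 0:
            raise ValidationError("red-channel slope must be nonzero (monotone redness)")
        lo, hi = HGB_RANGE_GDL
        for h in (5.0, 17.0):
            c = self.nailbed_color(h)
            if c[0] <= 0 or c[0] >= 255:
                raise ValidationError(
                    f"red channel clips at {h} g/dL ({c[0]:.1f}); reduce the slope"
                )

    def noiseless(self) -> "ForwardModelParams":
        """Copy with every noise source (pixel, channel, Hgb-scale) zeroed."""
        return replace(self, pixel_noise_sd=0.0, channel_jitter_sd=(0.0, 0.0, 0.0),
                       hgb_offset_sd=0.0, hgb_session_sd=0.0,
                       metadata_model=replace(self.metadata_model,
                                              exposure_jitter=0.0, iso_jitter=0.0,
                                              bv_jitter=0.0))

    def nailbed_color(self, effective_hgb: float, channel_jitter=(0.0, 0.0, 0.0)) -> np.ndarray:
        base = np.asarray(self.base_color_at_ref_hgb, dtype=float)
        slope = np.asarray(self.hgb_color_slope, dtype=float)
        return base + slope * (effective_hgb - self.ref_hgb) + np.asarray(channel_jitter)

    def lighting_gain(self, lux: float, flash: bool) -> float:
        """Multiplicative lux-coupled gain; the flash normalizes it to 1."""
        if flash:
            return 1.0
        lo, hi = self.lux_range
        g0, g1 = self.lighting_gain_range
        t = (math.log(lux) - math.log(lo)) / (math.log(hi) - math.log(lo))
        return g0 + min(max(t, 0.0), 1.0) * (g1 - g0)


@dataclass(frozen=True)
class ArtifactSpec:
    """Injected nailbed irregularities (all placed inside non-thumb ROIs)."""

    leukonychia_count: int = 0
    leukonychia_radius_px: int = 4
    specular_count: int = 0
    specular_radius_px: int = 2
    specular_value: tuple = (250.0, 250.0, 250.0)
    leukonychia_value: tuple = (235.0, 232.0, 228.0)

    def __post_init__(self):
        if self.leukonychia_count < 0 or self.specular_count < 0:
            raise ValidationError("artifact counts must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls()

    @classmethod
    def default_injected(cls) -> "ArtifactSpec":
        return cls(leukonychia_count=2, specular_count=2)


@dataclass
class SyntheticSubject:
    """One subject-session: a flash-on/flash-off photo pair plus truth."""

    subject_id: str
    true_hgb: float
    skin_L: float
    lux: float
    images: list                 # [flash-on, flash-off] FingernailImage
    roi_annotations: list        # list[ROI]
    session_index: int = 1
    effective_hgb: float = None  # true Hgb + subject offset + session term
    artifact_masks: list = None  # full-frame bool mask per image

    @property
    def image_flash(self) -> FingernailImage:
        return self.images[0]

    @property
    def image_noflash(self) -> FingernailImage:
        return self.images[1]


def _disc_mask(size: int, cx: int, cy: int, r: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def _render_image(effective_hgb, skin_L, lux, flash, params, artifacts, rng):
    """Render one photograph; returns (FingernailImage, artifact mask)."""
    gain = params.lighting_gain(lux, flash)
    jitter = rng.normal(0.0, params.channel_jitter_sd, size=3) \
        if any(s > 0 for s in params.channel_jitter_sd) else np.zeros(3)
    nail_rgb = params.nailbed_color(effective_hgb, jitter) * gain
    skin_rgb = lab_to_srgb([skin_L, *params.skin_ab]) * gain

    canvas = np.empty((IMAGE_H, IMAGE_W, 3), dtype=float)
    canvas[:] = skin_rgb
    artifact_mask = np.zeros((IMAGE_H, IMAGE_W), dtype=bool)

    def _noisy(shape, base):
        block = np.tile(np.asarray(base, dtype=float), shape + (1,))
        if params.pixel_noise_sd > 0:
            block += rng.normal(0.0, params.pixel_noise_sd, size=block.shape)
        return block

    for finger, (x, y) in sorted(_NAILBED_XY.items()):
        canvas[y:y + ROI_SIZE, x:x + ROI_SIZE] = _noisy((ROI_SIZE, ROI_SIZE), nail_rgb)
    sx, sy = _SKIN_XY
    canvas[sy:sy + ROI_SIZE, sx:sx + ROI_SIZE] = _noisy((ROI_SIZE, ROI_SIZE), skin_rgb)

    # artifacts only in analyzed (non-thumb) nailbed ROIs, fully inside the ROI
    specs = [(artifacts.leukonychia_radius_px, artifacts.leukonychia_value)] \
        * artifacts.leukonychia_count \
        + [(artifacts.specular_radius_px, artifacts.specular_value)] \
        * artifacts.specular_count
    for radius, value in specs:
        finger = int(rng.integers(2, 6))
        x, y = _NAILBED_XY[finger]
        cx = int(rng.integers(radius, ROI_SIZE - radius))
        cy = int(rng.integers(radius, ROI_SIZE - radius))
        disc = _disc_mask(ROI_SIZE, cx, cy, radius)
        patch = canvas[y:y + ROI_SIZE, x:x + ROI_SIZE]
        patch[disc] = np.asarray(value, dtype=float)
        artifact_mask[y:y + ROI_SIZE, x:x + ROI_SIZE] |= disc

    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    metadata = params.metadata_model.sample(lux, flash, rng)
    return FingernailImage(pixels=pixels, metadata=metadata), artifact_mask


def _generate_session(true_hgb, skin_L, lux, params, artifacts, rng,
                      subject_id, session_index, subject_offset):
    session_eps = rng.normal(0.0, params.hgb_session_sd) if params.hgb_session_sd > 0 else 0.0
    effective = true_hgb + subject_offset + session_eps
    images, masks = [], []
    for flash in (True, False):
        img, mask = _render_image(effective, skin_L, lux, flash, params, artifacts, rng)
        images.append(img)
        masks.append(mask)
    return SyntheticSubject(
        subject_id=subject_id, true_hgb=float(true_hgb), skin_L=float(skin_L),
        lux=float(lux), images=images, roi_annotations=list(DEFAULT_ROIS),
        session_index=session_index, effective_hgb=float(effective),
        artifact_masks=masks,
    )


def generate_subject(true_hgb: float, skin_L: float | None = None,
                     lux: float | None = None,
                     params: ForwardModelParams | None = None,
                     artifacts: ArtifactSpec | None = None,
                     rng_seed: int | np.random.SeedSequence = 0,
                     subject_id: str = "S000") -> SyntheticSubject:
    """Generate one subject: flash-on/off photo pair, ROIs, metadata, truth."""
    if not true_hgb > 0:
        raise ValidationError(f"true_hgb must be > 0, got {true_hgb}")
    params = params or ForwardModelParams()
    artifacts = artifacts or ArtifactSpec.none()
    rng = np.random.default_rng(rng_seed)
    if skin_L is None:
        skin_L = float(rng.uniform(*params.skin_L_range))
    if lux is None:
        lux = float(np.exp(rng.uniform(*np.log(params.lux_range))))
    offset = rng.normal(0.0, params.hgb_offset_sd) if params.hgb_offset_sd > 0 else 0.0
    return _generate_session(true_hgb, skin_L, lux, params, artifacts, rng,
                             subject_id, 1, offset)


def generate_serial_subject(weekly_hgb, params: ForwardModelParams | None = None,
                            artifacts: ArtifactSpec | None = None,
                            rng_seed: int | np.random.SeedSequence = 0,
                            skin_L: float | None = None,
                            lux: float | None = None,
                            subject_id: str = "S000") -> list:
    """One session per week (serial-monitoring study design).

    Subject-level nuisance parameters — skin tone, ambient light, the
    subject's Hgb-scale offset — are held fixed across weeks; the session
    term and channel jitter are redrawn weekly.
    """
    weekly_hgb = list(weekly_hgb)
    if len(weekly_hgb) == 0:
        raise ValidationError("weekly_hgb must not be empty")
    if len(weekly_hgb) < 2:
        raise ValidationError("a serial study needs at least 2 weekly sessions")
    params = params or ForwardModelParams()
    artifacts = artifacts or ArtifactSpec.none()
    rng = np.random.default_rng(rng_seed)
    if skin_L is None:
        skin_L = float(rng.uniform(*params.skin_L_range))
    if lux is None:
        lux = float(np.exp(rng.uniform(*np.log(params.lux_range))))
    offset = rng.normal(0.0, params.hgb_offset_sd) if params.hgb_offset_sd > 0 else 0.0
    sessions = []
    for week, hgb in enumerate(weekly_hgb, start=1):
        if not hgb > 0:
            raise ValidationError(f"weekly_hgb must be > 0, got {hgb}")
        sessions.append(_generate_session(hgb, skin_L, lux, params, artifacts,
                                          rng, subject_id, week, offset))
    return sessions


def _draw_hgb(distribution, n, rng):
    if callable(distribution):
        return np.asarray(distribution(rng, n), dtype=float)
    kind = distribution[0]
    if kind == "uniform":
        return rng.uniform(distribution[1], distribution[2], size=n)
    if kind == "normal":
        return rng.normal(distribution[1], distribution[2], size=n)
    if kind == "point":
        return np.full(n, float(distribution[1]))
    raise ValidationError(f"unknown hgb distribution spec: {distribution!r}")


def iter_cohort(n_subjects: int, hgb_distribution=("uniform", *HGB_RANGE_GDL),
                params: ForwardModelParams | None = None,
                artifacts: ArtifactSpec | None = None,
                rng_seed: int = 0):
    """Yield ``n_subjects`` independent subjects, deterministically seeded.

    Subjects are generated lazily (a rendered photo pair is ~1.8 MB) so large
    cohorts can be consumed one at a time.
    """
    if n_subjects < 2:
        raise ValidationError(f"a cohort needs >= 2 subjects, got {n_subjects}")
    params = params or ForwardModelParams()
    root = np.random.SeedSequence(rng_seed)
    hgb = _draw_hgb(hgb_distribution, n_subjects,
                    np.random.default_rng(root.spawn(1)[0]))
    width = max(3, len(str(n_subjects - 1)))
    for i, child in enumerate(root.spawn(n_subjects + 1)[1:]):
        yield generate_subject(float(hgb[i]), params=params, artifacts=artifacts,
                               rng_seed=child, subject_id=f"S{i:0{width}d}")


def cohort_row(subject: SyntheticSubject, flash_path="", noflash_path="", roi_path="") -> dict:
    return {
        "subject_id": subject.subject_id,
        "session_index": subject.session_index,
        "true_hgb_gdl": subject.true_hgb,
        "skin_L": subject.skin_L,
        "lux": subject.lux,
        "image_flash_path": flash_path,
        "image_noflash_path": noflash_path,
        "roi_json_path": roi_path,
    }


def generate_cohort(n_subjects: int, hgb_distribution=("uniform", *HGB_RANGE_GDL),
                    params: ForwardModelParams | None = None,
                    artifacts: ArtifactSpec | None = None,
                    rng_seed: int = 0,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """Generate a cohort table; with ``out_dir``, also write images to disk.

    On disk the layout is ``images/<id>_s<k>_{flash,noflash}.png`` (+ JSON
    metadata sidecars), ``rois/<id>_s<k>.json`` and ``cohort.csv`` with one
    row per subject-session.  Deterministic given the seed.
    """
    import json as _json

    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "rois").mkdir(parents=True, exist_ok=True)
    for subj in iter_cohort(n_subjects, hgb_distribution, params, artifacts, rng_seed):
        if out_dir is None:
            rows.append(cohort_row(subj))
            continue
        stem = f"{subj.subject_id}_s{subj.session_index}"
        fp = out_dir / "images" / f"{stem}_flash.png"
        np_ = out_dir / "images" / f"{stem}_noflash.png"
        rp = out_dir / "rois" / f"{stem}.json"
        save_image(subj.image_flash, fp)
        save_image(subj.image_noflash, np_)
        with open(rp, "w") as fh:
            _json.dump([r.to_dict() for r in subj.roi_annotations], fh, indent=1)
        rows.append(cohort_row(subj, str(fp.relative_to(out_dir)),
                               str(np_.relative_to(out_dir)),
                               str(rp.relative_to(out_dir))))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "cohort.csv", index=False, float_format="%.10g")
    return table


def true_model_coefficients(params: ForwardModelParams, schema) -> tuple:
    """Ground-truth intercept and weights of the inverse regression.

    Valid for flash-on features (lighting gain 1): effective Hgb =
    ref + (R - R0)/slope_R, so the red-mean weight is 1/slope_R, the
    intercept ref - R0/slope_R, and every other feature has weight 0.
    Only defined when the green/blue Hgb slopes are zero (otherwise the true
    coefficient vector is not unique).
    """
    slope = params.hgb_color_slope
    if slope[1] != 0 or slope[2] != 0:
        raise ValidationError(
            "true coefficients are only well-defined with zero green/blue slopes"
        )
    weights = np.zeros(len(schema))
    names = list(schema)
    weights[names.index("nail_mean_r")] = 1.0 / slope[0]
    constant = params.ref_hgb - params.base_color_at_ref_hgb[0] / slope[0]
    return float(constant), weights
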