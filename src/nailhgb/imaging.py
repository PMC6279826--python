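"""Image I/O, ROI extraction and sRGB/CIELab color conversion.

A fingernail photograph is an 8-bit sRGB raster plus its capture metadata
(exposure time, ISO, aperture, brightness value, flash flag, optionally the
ambient lux reading).  Metadata travels either in EXIF tags (JPEG) or in a
JSON sidecar next to the image file; when both are present the sidecar wins.

Color conversions use the sRGB standard (D65 white point, 2 degree observer)
via scikit-image.  Lightness averaging over a patch is always per-pixel Lab
first, then the mean — the nonlinearity of the Lab transform makes the order
matter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from PIL.TiffImagePlugin import IFDRational
from skimage import color as _skcolor

from .errors import FormatError, GeometryError, MetadataError, ValidationError

# EXIF tag ids (Exif sub-IFD)
_EXIF_IFD = 0x8769
_TAG_EXPOSURE_TIME = 33434
_TAG_F_NUMBER = 33437
_TAG_ISO = 34855
_TAG_BRIGHTNESS_VALUE = 37379
_TAG_FLASH = 37385

SIDECAR_KEYS = (
    "exposure_time_s",
    "iso",
    "f_number",
    "brightness_value_ev",
    "flash_fired",
    "lux",
)


@dataclass(frozen=True)
class CaptureMetadata:
    """Capture parameters recorded alongside a photo.

    ``flash_fired`` is mandatory; the numeric fields may be absent (``None``)
    when the source image carries no such tag — they are never silently
    defaulted.  ``lux`` is an optional ambient light-meter reading.
    """

    flash_fired: bool
    exposure_time: float | None = None  # seconds
    iso: float | None = None
    f_number: float | None = None
    brightness_value: float | None = None  # EV (APEX)
    lux: float | None = None

    def __post_init__(self):
        if self.flash_fired is None:
            raise MetadataError("flash_fired")
        for name in ("exposure_time", "iso", "f_number"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise MetadataError(name, f"{name} must be > 0, got {v}")

    def to_sidecar(self) -> dict:
        return {
            "exposure_time_s": self.exposure_time,
            "iso": self.iso,
            "f_number": self.f_number,
            "brightness_value_ev": self.brightness_value,
            "flash_fired": bool(self.flash_fired),
            "lux": self.lux,
        }

    @classmethod
    def from_sidecar(cls, d: dict) -> "CaptureMetadata":
        if "flash_fired" not in d:
            raise MetadataError("flash_fired")
        return cls(
            flash_fired=bool(d["flash_fired"]),
            exposure_time=d.get("exposure_time_s"),
            iso=d.get("iso"),
            f_number=d.get("f_number"),
            brightness_value=d.get("brightness_value_ev"),
            lux=d.get("lux"),
        )


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest, 0-based, origin top-left.

    The rectangle is half-open: pixels [x, x+w) x [y, y+h).  ``finger`` uses
    the convention thumb = 1 .. little finger = 5; ``kind`` is ``"nailbed"``
    or ``"skin"``.  Protocol ROIs are 30x30 px (900 px^2, ~10 mm^2 on the
    nail).
    """

    finger: int
    kind: str
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.kind not in ("nailbed", "skin"):
            raise ValidationError(f"ROI kind must be 'nailbed' or 'skin', got {self.kind!r}")
        if not (1 <= self.finger <= 5):
            raise ValidationError(f"finger must be in 1..5, got {self.finger}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"ROI must have positive size, got {self.w}x{self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def to_dict(self) -> dict:
        return {"finger": self.finger, "kind": self.kind,
                "x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(finger=int(d["finger"]), kind=str(d["kind"]),
                   x=int(d["x"]), y=int(d["y"]), w=int(d["w"]), h=int(d["h"]))


@dataclass
class FingernailImage:
    """One photograph: HxWx3 uint8 sRGB raster plus capture metadata."""

    pixels: np.ndarray
    metadata: CaptureMetadata
    source_path: str | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValidationError(f"image too small: {px.shape[1]}x{px.shape[0]} (min 64x64)")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _metadata_from_exif(img: Image.Image) -> dict:
    out: dict = {}
    try:
        exif = img.getexif()
    except Exception:
        return out
    if not exif:
        return out
    ifd = exif.get_ifd(_EXIF_IFD)
    def _num(v):
        return float(v) if v is not None else None
    if _TAG_EXPOSURE_TIME in ifd:
        out["exposure_time_s"] = _num(ifd[_TAG_EXPOSURE_TIME])
    if _TAG_ISO in ifd:
        iso = ifd[_TAG_ISO]
        out["iso"] = float(iso[0] if isinstance(iso, (tuple, list)) else iso)
    if _TAG_F_NUMBER in ifd:
        out["f_number"] = _num(ifd[_TAG_F_NUMBER])
    if _TAG_BRIGHTNESS_VALUE in ifd:
        out["brightness_value_ev"] = _num(ifd[_TAG_BRIGHTNESS_VALUE])
    if _TAG_FLASH in ifd:
        # EXIF Flash tag: bit 0 indicates the flash fired
        out["flash_fired"] = bool(int(ifd[_TAG_FLASH]) & 0x1)
    return out


def load_image(path: str | Path) -> FingernailImage:
    """Read a PNG or JPEG photograph together with its capture metadata.

    Metadata is merged from EXIF tags and a ``<name>.json`` sidecar, with the
    sidecar taking precedence field by field.  ``flash_fired`` is mandatory;
    a file with neither source of that flag raises :class:`MetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with Image.open(path) as img:
            img.load()
            meta = _metadata_from_exif(img)
            pixels = np.asarray(img.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    except OSError as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta.update({k: v for k, v in json.load(fh).items() if k in SIDECAR_KEYS})
    if "flash_fired" not in meta:
        raise MetadataError("flash_fired",
                            f"flash_fired missing from EXIF and sidecar for {path}")
    return FingernailImage(
        pixels=pixels,
        metadata=CaptureMetadata.from_sidecar(meta),
        source_path=str(path),
    )


def save_image(image: FingernailImage, path: str | Path, *, exif: bool = False) -> Path:
    """Write a photograph as PNG/JPEG plus a JSON metadata sidecar.

    With ``exif=True`` (JPEG only) the metadata is additionally embedded as
    EXIF rationals, for realism; the sidecar remains the canonical channel.
    """
    path = Path(path)
    img = Image.fromarray(image.pixels)
    kwargs = {}
    if exif and path.suffix.lower() in (".jpg", ".jpeg"):
        md = image.metadata
        ex = Image.Exif()
        ifd = ex.get_ifd(_EXIF_IFD)
        if md.exposure_time is not None:
            frac = _as_rational(md.exposure_time)
            ifd[_TAG_EXPOSURE_TIME] = IFDRational(*frac)
        if md.iso is not None:
            ifd[_TAG_ISO] = int(round(md.iso))
        if md.f_number is not None:
            ifd[_TAG_F_NUMBER] = IFDRational(*_as_rational(md.f_number))
        if md.brightness_value is not None:
            ifd[_TAG_BRIGHTNESS_VALUE] = IFDRational(*_as_rational(md.brightness_value))
        ifd[_TAG_FLASH] = 1 if md.flash_fired else 0
        kwargs["exif"] = ex
    img.save(path, **kwargs)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(image.metadata.to_sidecar(), fh, indent=1, sort_keys=True)
    return path


def _as_rational(x: float, max_den: int = 100_000) -> tuple[int, int]:
    from fractions import Fraction

    f = Fraction(x).limit_denominator(max_den)
    return f.numerator, f.denominator


def extract_roi(image: FingernailImage, roi: ROI) -> np.ndarray:
    """Return the ROI pixel block as an (w*h, 3) array, row-major, unmodified.

    Raises :class:`GeometryError` if the rectangle leaves the image bounds.
    """
    h, w = image.pixels.shape[:2]
    if roi.x < 0 or roi.y < 0 or roi.x + roi.w > w or roi.y + roi.h > h:
        raise GeometryError(
            f"ROI [{roi.x},{roi.x + roi.w})x[{roi.y},{roi.y + roi.h}) outside "
            f"image bounds {w}x{h}"
        )
    block = image.pixels[roi.y:roi.y + roi.h, roi.x:roi.x + roi.w]
    return block.reshape(-1, 3).copy()


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB values to CIE 1976 L*a*b* (D65, 2 degree observer).

    Accepts a single triplet, an (N, 3) block or an (H, W, 3) raster; the
    output has the same shape with channels (L*, a*, b*).
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValidationError(f"expected trailing dimension 3, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("sRGB values must lie in [0, 255]")
    squeeze = arr.ndim == 1
    flat = arr.reshape(1, -1, 3) if arr.ndim <= 2 else arr
    lab = _skcolor.rgb2lab(flat / 255.0)
    lab = lab.reshape(arr.shape)
    return lab[0] if squeeze and lab.ndim > 1 else lab


def lab_to_srgb(lab) -> np.ndarray:
    """Inverse of :func:`srgb_to_lab`; returns float sRGB in [0, 255] (clipped)."""
    arr = np.asarray(lab, dtype=float)
    squeeze = arr.ndim == 1
    flat = arr.reshape(1, -1, 3) if arr.ndim <= 2 else arr
    rgb = np.clip(_skcolor.lab2rgb(flat), 0.0, 1.0) * 255.0
    rgb = rgb.reshape(arr.shape)
    return rgb[0] if squeeze and rgb.ndim > 1 else rgb


def skin_tone_L(image: FingernailImage, skin_roi: ROI) -> float:
    """Mean per-pixel L* over the adjacent-skin patch (skin-tone proxy).

    No quality control is applied to the skin patch.  Passing a nailbed ROI
    is an error: skin tone must come from melanin-bearing skin.
    """
    if skin_roi.kind != "skin":
        raise ValidationError(
            f"skin_tone_L requires a skin ROI, got kind={skin_roi.kind!r}"
        )
    block = extract_roi(image, skin_roi)
    return float(srgb_to_lab(block)[:, 0].mean())
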