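"""End-to-end plumbing: photographs -> QC -> features -> subject records.

A subject record bundles the feature vector extracted from one photo
(flash-on by default — the flash normalizes background lighting and gives
the most accurate measurement), the reference CBC Hgb when known, and the
per-ROI quality-control report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SubjectUnusableError, ValidationError
from .imaging import FingernailImage, ROI, extract_roi, load_image, skin_tone_L
from .model import FULL_SCHEMA, FeatureVector, build_features
from .qc import QCParams, qc_mask, robust_roi_mean

FLASH_POLICIES = ("flash_on", "flash_off")


@dataclass
class SubjectRecord:
    """One subject-session ready for model fitting or prediction."""

    subject_id: str
    feature_vector: FeatureVector
    cbc_hgb: float | None = None
    session_index: int = 1
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cbc_hgb is not None and not self.cbc_hgb > 0:
            raise ValidationError(f"cbc_hgb must be > 0, got {self.cbc_hgb}")


def select_image(images, flash_policy: str = "flash_on") -> FingernailImage:
    if flash_policy not in FLASH_POLICIES:
        raise ValidationError(f"flash_policy must be one of {FLASH_POLICIES}")
    want = flash_policy == "flash_on"
    for img in images:
        if bool(img.metadata.flash_fired) == want:
            return img
    raise ValidationError(f"no image matching flash_policy={flash_policy!r}")


def subject_features(images, rois, qc: QCParams | None = QCParams(),
                     flash_policy: str = "flash_on",
                     schema=FULL_SCHEMA):
    """Extract a subject's feature vector from one photo set.

    ``qc=None`` disables pixel quality control entirely (all pixels kept) —
    useful to quantify what the QC stage buys.  Unusable nailbed ROIs are
    skipped; if none survives, :class:`SubjectUnusableError` carries the
    pooled rejection-reason counts.  Returns ``(FeatureVector, qc_report)``.
    """
    image = select_image(images, flash_policy)
    nailbeds = [r for r in rois if r.kind == "nailbed"]
    skins = [r for r in rois if r.kind == "skin"]
    if len(skins) != 1:
        raise ValidationError(f"expected exactly 1 skin ROI, got {len(skins)}")
    if not nailbeds:
        raise ValidationError("no nailbed ROI provided")

    per_finger = {}
    report = {"rois": [], "flash_policy": flash_policy}
    pooled_reasons: dict = {}
    for roi in nailbeds:
        if roi.finger == 1:       # thumb: excluded from measurement
            continue
        block = extract_roi(image, roi)
        if qc is None:
            from .qc import PixelMask, robust_roi_mean as _rrm
            mask = PixelMask(keep=np.ones(block.shape[0], dtype=bool),
                             rejection_reasons=np.full(block.shape[0], "none"),
                             min_retained_fraction=0.0)
        else:
            mask = qc_mask(block, qc)
        entry = {"finger": roi.finger, "retained_fraction": mask.retained_fraction,
                 "reason_counts": mask.reason_counts(), "usable": mask.usable}
        report["rois"].append(entry)
        for k, v in entry["reason_counts"].items():
            pooled_reasons[k] = pooled_reasons.get(k, 0) + v
        if not mask.usable:
            continue
        per_finger[roi.finger] = robust_roi_mean(block, mask)
    if not per_finger:
        raise SubjectUnusableError(
            "no usable nailbed ROI after quality control", pooled_reasons
        )
    skin_L = skin_tone_L(image, skins[0])
    fv = build_features(per_finger, skin_L, image.metadata, schema=schema)
    report["n_usable_fingers"] = len(per_finger)
    return fv, report


def record_from_subject(subject, qc: QCParams | None = QCParams(),
                        flash_policy: str = "flash_on",
                        schema=FULL_SCHEMA) -> SubjectRecord:
    """Build a :class:`SubjectRecord` from a synthetic (or loaded) subject."""
    fv, report = subject_features(subject.images, subject.roi_annotations,
                                  qc=qc, flash_policy=flash_policy, schema=schema)
    return SubjectRecord(
        subject_id=subject.subject_id,
        feature_vector=fv,
        cbc_hgb=getattr(subject, "true_hgb", None),
        session_index=getattr(subject, "session_index", 1),
        qc_report=report,
    )


def records_from_subjects(subjects, qc: QCParams | None = QCParams(),
                          flash_policy: str = "flash_on",
                          schema=FULL_SCHEMA) -> list:
    """Map an iterable of subjects to records (lazy-friendly: consumes one
    subject at a time so rendered images can be garbage-collected)."""
    return [record_from_subject(s, qc=qc, flash_policy=flash_policy, schema=schema)
            for s in subjects]


def load_cohort(cohort_csv: str | Path, qc: QCParams | None = QCParams(),
                flash_policy: str = "flash_on", schema=FULL_SCHEMA,
                require_cbc: bool = False) -> list:
    """Read a cohort table (as written by the synthetic generator, or any CSV
    with the same columns) and extract one record per row."""
    cohort_csv = Path(cohort_csv)
    base = cohort_csv.parent
    table = pd.read_csv(cohort_csv)
    needed = {"subject_id", "image_flash_path", "image_noflash_path", "roi_json_path"}
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if require_cbc and "true_hgb_gdl" not in table.columns:
        raise ValidationError("cohort table has no CBC column (true_hgb_gdl)")
    records = []
    for _, row in table.iterrows():
        images = [load_image(base / row["image_flash_path"]),
                  load_image(base / row["image_noflash_path"])]
        with open(base / row["roi_json_path"]) as fh:
            rois = [ROI.from_dict(d) for d in json.load(fh)]
        fv, report = subject_features(images, rois, qc=qc,
                                      flash_policy=flash_policy, schema=schema)
        cbc = row.get("true_hgb_gdl")
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            feature_vector=fv,
            cbc_hgb=float(cbc) if cbc is not None and np.isfinite(cbc) else None,
            session_index=int(row.get("session_index", 1)),
            qc_report=report,
        ))
    return records
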