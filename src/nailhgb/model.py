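"""Hemoglobin regression model: feature assembly, robust fit, prediction.

The estimate is a multi-linear form

    Hgb = C + P1*W1 + P2*W2 + ... + Pn*Wn + bias

over nailbed color summaries, the adjacent-skin lightness and capture
metadata.  The weights come from iteratively reweighted least squares with
Tukey bisquare weights (tuning constant 4.685, residual scale 1.4826*MAD),
initialized at ordinary least squares — the redescending weight function
zeroes gross outliers entirely.  A uniform bias adjustment (the mean
discovery residual) is added after the robust fit so that discovery
residuals average exactly zero.

Population training mirrors the screening protocol: the cohort is split
into discovery/testing groups (237/100 by default), the model is fitted on
discovery and evaluated on testing, and the whole procedure is repeated over
many random splits; the split minimizing test mean |residual| is retained as
the screening model, with the full per-repeat distribution reported so the
selection optimism is visible.  Personalized calibration fits a reduced
color-only model to a handful of weekly sessions of a single subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import (
    DegenerateCalibrationError,
    MetadataError,
    SchemaError,
    SingularityError,
    SubjectUnusableError,
    ValidationError,
)
from .imaging import CaptureMetadata
from .qc import ColorFeatures

#: Default feature schema: 6 nailbed color summaries, skin tone, 5 metadata.
FULL_SCHEMA = (
    "nail_mean_r", "nail_mean_g", "nail_mean_b",
    "nail_mean_L", "nail_mean_a", "nail_mean_bstar",
    "skin_L",
    "exposure_time_s", "iso", "f_number", "brightness_value_ev", "flash_fired",
)

#: RGB-only color schema (no nailbed Lab): the Lab summaries are smooth
#: functions of the RGB means, so excluding them gives a well-conditioned
#: design when individual coefficients matter.
RGB_SCHEMA = (
    "nail_mean_r", "nail_mean_g", "nail_mean_b",
    "skin_L",
    "exposure_time_s", "iso", "f_number", "brightness_value_ev", "flash_fired",
)

#: Personal calibration schema: a 4-point calibration cannot identify the
#: full parameter set, so only the Hgb-coupled red nailbed mean enters.
#: Fitting the green/blue means as well on 4 points is exactly determined
#: and inflates test error by interpolating session-to-session imaging
#: variation, which defeats the point of personalization.
PERSONAL_SCHEMA = ("nail_mean_r",)

METADATA_FEATURES = ("exposure_time_s", "iso", "f_number",
                     "brightness_value_ev", "flash_fired")

BISQUARE_C = 4.685
MAD_SCALE = 1.4826
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with their schema."""

    values: tuple
    schema: tuple

    def __post_init__(self):
        if len(self.values) != len(self.schema):
            raise ValidationError(
                f"{len(self.values)} values for {len(self.schema)} schema names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def subset(self, schema) -> "FeatureVector":
        index = {n: i for i, n in enumerate(self.schema)}
        try:
            vals = tuple(self.values[index[n]] for n in schema)
        except KeyError:
            raise SchemaError(schema, self.schema)
        return FeatureVector(values=vals, schema=tuple(schema))


@dataclass
class HgbModel:
    """Fitted model: constant C, weights W, uniform bias adjustment, schema."""

    constant: float
    weights: np.ndarray
    schema: tuple
    bias_adjustment: float = 0.0
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.schema),):
            raise ValidationError("weights length must match schema length")


def build_features(per_finger_colors, skin_L: float, metadata: CaptureMetadata,
                   schema=FULL_SCHEMA) -> FeatureVector:
    """Assemble a subject's feature vector.

    ``per_finger_colors`` maps finger index (1=thumb .. 5) to the QC-filtered
    :class:`ColorFeatures` of that finger's nailbed ROI.  The thumb is always
    excluded; the remaining fingers are averaged unweighted.  Metadata fields
    required by the schema must be present (``None`` raises
    :class:`MetadataError` naming the field).
    """
    if isinstance(per_finger_colors, dict):
        items = sorted(per_finger_colors.items())
    else:
        items = sorted(per_finger_colors)
    usable = [(f, cf) for f, cf in items if f != 1]
    if not usable:
        raise SubjectUnusableError("no usable non-thumb nailbed ROI")
    rgb = np.mean([cf.mean_rgb for _, cf in usable], axis=0)
    lab = np.mean([cf.mean_lab for _, cf in usable], axis=0)
    pool = {
        "nail_mean_r": rgb[0], "nail_mean_g": rgb[1], "nail_mean_b": rgb[2],
        "nail_mean_L": lab[0], "nail_mean_a": lab[1], "nail_mean_bstar": lab[2],
        "skin_L": float(skin_L),
        "exposure_time_s": metadata.exposure_time,
        "iso": metadata.iso,
        "f_number": metadata.f_number,
        "brightness_value_ev": metadata.brightness_value,
        "flash_fired": float(bool(metadata.flash_fired)),
    }
    values = []
    for name in schema:
        if name not in pool:
            raise SchemaError(schema, tuple(pool))
        if pool[name] is None:
            raise MetadataError(name, f"feature {name!r} required by schema is absent")
        values.append(float(pool[name]))
    return FeatureVector(values=tuple(values), schema=tuple(schema))


def _check_design(X1: np.ndarray, names) -> None:
    """Reject zero-variance and collinear columns, naming the offenders."""
    spans = np.ptp(X1[:, 1:], axis=0)
    dead = [names[j] for j in np.nonzero(spans == 0)[0]]
    if dead:
        raise SingularityError(dead, "zero-variance feature columns")
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        # pivoted QR: columns pivoted beyond the numerical rank are the
        # (approximately) linearly dependent ones
        _, _, piv = scipy.linalg.qr(X1, pivoting=True, mode="economic")
        bad = [names[j - 1] for j in piv[rank:] if j >= 1]
        raise SingularityError(bad or list(names))


def fit_robust(X: np.ndarray, y: np.ndarray, schema=None, *,
               c: float = BISQUARE_C, tol: float = IRLS_TOL,
               max_iter: int = IRLS_MAX_ITER,
               allow_rank_deficient: bool = False) -> HgbModel:
    """Robust multi-linear regression via IRLS with Tukey bisquare weights.

    Residuals are standardized by 1.4826 * MAD each iteration; observations
    with |standardized residual| >= c get zero weight.  Iterates from the
    OLS solution until the maximum coefficient change is below ``tol``
    (relative to the coefficient magnitude) or ``max_iter`` is reached; a
    non-converged fit carries ``converged=False`` in ``fit_info`` and emits
    a warning.  ``allow_rank_deficient`` switches to minimum-norm least
    squares and skips the design checks (used by saturated personal fits).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    schema = tuple(schema) if schema is not None else tuple(f"x{j}" for j in range(p))
    if len(schema) != p:
        raise ValidationError("schema length must match number of columns")
    if not allow_rank_deficient and n <= p + 1:
        raise ValidationError(f"need n > p + 1 observations, got n={n}, p={p}")
    if n < p:
        raise ValidationError(f"underdetermined fit: n={n} < p={p}")
    X1 = np.column_stack([np.ones(n), X])
    if not allow_rank_deficient:
        _check_design(X1, schema)

    def _lstsq(A, b):
        return np.linalg.lstsq(A, b, rcond=None)[0]

    beta = _lstsq(X1, y)
    converged = False
    scale = 0.0
    w = np.ones(n)
    iterations = 0
    # With fewer than ~p+1 residual degrees of freedom the MAD scale is
    # meaningless and the reweighting just chases noise; fall back to the
    # least-squares solution (relevant for saturated personal calibrations).
    reweighted = n > 2 * (p + 1)
    for iterations in range(1, max_iter + 1) if reweighted else ():
        r = y - X1 @ beta
        scale = MAD_SCALE * np.median(np.abs(r - np.median(r)))
        if scale < 1e-10 * max(1.0, float(np.median(np.abs(y)))):
            converged = True  # (near-)exact fit; weights stay at 1
            w = np.ones(n)
            break
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        sw = np.sqrt(w)
        beta_new = _lstsq(X1 * sw[:, None], y * sw)
        if np.max(np.abs(beta_new - beta)) <= tol * max(1.0, np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not reweighted:
        converged = True
    if not converged:
        warnings.warn("bisquare IRLS did not converge; returning last iterate",
                      RuntimeWarning, stacklevel=2)
    fit_info = {
        "iterations": iterations,
        "converged": bool(converged),
        "reweighted": bool(reweighted),
        "tuning_constant": c,
        "scale": float(scale),
        "n": int(n),
        "p": int(p),
        "robust_weights_min": float(w.min()),
        "robust_weights_mean": float(w.mean()),
        "n_zero_weight": int(np.sum(w == 0)),
    }
    return HgbModel(constant=float(beta[0]), weights=beta[1:], schema=schema,
                    bias_adjustment=0.0, fit_info=fit_info)


def predict_matrix(model: HgbModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.schema):
        raise SchemaError(model.schema, tuple(f"x{j}" for j in range(X.shape[1])))
    return model.constant + X @ model.weights + model.bias_adjustment


def predict(model: HgbModel, fv: FeatureVector) -> float:
    """Predict Hgb (g/dL, full precision) for one feature vector."""
    if tuple(fv.schema) != tuple(model.schema):
        if set(fv.schema) >= set(model.schema):
            fv = fv.subset(model.schema)
        else:
            raise SchemaError(model.schema, fv.schema)
    return float(predict_matrix(model, fv.as_array()[None, :])[0])


def display_hgb(value: float) -> float:
    """User-facing rounding: CBC convention, 0.1 g/dL."""
    return round(float(value), 1)


def bias_adjust(model: HgbModel, X_discovery: np.ndarray,
                y_discovery: np.ndarray) -> HgbModel:
    """Add the uniform bias adjustment estimated on the discovery set.

    After adjustment the discovery residuals average exactly zero.
    """
    y = np.asarray(y_discovery, dtype=float)
    if y.size == 0:
        raise ValidationError("empty discovery set")
    raw = predict_matrix(model, X_discovery) - model.bias_adjustment
    adjustment = float(np.mean(y - raw))
    return HgbModel(constant=model.constant, weights=model.weights.copy(),
                    schema=model.schema, bias_adjustment=adjustment,
                    fit_info=dict(model.fit_info))


@dataclass
class SplitResult:
    """One discovery/testing repeat of population training."""

    repeat_index: int
    discovery_ids: list
    test_ids: list
    model: HgbModel
    test_residuals: np.ndarray   # predicted - reference, g/dL
    test_mae: float
    test_loa: float              # 1.96 * sd of test residuals
    test_bias: float


@dataclass
class TrainResult:
    best: SplitResult
    summary: pd.DataFrame        # one row per repeat
    schema: tuple
    pruned_features: tuple       # zero-variance columns removed pre-fit
    n_repeats: int
    seed: int | None


def _design_from_records(records, schema):
    ids, X, y = [], [], []
    for rec in records:
        fv = rec.feature_vector
        if tuple(fv.schema) != tuple(schema):
            fv = fv.subset(schema)
        X.append(fv.as_array())
        y.append(rec.cbc_hgb)
        ids.append(rec.subject_id)
    return ids, np.asarray(X), np.asarray(y, dtype=float)


def train_population(records, n_repeats: int = 1000, discovery_n: int = 237,
                     rng_seed: int | None = 0, schema=FULL_SCHEMA) -> TrainResult:
    """Repeated discovery/testing training of the screening model.

    Each repeat draws a without-replacement split (``discovery_n`` subjects
    for discovery, the remainder for testing — with the defaults, 237/100 on
    a 337-subject cohort), fits the robust model plus bias adjustment on
    discovery, and scores residuals on testing.  The repeat with minimum
    test mean |residual| is returned as ``best``, alongside the per-repeat
    summary.  Constant feature columns (e.g. a fixed aperture) are pruned
    before fitting and recorded.
    """
    records = list(records)
    n = len(records)
    if any(rec.cbc_hgb is None for rec in records):
        raise ValidationError("population training requires CBC Hgb for every record")
    if n < discovery_n + 1:
        raise ValidationError(
            f"cohort of {n} too small for discovery_n={discovery_n} (+>=1 test subject)"
        )
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    ids, X, y = _design_from_records(records, schema)
    if len(set(ids)) != n:
        raise ValidationError("duplicate subject ids across records (split leakage)")
    spans = np.ptp(X, axis=0)
    keep = spans > 0
    pruned = tuple(name for name, k in zip(schema, keep) if not k)
    schema_used = tuple(name for name, k in zip(schema, keep) if k)
    X = X[:, keep]

    rng = np.random.default_rng(rng_seed)
    rows = []
    best = None
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        disc, test = perm[:discovery_n], perm[discovery_n:]
        model = fit_robust(X[disc], y[disc], schema=schema_used)
        model = bias_adjust(model, X[disc], y[disc])
        resid = predict_matrix(model, X[test]) - y[test]
        mae = float(np.mean(np.abs(resid)))
        loa = float(1.96 * np.std(resid, ddof=1))
        bias = float(np.mean(resid))
        rows.append({"repeat_index": rep, "test_mae": mae, "test_loa": loa,
                     "test_bias": bias})
        if best is None or mae < best.test_mae:
            best = SplitResult(
                repeat_index=rep,
                discovery_ids=[ids[i] for i in disc],
                test_ids=[ids[i] for i in test],
                model=model, test_residuals=resid,
                test_mae=mae, test_loa=loa, test_bias=bias,
            )
    return TrainResult(best=best, summary=pd.DataFrame(rows),
                       schema=schema_used, pruned_features=pruned,
                       n_repeats=n_repeats, seed=rng_seed)


def calibrate_personal(sessions, schema=PERSONAL_SCHEMA) -> HgbModel:
    """Fit a personal calibration model from one subject's weekly sessions.

    With 4 calibration sessions and the 3-feature color schema the fit is
    exactly determined; minimum-norm least squares keeps it well-defined
    even when a color channel barely varies.  With fewer sessions the schema
    truncates to the first ``n_sessions - 1`` features.  All-identical
    calibration Hgb values leave the slope unidentifiable and raise
    :class:`DegenerateCalibrationError`.
    """
    sessions = list(sessions)
    if len(sessions) < 2:
        raise ValidationError("personal calibration needs >= 2 sessions")
    y = np.array([s.cbc_hgb for s in sessions], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError("personal calibration requires CBC Hgb for every session")
    if np.ptp(y) == 0:
        raise DegenerateCalibrationError(
            "all calibration Hgb values identical; slope unidentifiable"
        )
    schema_used = tuple(schema)[:max(1, min(len(schema), len(sessions) - 1))]
    _, X, y = _design_from_records(sessions, schema_used)
    model = fit_robust(X, y, schema=schema_used, allow_rank_deficient=True)
    model.fit_info["personal"] = True
    return model


# ---------------------------------------------------------------------------
# model file I/O

def save_model(model: HgbModel, path: str | Path, seed: int | None = None) -> Path:
    path = Path(path)
    payload = {
        "schema": list(model.schema),
        "constant": model.constant,
        "weights": [float(w) for w in model.weights],
        "bias_adjustment": model.bias_adjustment,
        "fit_info": model.fit_info,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path


def load_model(path: str | Path) -> HgbModel:
    with open(path) as fh:
        payload = json.load(fh)
    return HgbModel(
        constant=float(payload["constant"]),
        weights=np.asarray(payload["weights"], dtype=float),
        schema=tuple(payload["schema"]),
        bias_adjustment=float(payload.get("bias_adjustment", 0.0)),
        fit_info=dict(payload.get("fit_info", {})),
    )
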