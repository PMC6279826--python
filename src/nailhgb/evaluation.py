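"""Agreement and diagnostic-performance statistics.

The assessment suite for a candidate hemoglobin measurement against the CBC
reference: Bland-Altman bias and 95% limits of agreement (LoA), a
random-effects variant for repeated measures, ROC/AUC for anemia screening
at a stated Hgb cutoff, sensitivity/specificity with efficient-score
(Wilson) confidence intervals, the two-way random-effects intraclass
correlation ICC(2,1), Pearson correlation, and the fraction of measurements
within the CLIA allowable total error of +/-7%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

LOA_Z = 1.96  # 95% limits of agreement multiplier


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    sd_source: str               # "pooled" | "random_effects"
    r_residual_vs_mean: float
    n: int

    def __post_init__(self):
        if self.loa_low > self.loa_high:
            raise ValidationError("loa_low must not exceed loa_high")


@dataclass(frozen=True)
class DiagnosticReport:
    auc: float
    sensitivity: float
    specificity: float
    ci_sensitivity: tuple
    ci_specificity: tuple
    cutoff: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ICCReport:
    icc: float
    ci: tuple
    n_subjects: int
    n_raters: int


def _paired(pred, ref):
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValidationError(
            f"pred and ref must be equal-length 1-D, got {pred.shape} vs {ref.shape}"
        )
    return pred, ref


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValidationError("pearson_r needs >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(_sps.pearsonr(x, y).statistic)


def bland_altman(pred, ref) -> AgreementReport:
    """Bland-Altman agreement: bias = mean(pred - ref), LoA = bias +/- 1.96 sd.

    Also reports the Pearson correlation between the difference and the
    pairwise mean (proportional-bias check; 0 when error is independent of
    level).
    """
    pred, ref = _paired(pred, ref)
    if pred.size < 3:
        raise ValidationError("bland_altman needs >= 3 pairs")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (pred + ref) / 2.0
    r = 0.0 if (np.std(d) == 0 or np.std(means) == 0) else float(
        _sps.pearsonr(d, means).statistic)
    return AgreementReport(bias=bias, loa_low=bias - LOA_Z * sd,
                           loa_high=bias + LOA_Z * sd, sd=sd,
                           sd_source="pooled", r_residual_vs_mean=r, n=pred.size)


def loa_random_effects(pred, ref, subject_ids) -> AgreementReport:
    """Limits of agreement for repeated measures via a one-way random-effects
    decomposition of the differences d_ij = mu + b_i + e_ij.

    The within-subject variance is the pooled within-group variance; the
    between-subject variance is the population variance of subject means
    minus its within-subject sampling share, floored at zero.  LoA = mu +/-
    1.96 * sqrt(sigma_b^2 + sigma_w^2), so intra-patient variability from
    repeated measurements of the same subject is counted once, not n times.
    With a single subject this degenerates to plain Bland-Altman (with a
    warning).
    """
    pred, ref = _paired(pred, ref)
    subject_ids = np.asarray(subject_ids)
    if subject_ids.shape != pred.shape:
        raise ValidationError("subject_ids must match pred/ref length")
    d = pred - ref
    groups = [d[subject_ids == s] for s in np.unique(subject_ids)]
    k = len(groups)
    if k < 2:
        warnings.warn("single subject: falling back to Bland-Altman LoA",
                      RuntimeWarning, stacklevel=2)
        return bland_altman(pred, ref)
    if max(len(g) for g in groups) < 2:
        warnings.warn("no subject has repeated measures; within-variance is 0",
                      RuntimeWarning, stacklevel=2)
    N = d.size
    mu = float(d.mean())
    means = np.array([g.mean() for g in groups])
    sizes = np.array([len(g) for g in groups], dtype=float)
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    sigma_w2 = ssw / (N - k) if N > k else 0.0
    v_means = float(((means - means.mean()) ** 2).mean())
    sigma_b2 = max(0.0, v_means - sigma_w2 * float(np.mean(1.0 / sizes)))
    sd = float(np.sqrt(sigma_b2 + sigma_w2))
    r = 0.0
    m = (pred + ref) / 2.0
    if np.std(d) > 0 and np.std(m) > 0:
        r = float(_sps.pearsonr(d, m).statistic)
    return AgreementReport(bias=mu, loa_low=mu - LOA_Z * sd,
                           loa_high=mu + LOA_Z * sd, sd=sd,
                           sd_source="random_effects", r_residual_vs_mean=r, n=N)


def _anemia_labels(ref_hgb, cutoff):
    ref = np.asarray(ref_hgb, dtype=float)
    labels = ref < cutoff        # anemic = positive; ties at cutoff non-anemic
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"both classes required at cutoff {cutoff} g/dL "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    return labels, n_pos, n_neg


def roc_auc(pred_hgb, ref_hgb, cutoff: float):
    """ROC area for anemia screening at ``cutoff``.

    Positive class is reference Hgb strictly below the cutoff; the score is
    the negated predicted Hgb (lower predicted Hgb = more anemic).  The AUC
    is the Mann-Whitney pairwise probability with ties counted 1/2.
    Returns ``(auc, fpr, tpr)``.
    """
    pred, ref = _paired(pred_hgb, ref_hgb)
    labels, _, _ = _anemia_labels(ref, cutoff)
    score = -pred
    auc = float(roc_auc_score(labels, score))
    fpr, tpr, _ = roc_curve(labels, score)
    return auc, fpr, tpr


def wilson_interval(k: int, n: int, alpha: float = 0.05,
                    continuity: bool = False) -> tuple:
    """Efficient-score (Wilson) confidence interval for a binomial proportion."""
    if n <= 0 or not (0 <= k <= n):
        raise ValidationError(f"invalid counts k={k}, n={n}")
    if not continuity:
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        return float(lo), float(hi)
    z = _sps.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 2 * (n + z ** 2)
    lo = (2 * n * p + z ** 2 - 1 - z * np.sqrt(
        z ** 2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    hi = (2 * n * p + z ** 2 + 1 + z * np.sqrt(
        z ** 2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    if p == 0:
        lo = 0.0
    if p == 1:
        hi = 1.0
    return float(max(0.0, lo)), float(min(1.0, hi))


def sens_spec(pred_hgb, ref_hgb, cutoff: float, *,
              continuity: bool = False) -> DiagnosticReport:
    """Sensitivity/specificity of the anemia call at ``cutoff``, with 95%
    efficient-score (Wilson) intervals.

    The test is positive when the predicted Hgb is strictly below the
    cutoff; disease status comes from the reference the same way.
    """
    pred, ref = _paired(pred_hgb, ref_hgb)
    labels, n_pos, n_neg = _anemia_labels(ref, cutoff)
    test_pos = pred < cutoff
    tp = int(np.sum(test_pos & labels))
    tn = int(np.sum(~test_pos & ~labels))
    sens = tp / n_pos
    spec = tn / n_neg
    auc = float(roc_auc_score(labels, -pred))
    return DiagnosticReport(
        auc=auc, sensitivity=float(sens), specificity=float(spec),
        ci_sensitivity=wilson_interval(tp, n_pos, continuity=continuity),
        ci_specificity=wilson_interval(tn, n_neg, continuity=continuity),
        cutoff=float(cutoff), n_pos=n_pos, n_neg=n_neg,
    )


def icc2_1(ratings: np.ndarray) -> ICCReport:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix (no imputation:
    missing cells are an error).  The point estimate comes from the two-way
    ANOVA mean squares; the 95% CI uses the standard F-based interval.
    """
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects x raters matrix")
    if np.any(~np.isfinite(M)):
        raise ValidationError("ratings matrix has missing cells")
    n, k = M.shape
    if n < 5 or k < 2:
        raise ValidationError(f"need >= 5 subjects and >= 2 raters, got {n}x{k}")
    grand = M.mean()
    msr = k * ((M.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((M.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((M - grand) ** 2).sum()
    sse = sst - (n - 1) / k * msr * k - (k - 1) * msc
    # (equivalently SST - SSR - SSC); guard tiny negatives from rounding
    sse = max(sse, 0.0)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0

    alpha = 0.05
    if mse == 0:
        # error-free ratings: the F-based interval degenerates
        ci = (float(icc), float(icc)) if icc < 1.0 else (1.0, 1.0)
    else:
        fj = msc / mse if mse > 0 else np.inf
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 \
            + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd if vd > 0 else 1.0
        f2u = _sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = _sps.f.ppf(1 - alpha / 2, v, n - 1)
        lb = n * (msr - f2u * mse) / (
            f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
        ub = n * (f2l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2l * msr)
        ci = (float(np.clip(lb, -1, 1)), float(np.clip(ub, -1, 1)))
    return ICCReport(icc=float(icc), ci=ci, n_subjects=n, n_raters=k)


def clia_fraction(pred, ref, tolerance_pct: float = 7.0) -> float:
    """Fraction of measurements within the CLIA allowable total error.

    A pair counts as acceptable when |pred - ref| <= tolerance_pct% of the
    reference (boundary inclusive).
    """
    pred, ref = _paired(pred, ref)
    if np.any(ref <= 0):
        raise ValidationError("reference Hgb must be positive")
    return float(np.mean(np.abs(pred - ref) <= tolerance_pct / 100.0 * ref))


def error_reduction(pred_with_qc: float, pred_without_qc: float,
                    ref: float) -> float:
    """Relative reduction in absolute error achieved by quality control.

    (|e_without| - |e_with|) / |e_without| for a single measurement made with
    and without the QC stage against the same reference.
    """
    e_with = abs(float(pred_with_qc) - float(ref))
    e_without = abs(float(pred_without_qc) - float(ref))
    if e_without == 0:
        raise ValidationError("error reduction undefined: zero baseline error")
    return (e_without - e_with) / e_without


def evaluate_predictions(pred, ref, cutoffs=(11.0, 12.5), subject_ids=None,
                         clia_tolerance_pct: float = 7.0) -> dict:
    """Full evaluation block: agreement + correlation + CLIA + diagnostics.

    Diagnostics that cannot be computed at a cutoff (single-class cohort)
    are reported as ``None`` with the reason; the agreement block is always
    emitted.  With ``subject_ids`` containing repeats, the LoA switches to
    the random-effects estimator.
    """
    pred, ref = _paired(pred, ref)
    if subject_ids is not None and len(np.unique(subject_ids)) < len(pred):
        agreement = loa_random_effects(pred, ref, subject_ids)
    else:
        agreement = bland_altman(pred, ref)
    out = {
        "agreement": agreement,
        "pearson_r": pearson_r(pred, ref),
        "mean_abs_error": float(np.mean(np.abs(pred - ref))),
        "clia_within_fraction": clia_fraction(pred, ref, clia_tolerance_pct),
        "n": int(pred.size),
        "diagnostics": {},
    }
    for cutoff in cutoffs:
        try:
            out["diagnostics"][cutoff] = sens_spec(pred, ref, cutoff)
        except ValidationError as exc:
            out["diagnostics"][cutoff] = {"not_computable": str(exc)}
    return out


# ---------------------------------------------------------------------------
# optional plot conveniences (numbers above are the contract)

def plot_bland_altman(pred, ref, path):
    """Write a Bland-Altman scatter with bias and LoA lines to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred, ref = _paired(pred, ref)
    rep = bland_altman(pred, ref)
    m, d = (pred + ref) / 2.0, pred - ref
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=12, alpha=0.6)
    ax.axhline(rep.bias, color="k")
    for y in (rep.loa_low, rep.loa_high):
        ax.axhline(y, color="r")
    ax.set_xlabel("mean of methods (g/dL)")
    ax.set_ylabel("difference (g/dL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_roc(pred_hgb, ref_hgb, cutoff, path):
    """Write the ROC curve at ``cutoff`` to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    auc, fpr, tpr = roc_auc(pred_hgb, ref_hgb, cutoff)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, "k-", label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "r--", label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
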