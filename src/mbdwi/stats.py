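"""Cohort-level statistics for imaging-biomarker response prediction.

Covers group comparison (pooled-variance two-sample t test, chi-square /
Fisher for categorical covariates), inter-observer agreement (Lin's
concordance correlation coefficient with the conventional good/moderate/
poor bands), ROC analysis with a Youden-index cutoff and DeLong
confidence interval, and the DeLong paired test for comparing two AUCs
measured on the same patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "AgreementResult",
    "RocResult",
    "lin_ccc",
    "ccc_band",
    "two_group_t",
    "categorical_test",
    "roc_analysis",
    "compare_auc",
    "binormal_auc",
    "parameter_comparison_table",
    "roc_table",
]

RESPONDER = "responder"


@dataclass(frozen=True)
class AgreementResult:
    """Lin's CCC and its qualitative agreement band."""

    ccc: float
    band: Literal["good", "moderate", "poor"]


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one biomarker.

    ``orientation`` records which direction of the biomarker predicts a
    responder ("lower" or "higher"); sensitivity and specificity are
    evaluated at the Youden-optimal ``cutoff``.
    """

    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: str


def ccc_band(ccc: float) -> str:
    """good > 0.75; moderate in (0.40, 0.75]; poor < 0.40.

    The boundary value 0.40 itself is assigned to "moderate".
    """
    if ccc > 0.75:
        return "good"
    if ccc >= 0.40:
        return "moderate"
    return "poor"


def lin_ccc(x, y) -> AgreementResult:
    """Lin's concordance correlation coefficient between two readers.

    ccc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n)
    moments.  Unlike Pearson's r it penalises location and scale shifts,
    so |ccc| ≤ |r| always.  Undefined (NaN) when both readers are
    constant with equal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    sx2 = x.var()   # population (1/n) variance
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        return AgreementResult(float("nan"), "poor")
    ccc = float(2.0 * sxy / denom)
    return AgreementResult(ccc, ccc_band(ccc))


def two_group_t(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed two-sample t test.

    Student's pooled-variance form by default; ``welch=True`` drops the
    equal-variance assumption.  Returns (t, p); a zero pooled variance is
    degenerate and yields (nan, nan) unless the means differ, in which
    case (inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return float("nan"), float("nan")
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def categorical_test(table) -> float:
    """Chi-square test of independence for a 2×k contingency table,
    falling back to Fisher's exact test for 2×2 tables with any expected
    count below 5.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold non-negative integer counts")
    if table.sum() == 0:
        raise ValueError("contingency table is all zeros")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and np.any(expected < 5):
        _, p = sps.fisher_exact(table)
    return float(p)


def _scores(values: np.ndarray, orientation: str) -> np.ndarray:
    return -values if orientation == "lower" else values


def _delong_components(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative).

    Midrank formulation, O((m+n)·log(m+n)); ties contribute 1/2 exactly
    as in the pairwise definition psi = 1[x>y] + ½·1[x=y].
    """
    m, n = len(pos_scores), len(neg_scores)
    r_all = sps.rankdata(np.concatenate([pos_scores, neg_scores]))
    r_pos = sps.rankdata(pos_scores)
    r_neg = sps.rankdata(neg_scores)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def _delong_variance(pos_scores, neg_scores) -> float:
    v10, v01 = _delong_components(pos_scores, neg_scores)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(
    values,
    groups,
    orientation: Literal["lower", "higher", "auto"] = "auto",
) -> RocResult:
    """Empirical ROC of a biomarker for predicting responder status.

    The AUC is the trapezoid area under the empirical ROC, identical to
    the normalised Mann–Whitney U statistic.  The cutoff maximises
    Youden's J = sensitivity + specificity − 1, reported as the midpoint
    between the adjacent observed values; ties in J are broken toward
    higher sensitivity, then toward the lower threshold.  The 95% CI uses the DeLong variance with a
    normal approximation, clipped to [0, 1].

    ``orientation="auto"`` picks the direction giving AUC ≥ 0.5.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    is_pos = groups == RESPONDER
    if not is_pos.any() or is_pos.all():
        raise ValueError("both responder and non-responder groups must be non-empty")

    if orientation == "auto":
        auc_hi = roc_auc_score(is_pos, values)
        orientation = "higher" if auc_hi >= 0.5 else "lower"
    scores = _scores(values, orientation)

    if np.unique(values).size == 1:
        return RocResult(0.5, (float("nan"), float("nan")), float("nan"),
                         float("nan"), float("nan"), orientation)

    auc = float(roc_auc_score(is_pos, scores))
    var = _delong_variance(scores[is_pos], scores[~is_pos])
    half = 1.959963984540054 * np.sqrt(var)
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))

    # Youden scan over midpoints between adjacent observed values
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    pos_sorted = np.sort(values[is_pos])
    neg_sorted = np.sort(values[~is_pos])
    m, n = len(pos_sorted), len(neg_sorted)
    if orientation == "lower":
        sens_all = np.searchsorted(pos_sorted, mids) / m
        spec_all = (n - np.searchsorted(neg_sorted, mids)) / n
    else:
        sens_all = (m - np.searchsorted(pos_sorted, mids)) / m
        spec_all = np.searchsorted(neg_sorted, mids) / n
    j_all = sens_all + spec_all - 1.0
    # maximise J, then sensitivity, then take the lower threshold
    order = np.lexsort((mids, -sens_all, -j_all))
    i = order[0]
    return RocResult(auc, ci, float(mids[i]), float(sens_all[i]),
                     float(spec_all[i]), orientation)


def compare_auc(values_a, values_b, groups) -> float:
    """DeLong paired test comparing the AUCs of two biomarkers measured
    on the same patients.  Returns the two-tailed p-value.

    Both biomarkers are oriented so that higher score predicts responder
    (AUC ≥ 0.5) before comparison, matching how ROC curves of oppositely
    signed biomarkers are compared in practice.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    groups = np.asarray(groups)
    if a.shape != b.shape or a.shape != groups.shape:
        raise ValueError("both biomarkers must be measured on the same patients")
    is_pos = groups == RESPONDER
    if not is_pos.any() or is_pos.all():
        raise ValueError("both groups must be non-empty")

    aucs, v10s, v01s = [], [], []
    for v in (a, b):
        if roc_auc_score(is_pos, v) < 0.5:
            v = -v
        v10, v01 = _delong_components(v[is_pos], v[~is_pos])
        aucs.append(v10.mean())
        v10s.append(v10)
        v01s.append(v01)
    m, n = int(is_pos.sum()), int((~is_pos).sum())
    s10 = np.cov(np.vstack(v10s), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack(v01s), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 1.0 if np.isclose(aucs[0], aucs[1]) else 0.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z)))


def binormal_auc(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form AUC for two normal populations:
    Φ(|μ₁−μ₂| / sqrt(σ₁² + σ₂²)).  Serves as the analytic reference for
    validating the empirical ROC on large simulated cohorts.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    return float(sps.norm.cdf(abs(mean1 - mean2) / np.hypot(sd1, sd2)))


# ---------------------------------------------------------------------------
# report tables

# reporting order and scale of the biomarker columns
PARAMETER_ORDER = ("adc", "d", "d_star", "f", "alpha", "ddc")
PARAMETER_LABELS = {
    "adc": "ADC (10^-3 mm^2/s)",
    "d": "D (10^-3 mm^2/s)",
    "d_star": "D* (10^-3 mm^2/s)",
    "f": "f (%)",
    "alpha": "alpha (unitless)",
    "ddc": "DDC (10^-3 mm^2/s)",
}
ROC_PARAMETERS = ("adc", "d", "alpha", "ddc")


def parameter_comparison_table(cohort: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Group means ± SD and t-test p per biomarker (responders vs
    non-responders), on the reporting scale the cohort table carries."""
    rows = []
    for p in PARAMETER_ORDER:
        if p not in cohort.columns:
            continue
        a = cohort.loc[cohort["group"] == RESPONDER, p].to_numpy(float)
        b = cohort.loc[cohort["group"] != RESPONDER, p].to_numpy(float)
        t, pval = two_group_t(a, b, welch=welch)
        rows.append((PARAMETER_LABELS[p],
                     f"{a.mean():.3f} ± {a.std(ddof=1):.3f}",
                     f"{b.mean():.3f} ± {b.std(ddof=1):.3f}",
                     round(pval, 4)))
    return pd.DataFrame(rows, columns=["parameter", "responders", "non_responders", "p_value"])


def roc_table(cohort: pd.DataFrame, parameters=ROC_PARAMETERS) -> pd.DataFrame:
    """ROC summary per biomarker: cutoff, AUC (95% CI), sensitivity,
    specificity, orientation."""
    rows = []
    for p in parameters:
        if p not in cohort.columns:
            continue
        r = roc_analysis(cohort[p].to_numpy(float), cohort["group"].to_numpy())
        rows.append((PARAMETER_LABELS[p], round(r.cutoff, 3), round(r.auc, 3),
                     f"({r.ci95[0]:.3f}-{r.ci95[1]:.3f})",
                     f"{100 * r.sensitivity:.1f}%", f"{100 * r.specificity:.1f}%",
                     r.orientation))
    return pd.DataFrame(rows, columns=["parameter", "cutoff", "auc", "ci95",
                                       "sensitivity", "specificity",
                                       "responder_direction"])
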