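"""Lesion-level response labeling and the inference layer.

Response categories follow diameter-based criteria (RECIST 1.1 style): a
>= 30% diameter reduction (or disappearance) is responding, a >= 20% increase
is progressing, anything between is stable; responding and stable lesions
form the favorable binary outcome, progressing lesions the nonresponding one.

Group comparisons use the Mann-Whitney U test (exact enumeration for small
untied samples, tie-corrected normal approximation with continuity correction
otherwise), classification uses unregularized maximum-likelihood logistic
regression, and discrimination is summarized by ROC/AUC with a seeded,
class-stratified percentile bootstrap CI. Lesions are treated as independent
units; patient-level clustering is a documented limitation, not modeled.
P values are reported unadjusted by default, with optional Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "classify_response",
    "binarize_outcome",
    "mann_whitney",
    "LogisticFit",
    "logistic_fit",
    "RocResult",
    "roc_auc",
    "rank_auc",
    "metric_comparison_table",
    "frequency_table",
    "TABLE_METRICS",
]

RESPONSE_REDUCTION = -0.30  # partial-response boundary on fractional diameter change
PROGRESSION_INCREASE = 0.20
EXACT_MW_MAX_N = 12  # combined sample size up to which the exact null is enumerated

TABLE_METRICS = (
    "suv_mean",
    "suv_median",
    "suv_max",
    "adc_mean",
    "tbr_mean",
    "tbr_max",
    "suv_max_normal_breast",
    "suv_mean_adc_low",
    "suv_mean_adc_high",
)


def classify_response(baseline_mm: float, followup_mm: float) -> str:
    """Categorize one lesion from baseline and follow-up longest diameters (mm)."""
    if baseline_mm <= 0:
        raise ValueError("baseline diameter must be positive")
    if followup_mm < 0:
        raise ValueError("follow-up diameter must be nonnegative")
    if followup_mm == 0:
        return "responding"
    change = (followup_mm - baseline_mm) / baseline_mm
    if change <= RESPONSE_REDUCTION:
        return "responding"
    if change >= PROGRESSION_INCREASE:
        return "progressing"
    return "stable"


def binarize_outcome(category: str) -> str:
    """Collapse the three categories to the favorable/nonresponding outcome."""
    if category in ("responding", "stable"):
        return "favorable"
    if category == "progressing":
        return "nonresponding"
    raise ValueError(f"unknown response category: {category!r}")


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U_a, p).

    U_a counts (a, b) pairs with a > b plus half the ties. The p value is by
    exact enumeration of all label assignments when the combined sample is
    small (<= 12) and untied, otherwise by the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size + b.size <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LogisticFit:
    """Unregularized ML logistic fit; ``separation_flag`` marks quasi/complete
    separation (coefficients diverge; the fitted ranking remains usable for ROC)."""

    intercept: float
    coefficients: np.ndarray
    fitted_probabilities: np.ndarray
    feature_names: list[str]
    converged: bool
    separation_flag: bool


def logistic_fit(features, outcome, feature_names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on metrics.

    ``features`` is (n, p) (a 1-D array is one feature); ``outcome`` is 0/1.
    Zero-variance features are dropped (coefficient 0, warning) so the fit
    stays identified; with no informative feature the model reduces to the
    intercept log(p/(1-p)). Complete separation is detected and flagged
    rather than raised.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.unique(y, return_counts=True)[1].min() < 2:
        raise ValueError("need at least 2 lesions per outcome class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]

    informative = X.std(axis=0) > 0
    for j in np.flatnonzero(~informative):
        warnings.warn(f"feature {names[j]!r} is constant; coefficient set to 0")

    coefs = np.zeros(X.shape[1])
    separation = False
    converged = True
    if informative.any():
        design = sm.add_constant(X[:, informative])
        model = sm.Logit(y.astype(float), design)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fit = model.fit(disp=0, maxiter=200, tol=1e-8)
                params = np.asarray(fit.params)
                converged = bool(fit.mle_retvals.get("converged", True))
            except PerfectSeparationError:
                separation = True
                fit = model.fit(disp=0, method="bfgs", maxiter=100)
                params = np.asarray(fit.params)
                converged = False
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            separation = True
        if np.abs(params).max() > 1e3:  # diverging coefficients: quasi-separation
            separation = True
        intercept = float(params[0])
        coefs[informative] = params[1:]
        probs = np.asarray(fit.predict(design))
    else:
        p = float(y.mean())
        intercept = float(np.log(p / (1 - p)))
        probs = np.full(y.shape, p)
    return LogisticFit(intercept, coefs, probs, names, converged, separation)


def rank_auc(scores, outcome) -> float:
    """AUC by the rank (Mann-Whitney) formula; tied pairs count 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocResult:
    """ROC curve, AUC and a seeded class-stratified percentile-bootstrap CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int


def roc_auc(scores, outcome, n_boot: int = 2000, seed: int = 0, ci_level: float = 0.95) -> RocResult:
    """ROC analysis of a score against a binary outcome.

    The AUC comes from the rank formula (equivalent to the proportion of
    concordant positive-negative pairs with ties at 0.5). The CI resamples
    lesions with replacement within each class, seeded; replicates that lose a
    class cannot occur under stratified resampling.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s)
    auc = rank_auc(s, y)

    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        reps[i] = rank_auc(s[idx], y[idx])
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return RocResult(thr, tpr, 1.0 - fpr, auc, ci_level, float(lo), float(hi), n_boot, seed)


def metric_comparison_table(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = TABLE_METRICS,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-metric mean +/- SD by outcome class with Mann-Whitney p values.

    ``records`` must carry an ``outcome`` column (favorable/nonresponding).
    Metrics absent from the table are skipped with a warning. With ``holm``
    True a Holm-adjusted p column is appended.
    """
    if "outcome" not in records.columns:
        raise ValueError("records must have an 'outcome' column")
    fav = records[records.outcome == "favorable"]
    non = records[records.outcome == "nonresponding"]
    rows = []
    for m in metrics:
        if m not in records.columns:
            warnings.warn(f"metric {m!r} absent from records; column skipped")
            continue
        a, b = fav[m].dropna().to_numpy(), non[m].dropna().to_numpy()
        _, p = mann_whitney(a, b)
        rows.append(
            {
                "metric": m,
                "favorable_mean": a.mean(),
                "favorable_sd": a.std(ddof=1),
                "nonresponding_mean": b.mean(),
                "nonresponding_sd": b.std(ddof=1),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if holm and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table.p_value, method="holm")[1]
    return table


def frequency_table(series: pd.Series, order: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages of a categorical column, clinical-table style.

    ``percent`` is the raw share of the total x 100; ``percent_rounded`` is
    the integer percentage as printed in descriptive tables.
    """
    counts = series.value_counts()
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "count": counts,
            "percent": counts / total * 100.0,
            "percent_rounded": (counts / total * 100.0).round().astype(int),
        }
    )
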