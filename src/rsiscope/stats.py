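"""Patient-level discrimination statistics.

Contains the ROC/AUC machinery used throughout the analysis:

* midrank (Mann-Whitney) AUC, handling ordinal scores such as PI-RADS and
  continuous markers identically — ties count as half-wins;
* paired bootstrap comparison of two markers (patients resampled with
  replacement, both AUCs computed on identical indices) with percentile
  confidence intervals and a two-sided bootstrap p-value;
* within-stratum logistic posterior probabilities and their concatenation
  across ordered strata into a combined score (used for PI-RADS + RSIrs);
* per-category detection-rate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocCurve",
    "AucComparison",
    "StratifiedCombination",
    "auc",
    "roc_points",
    "bootstrap_auc",
    "bootstrap_compare",
    "stratified_posteriors",
    "combined_roc",
    "detection_rate_table",
    "pirads_stratum",
]


@dataclass
class RocCurve:
    score_name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class AucComparison:
    """Paired bootstrap comparison of two markers on the same patients."""

    auc_a: float
    auc_b: float
    delta: float
    ci95: tuple[float, float]
    p_two_sided: float
    n_boot: int
    seed: int | None = None


@dataclass
class StratifiedCombination:
    """Within-stratum logistic posteriors concatenated across ordered strata."""

    strata_levels: np.ndarray
    stratum_index: np.ndarray  # dense 0-based index per patient
    posterior: np.ndarray  # within-stratum posterior probability
    combined_score: np.ndarray  # stratum_index + posterior * (1 - eps)
    models: dict = field(default_factory=dict)  # level -> (intercept, slope) or None


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute an AUC")
    return y


def auc(scores, labels) -> float:
    """Midrank AUC: P(score+ > score-) + 0.5 P(tie), via the rank-sum identity."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    ranks = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auc_rows(scores_2d: np.ndarray, labels_2d: np.ndarray) -> np.ndarray:
    """Row-wise midrank AUC for resample matrices (every row has both classes)."""
    ranks = rankdata(scores_2d, axis=1)
    n_pos = labels_2d.sum(axis=1)
    n_neg = labels_2d.shape[1] - n_pos
    pos_rank_sum = (ranks * labels_2d).sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(scores, labels, score_name: str = "score") -> RocCurve:
    """ROC curve points (sensitivity / specificity) plus the midrank AUC."""
    y = _check_labels(labels)
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return RocCurve(
        score_name=score_name,
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc(scores, labels),
    )


def _resample_indices(
    labels: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap index matrix; rows that drew a single class are redrawn."""
    n = labels.size
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(1000):
        lab = labels[idx]
        bad = ~(lab.any(axis=1) & (~lab).any(axis=1))
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    raise RuntimeError("could not draw two-class bootstrap resamples")


def bootstrap_auc(scores, labels, n_boot: int = 10000, seed: int | None = None):
    """AUC with a percentile bootstrap 95% CI."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(y, n_boot, rng)
    aucs = _auc_rows(s[idx], y[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return auc(s, y), (float(lo), float(hi))


def bootstrap_compare(
    scores_a,
    scores_b,
    labels,
    n_boot: int = 10000,
    seed: int | None = None,
) -> AucComparison:
    """Paired bootstrap comparison of the AUCs of two markers.

    Patients are resampled with replacement; both AUCs are computed on
    identical indices per resample.  ``ci95`` is the 2.5/97.5 percentile
    interval of the AUC difference, and the two-sided p-value inverts the
    resample distribution, floored at 2/(n_boot+1).  Resamples containing a
    single class are redrawn so the percentile grid stays fixed.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals", stacklevel=2)
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != y.shape or b.shape != y.shape:
        raise ValueError("scores_a, scores_b, labels must be paired (same length)")
    rng = np.random.default_rng(seed)
    idx = _resample_indices(y, n_boot, rng)
    lab = y[idx]
    deltas = _auc_rows(a[idx], lab) - _auc_rows(b[idx], lab)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    p = min(max(p, 2.0 / (n_boot + 1)), 1.0)
    return AucComparison(
        auc_a=auc(a, y),
        auc_b=auc(b, y),
        delta=auc(a, y) - auc(b, y),
        ci95=(float(lo), float(hi)),
        p_two_sided=p,
        n_boot=n_boot,
        seed=seed,
    )


def pirads_stratum(pirads) -> np.ndarray:
    """Map PI-RADS 1-5 to ordered strata, merging 1 and 2 into the lowest.

    Categories 1-2 contain too few patients for a stable within-stratum fit
    and sit below category 3 in the detection table, so they form a single
    lowest stratum of the combined score.
    """
    p = np.asarray(pirads, dtype=int)
    if ((p < 1) | (p > 5)).any():
        raise ValueError("PI-RADS categories must lie in 1..5")
    return np.maximum(p, 2) - 2  # 1,2 -> 0; 3 -> 1; 4 -> 2; 5 -> 3


def _rank_posterior(marker: np.ndarray) -> np.ndarray:
    """Within-stratum fallback: marker midranks scaled into (0, 1)."""
    r = rankdata(marker)
    return (r - 0.5) / r.size


def stratified_posteriors(
    marker,
    labels,
    strata,
    min_per_class: int = 3,
    eps: float = 1e-9,
) -> StratifiedCombination:
    """Fit a univariate logistic model of label on marker within each stratum.

    The posterior probabilities are concatenated across ordered strata into
    ``combined_score = stratum_index + posterior * (1 - eps)``, so that
    stratum order is never violated while within-stratum ordering follows the
    logistic posterior.  Strata with fewer than ``min_per_class`` patients of
    either class, or in which the fit separates perfectly, fall back to the
    within-stratum marker rank scaled to (0, 1): ranks preserve the ROC,
    which is all the downstream analysis consumes.
    """
    m = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(strata)
    if not (m.shape == y.shape == s.shape):
        raise ValueError("marker, labels, strata must be aligned")
    levels, stratum_index = np.unique(s, return_inverse=True)

    posterior = np.empty(m.size)
    models: dict = {}
    for k, level in enumerate(levels):
        sel = stratum_index == k
        mk, yk = m[sel], y[sel]
        n_pos, n_neg = int(yk.sum()), int((~yk).sum())
        fitted = None
        if min(n_pos, n_neg) >= min_per_class and np.ptp(mk) > 0:
            X = sm.add_constant(mk)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(yk.astype(float), X).fit(disp=0, maxiter=200)
                if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
                    fitted = res
            except Exception:  # separation / non-convergence -> rank fallback
                fitted = None
        if fitted is not None:
            posterior[sel] = np.clip(fitted.predict(X), 0.0, 1.0)
            models[level] = (float(fitted.params[0]), float(fitted.params[1]))
        else:
            posterior[sel] = _rank_posterior(mk)
            models[level] = None

    combined = stratum_index + posterior * (1.0 - eps)
    return StratifiedCombination(
        strata_levels=levels,
        stratum_index=stratum_index,
        posterior=posterior,
        combined_score=combined,
        models=models,
    )


def combined_roc(
    combination: StratifiedCombination, labels, pooled: bool = False
) -> RocCurve:
    """ROC of the concatenated combined score (or of pooled posteriors).

    With the default stratum-ordered construction the curve is the
    concatenation of within-stratum ROC segments ordered by stratum; the
    pooled variant ranks patients by posterior alone and coincides with it
    whenever posteriors respect the stratum ordering.
    """
    score = combination.posterior if pooled else combination.combined_score
    name = "pooled_posterior" if pooled else "stratified_combined"
    return roc_points(score, labels, score_name=name)


def detection_rate_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-PI-RADS-category counts and csPCa detection rate (percent, 1 dp).

    Expects columns ``pirads`` and ``cspca``.  Empty categories are reported
    with zero counts and an undefined (NaN) rate.
    """
    out = []
    for cat in range(1, 6):
        sel = records["pirads"] == cat
        n_pos = int(records.loc[sel, "cspca"].sum())
        n_neg = int(sel.sum()) - n_pos
        total = n_pos + n_neg
        rate = round(100.0 * n_pos / total, 1) if total else float("nan")
        out.append(
            {"pirads": cat, "n_negative": n_neg, "n_positive": n_pos, "detection_rate_pct": rate}
        )
    return pd.DataFrame(out).set_index("pirads")
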