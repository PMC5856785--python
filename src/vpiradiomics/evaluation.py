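"""Performance and association statistics.

DeLong AUC with standard error / CI and paired curve comparison, 2×2
confusion metrics with likelihood ratios, logistic-regression odds ratios
with AIC, the concordance index, Mann–Whitney and Wilcoxon signed-rank
tests, and contingency-table cohort summaries (row/column percentages with
per-category χ² against the rest, no continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import ParameterError


# --------------------------------------------------------------------------
# DeLong AUC


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


@dataclass
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float

    def as_dict(self):
        return asdict(self)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and the DeLong structural components (V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ParameterError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per positive case
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per negative case
    return auc, v10, v01


def roc_auc_delong(scores, labels, alpha: float = 0.05) -> AUCResult:
    """AUC (Mann–Whitney statistic, ties ½) with DeLong SE and normal CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return AUCResult(float(auc), se,
                     float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def compare_auc_delong(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong test for two paired score sets: (AUC difference, two-sided p)."""
    labels = np.asarray(labels, dtype=int)
    auc_a, v10_a, v01_a = _delong_components(np.asarray(scores_a, float), labels)
    auc_b, v10_b, v01_b = _delong_components(np.asarray(scores_b, float), labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = float(auc_a - auc_b)
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2 * stats.norm.sf(abs(z)))


def concordance_index(scores, labels) -> float:
    """P(score⁺ > score⁻) with ½ for ties; equals the AUC for binary outcomes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


# --------------------------------------------------------------------------
# confusion metrics


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float     # all rate metrics in percent
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float          # +LR = sens / (1 − spec), ratio scale
    nlr: float          # −LR = (1 − sens) / spec

    def as_dict(self):
        return asdict(self)


def confusion_metrics(labels, predicted_positive) -> ConfusionMetrics:
    """Standard 2×2 diagnostics; rates in percent, likelihood ratios as ratios.

    Undefined quantities (empty denominator) are NaN; +LR at perfect
    specificity is +inf.
    """
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(predicted_positive, dtype=bool)
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())

    def _pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sens = _pct(tp, tp + fn)
    spec = _pct(tn, tn + fp)
    if np.isnan(sens) or np.isnan(spec):
        plr = nlr = float("nan")
    else:
        plr = (sens / (100.0 - spec)) if spec < 100.0 else float("inf")
        nlr = ((100.0 - sens) / spec) if spec > 0 else float("inf")
    return ConfusionMetrics(
        tp, fn, tn, fp,
        accuracy=_pct(tp + tn, tp + fn + tn + fp),
        sensitivity=sens, specificity=spec,
        ppv=_pct(tp, tp + fp), npv=_pct(tn, tn + fn),
        plr=plr, nlr=nlr,
    )


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticResult:
    odds_ratio: float
    p_value: float
    aic: float
    coef: float
    separated: bool

    def as_dict(self):
        return asdict(self)


def logistic_or(predictor, labels, haldane: bool = False) -> LogisticResult:
    """Univariate logistic regression of the outcome on one predictor.

    For a binary predictor the fitted odds ratio equals the cross-product
    ratio ad/bc.  With a zero cell (or complete separation) the OR is
    unbounded and flagged; ``haldane=True`` applies the +0.5 cell
    correction for binary predictors instead.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(labels, dtype=int)
    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary:
        a = ((x == 1) & (y == 1)).sum()  # exposed, outcome+
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        if min(a, b, c, d) == 0:
            if haldane:
                a, b, c, d = (v + 0.5 for v in (a, b, c, d))
                or_h = (a * d) / (b * c)
                return LogisticResult(float(or_h), float("nan"), float("nan"),
                                      float(np.log(or_h)), separated=True)
            return LogisticResult(float("inf"), float("nan"), float("nan"),
                                  float("inf"), separated=True)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:
            return LogisticResult(float("inf"), float("nan"), float("nan"),
                                  float("inf"), separated=True)
    coef = float(fit.params[1])
    return LogisticResult(float(np.exp(coef)), float(fit.pvalues[1]),
                          float(fit.aic), coef, separated=False)


# --------------------------------------------------------------------------
# rank tests


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U of group a vs b: (U, p).

    Exact null distribution when both groups have ≤ 8 observations and no
    ties; the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(differences, alternative: str = "two-sided"
                         ) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences: (W, p).

    Zero differences are dropped; exact null for ≤ 12 nonzero differences
    (no tied magnitudes), continuity-corrected normal approximation above.  All-zero input
    returns p = 1 with a warning.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; test is uninformative")
        return 0.0, 1.0
    no_ties = np.unique(np.abs(d)).size == d.size
    if d.size <= 12 and no_ties:
        res = stats.wilcoxon(d, alternative=alternative, method="exact")
    else:
        res = stats.wilcoxon(d, alternative=alternative, method="approx",
                             correction=True)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# cohort contingency summaries


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Row/column percentages and per-category χ² for a categories×outcome table.

    ``table``: index = category labels, two count columns (outcome−,
    outcome+).  Each category is tested against the pooled rest with a
    1-df Pearson χ² (no continuity correction); categories with a zero
    margin are skipped with a warning (p = NaN).
    """
    counts = table.to_numpy(dtype=float)
    if counts.shape[1] != 2 or (counts < 0).any():
        raise ParameterError("expected non-negative counts with two outcome columns")
    total = counts.sum()
    col_totals = counts.sum(axis=0)
    rows = []
    for k, cat in enumerate(table.index):
        n_neg, n_pos = counts[k]
        row_total = n_neg + n_pos
        rest = col_totals - counts[k]
        contingency = np.array([[n_neg, n_pos], rest])
        if row_total == 0 or min(contingency.sum(axis=0)) == 0 or rest.sum() == 0:
            warnings.warn(f"category {cat!r} has a zero margin; χ² skipped")
            p = float("nan")
        else:
            _, p, _, _ = stats.chi2_contingency(contingency, correction=False)
        rows.append({
            "category": cat,
            "n_neg": int(n_neg), "n_pos": int(n_pos), "n": int(row_total),
            "total_pct": round(100.0 * row_total / total, 1),
            "row_pct_neg": round(100.0 * n_neg / row_total, 1) if row_total else float("nan"),
            "row_pct_pos": round(100.0 * n_pos / row_total, 1) if row_total else float("nan"),
            "col_pct_neg": round(100.0 * n_neg / col_totals[0], 1) if col_totals[0] else float("nan"),
            "col_pct_pos": round(100.0 * n_pos / col_totals[1], 1) if col_totals[1] else float("nan"),
            "chi2_p": p,
        })
    return pd.DataFrame(rows).set_index("category")


# --------------------------------------------------------------------------
# composite report


def evaluate_predictions(predictions: pd.DataFrame, pi_cutoff: float) -> dict:
    """Full evaluation of aggregated per-case predictions at a Pi cut-off.

    ``predictions`` needs ``label`` and ``pi`` columns.  Returns a plain
    dict (JSON-ready): DeLong AUC/SE/CI, confusion metrics at the cut-off,
    risk-group logistic OR with AIC, concordance index, and the
    Mann–Whitney p for Pi between classes.
    """
    y = predictions["label"].to_numpy(dtype=int)
    pi = predictions["pi"].to_numpy(dtype=float)
    auc = roc_auc_delong(pi, y)
    cm = confusion_metrics(y, pi >= pi_cutoff)
    high_risk = (pi >= pi_cutoff).astype(float)
    logistic = logistic_or(high_risk, y)
    _, mw_p = mann_whitney(pi[y == 1], pi[y == 0])
    return {
        "auc": auc.as_dict(),
        "pi_cutoff": float(pi_cutoff),
        "confusion": cm.as_dict(),
        "risk_group_logistic": logistic.as_dict(),
        "concordance_index": concordance_index(pi, y),
        "mann_whitney_p": mw_p,
        "n_cases": int(len(y)),
    }
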