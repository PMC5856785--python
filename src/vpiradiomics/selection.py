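"""Three-stage feature reduction.

1. Reproducibility: the concordance correlation coefficient (CCC)

       ρ_c = 2ρσ_xσ_y / (σ_x² + σ_y² + (μ_x − μ_y)²)

   between paired replicate extractions; features with CCC ≥ 0.9 are kept,
   capped at the 100 most stable.  Moments are population (divide-by-n)
   moments.
2. Redundancy: correlation distance 1 − |Pearson r| on standardized
   features; while any pair is closer than 0.05 the member with the lower
   CCC (tie: later catalog order) is dropped.
3. Ranking: SVM-RFE — recursively train a linear maximum-margin classifier,
   eliminate the feature with the smallest squared weight, and record that
   squared weight as the feature's contribution ω (normalized to sum 1 over
   all features).  The final selection is the shortest prefix of the
   ranking whose cumulative ω reaches the stop threshold (default 0.80);
   a fixed-k mode is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .exceptions import ParameterError


# --------------------------------------------------------------------------
# concordance correlation coefficient


@dataclass
class CCCResult:
    feature: str
    ccc: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    rho: float

    def as_dict(self) -> dict:
        return asdict(self)


def ccc(x, y, feature: str = "") -> CCCResult:
    """Concordance correlation coefficient of two replicate value vectors.

    Degenerate conventions: if both replicates have zero variance the CCC
    is 1 when the means agree and 0 otherwise; if exactly one has zero
    variance the correlation is taken as 0, giving CCC 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("replicates must be 1D vectors of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 paired observations")
    mu_x, mu_y = float(x.mean()), float(y.mean())
    var_x, var_y = float(x.var()), float(y.var())  # population moments
    sigma_x, sigma_y = np.sqrt(var_x), np.sqrt(var_y)
    if var_x == 0.0 and var_y == 0.0:
        value, rho = (1.0, 1.0) if mu_x == mu_y else (0.0, 0.0)
    elif var_x == 0.0 or var_y == 0.0:
        value, rho = 0.0, 0.0
    else:
        cov = float(((x - mu_x) * (y - mu_y)).mean())
        rho = cov / (sigma_x * sigma_y)
        value = 2 * cov / (var_x + var_y + (mu_x - mu_y) ** 2)
    return CCCResult(feature, float(value), mu_x, mu_y,
                     float(sigma_x), float(sigma_y), float(rho))


def ccc_table(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict[str, CCCResult]:
    """Per-feature CCC between two aligned replicate feature tables."""
    features = [c for c in table_a.columns if c != "label"]
    missing = [c for c in features if c not in table_b.columns]
    if missing:
        raise ParameterError(f"replicate table lacks features: {missing[:5]}")
    return {f: ccc(table_a[f].to_numpy(), table_b.loc[table_a.index, f].to_numpy(),
                   feature=f) for f in features}


def reproducibility_filter(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           threshold: float = 0.9, cap: int = 100
                           ) -> tuple[list[str], dict[str, CCCResult]]:
    """Keep the (≤ cap) most stable features with CCC ≥ threshold.

    Ranking is by CCC descending with ties broken by column order; the
    returned list preserves that stability ranking.
    """
    results = ccc_table(table_a, table_b)
    order = [c for c in table_a.columns if c != "label"]
    ranked = sorted(order, key=lambda f: -results[f].ccc)  # stable sort
    kept = [f for f in ranked if results[f].ccc >= threshold][:cap]
    return kept, results


# --------------------------------------------------------------------------
# redundancy pruning


def redundancy_filter(table: pd.DataFrame, features: list[str] | None = None,
                      ccc_values: dict[str, float] | None = None,
                      distance_threshold: float = 0.05) -> list[str]:
    """Drop one member of every feature pair closer than the threshold.

    Distance is 1 − |Pearson r| on standardized columns.  Of a close pair,
    the member with the lower CCC is dropped (missing CCC counts as −∞;
    ties drop the later column).  Constant columns are undefined under
    correlation distance and are dropped with a warning.
    """
    if features is None:
        features = [c for c in table.columns if c != "label"]
    ccc_values = ccc_values or {}
    X = table[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        dropped = [f for f, c in zip(features, constant) if c]
        warnings.warn(f"dropping constant features: {dropped}")
        features = [f for f, c in zip(features, constant) if not c]
        X = X[:, ~constant]
    if len(features) < 2:
        return list(features)
    dist = 1.0 - np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(dist, np.inf)

    position = {f: k for k, f in enumerate(features)}
    alive = list(range(len(features)))
    while True:
        sub = dist[np.ix_(alive, alive)]
        k = int(np.argmin(sub))
        if sub.flat[k] >= distance_threshold:
            break
        i, j = alive[k // len(alive)], alive[k % len(alive)]
        ci = ccc_values.get(features[i], float("-inf"))
        cj = ccc_values.get(features[j], float("-inf"))
        if ci < cj or (ci == cj and position[features[i]] > position[features[j]]):
            alive.remove(i)
        else:
            alive.remove(j)
    return [features[i] for i in alive]


# --------------------------------------------------------------------------
# SVM-RFE ranking and cumulative-weight selection


class SVMRFESelector(SelectorMixin, BaseEstimator):
    """Recursive feature elimination with a linear maximum-margin classifier.

    One feature is eliminated per iteration (the one with the smallest
    squared weight); its squared weight at elimination becomes its raw
    contribution, normalized over all features into weights ω summing to 1.
    The ranking is the reverse elimination order.  Selection keeps the
    shortest ranking prefix whose cumulative ω reaches ``stop``, or exactly
    ``fixed_k`` features when that mode is used.

    Features are assumed standardized (zero mean, unit variance).

    Attributes
    ----------
    ranking_ : ndarray of int
        1 = best, in input column order.
    omega_ : ndarray of float
        Normalized contribution weights, input column order; sums to 1.
    support_ : ndarray of bool
        Selected-feature mask.
    selected_features_ : list
        Selected column names (indices for array input), best first.
    cumulative_weight_ : float
        Σω of the selected prefix.
    """

    def __init__(self, stop: float = 0.80, fixed_k: int | None = None, C: float = 0.01):
        self.stop = stop
        self.fixed_k = fixed_k
        self.C = C

    def fit(self, X, y):
        feature_names = list(X.columns) if hasattr(X, "columns") else None
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ParameterError("SVM-RFE requires exactly two classes")
        if self.fixed_k is None and not (0 < self.stop <= 1):
            raise ParameterError("stop must be in (0, 1]")
        n_features = X.shape[1]
        if feature_names is None:
            feature_names = list(range(n_features))

        remaining = list(range(n_features))
        raw = np.zeros(n_features)
        elimination_order: list[int] = []
        while remaining:
            svm = SVC(kernel="linear", C=self.C)
            svm.fit(X[:, remaining], y)
            w2 = np.asarray(svm.coef_).ravel() ** 2
            k = int(np.argmin(w2))
            raw[remaining[k]] = w2[k]
            elimination_order.append(remaining.pop(k))

        rank_order = elimination_order[::-1]  # best first
        self.ranking_ = np.empty(n_features, dtype=int)
        for rank, idx in enumerate(rank_order, start=1):
            self.ranking_[idx] = rank
        total = raw.sum()
        self.omega_ = raw / total if total > 0 else np.full(n_features, 1.0 / n_features)

        if self.fixed_k is not None:
            n_keep = min(self.fixed_k, n_features)
        else:
            cum = np.cumsum(self.omega_[rank_order])
            n_keep = int(np.searchsorted(cum, self.stop - 1e-12) + 1)
            n_keep = min(n_keep, n_features)
        selected = rank_order[:n_keep]
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[selected] = True
        self.selected_features_ = [feature_names[i] for i in selected]
        self.cumulative_weight_ = float(self.omega_[selected].sum())
        self.feature_names_all_ = feature_names
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def ranking_table(self) -> list[tuple[str, float]]:
        """(feature, ω) pairs in rank order (best first)."""
        check_is_fitted(self)
        order = np.argsort(self.ranking_)
        return [(self.feature_names_all_[i], float(self.omega_[i])) for i in order]


def svm_rfe_rank(table: pd.DataFrame, labels, C: float = 0.01) -> list[tuple[str, float]]:
    """SVM-RFE ranking of a standardized feature table: (feature, ω) pairs."""
    selector = SVMRFESelector(stop=1.0, C=C).fit(table, np.asarray(labels))
    return selector.ranking_table()


def cumulative_weight_select(rfe_ranking: list[tuple[str, float]],
                             stop: float = 0.80) -> tuple[list[str], float]:
    """Shortest ranking prefix whose cumulative ω reaches ``stop``."""
    if not rfe_ranking:
        raise ParameterError("empty ranking")
    if not (0 < stop <= 1):
        raise ParameterError("stop must be in (0, 1]")
    omegas = np.array([w for _, w in rfe_ranking])
    if (omegas < 0).any() or not np.isclose(omegas.sum(), 1.0, atol=1e-6):
        raise ParameterError("ranking weights must be non-negative and sum to 1")
    cum = np.cumsum(omegas)
    n_keep = int(np.searchsorted(cum, stop - 1e-12) + 1)
    n_keep = min(n_keep, len(rfe_ranking))
    return [f for f, _ in rfe_ranking[:n_keep]], float(cum[n_keep - 1])


# --------------------------------------------------------------------------
# stage report


@dataclass
class SelectionReport:
    """Everything the three reduction stages decided, serializable to JSON."""

    kept_after_ccc: list[str] = field(default_factory=list)
    kept_after_redundancy: list[str] = field(default_factory=list)
    rfe_ranking: list[tuple[str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    cumulative_weight: float = 0.0
    ccc_values: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["rfe_ranking"] = [[f, w] for f, w in self.rfe_ranking]
        return d


def select_features(table: pd.DataFrame, replicate: pd.DataFrame, labels,
                    ccc_threshold: float = 0.9, ccc_cap: int = 100,
                    redundancy_threshold: float = 0.05,
                    stop: float = 0.80, C: float = 0.01) -> SelectionReport:
    """Run the full reduction: CCC filter → redundancy pruning → SVM-RFE."""
    kept_ccc, ccc_results = reproducibility_filter(
        table, replicate, threshold=ccc_threshold, cap=ccc_cap
    )
    ccc_scalar = {f: r.ccc for f, r in ccc_results.items()}
    kept_red = redundancy_filter(table, kept_ccc, ccc_values=ccc_scalar,
                                 distance_threshold=redundancy_threshold)
    X = table[kept_red]
    Xs = (X - X.mean()) / X.std(ddof=0)
    ranking = svm_rfe_rank(Xs, labels, C=C)
    selected, cumw = cumulative_weight_select(ranking, stop=stop)
    return SelectionReport(
        kept_after_ccc=kept_ccc,
        kept_after_redundancy=kept_red,
        rfe_ranking=ranking,
        selected=selected,
        cumulative_weight=cumw,
        ccc_values=ccc_scalar,
    )
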