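"""The radiomics signature: an RBF-SVM probability score with CV validation.

The classifier separates the two classes with a soft-margin SVM using the
radial basis kernel k(x, x') = exp(−γ‖x − x'‖²).  Its raw decision value x
is mapped to the signature probability Pi = 1/(1 + e^(−x)); no additional
probability calibration is applied.  Validation uses repeated stratified
ten-fold cross-validation (10 repeats by default); standardization, SVM-RFE
selection and the hyperparameter grid search are re-fit inside every
training split so no information leaks from a validation fold.  The
operating point is the Pi cut-off maximizing the Youden index, with ties
broken toward higher specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .exceptions import ParameterError
from .selection import SVMRFESelector

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


def sigmoid_probability(x):
    """Map a decision value to the signature probability Pi = 1/(1+e^−x)."""
    return expit(x)


class RadiomicsSignature(ClassifierMixin, BaseEstimator):
    """RBF-SVM signature classifier with internal scaling and selection.

    Parameters
    ----------
    C, gamma : float or None
        SVM hyperparameters; when None they are chosen by an inner
        stratified 3-fold grid search (AUC-scored) over ``c_grid`` ×
        ``gamma_grid``.
    select : bool
        Run SVM-RFE with a cumulative-ω stop inside ``fit`` (on the
        standardized training data).
    rfe_stop : float
        Cumulative contribution-weight threshold for the RFE selection.
    random_state : int or None
        Seeds the inner grid-search folds.

    Attributes
    ----------
    scaler_ : fitted StandardScaler
    selector_ : fitted SVMRFESelector or None
    svm_ : fitted SVC
    C_, gamma_ : chosen hyperparameters
    """

    def __init__(self, C=None, gamma=None, select=False, rfe_stop=0.80,
                 rfe_C=0.01, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 inner_folds=3, tol=1e-3, random_state=None):
        self.C = C
        self.gamma = gamma
        self.select = select
        self.rfe_stop = rfe_stop
        self.rfe_C = rfe_C
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        feature_names = list(X.columns) if hasattr(X, "columns") else None
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ParameterError("signature model requires exactly two classes")

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        if self.select:
            self.selector_ = SVMRFESelector(stop=self.rfe_stop, C=self.rfe_C)
            self.selector_.fit(
                pd.DataFrame(Xs, columns=feature_names) if feature_names else Xs, y
            )
            Xsel = Xs[:, self.selector_.support_]
            self.selected_features_ = self.selector_.selected_features_
        else:
            self.selector_ = None
            Xsel = Xs
            self.selected_features_ = feature_names

        C, gamma = self.C, self.gamma
        if C is None or gamma is None:
            grid = {
                "C": list(self.c_grid) if C is None else [C],
                "gamma": list(self.gamma_grid) if gamma is None else [gamma],
            }
            folds = min(self.inner_folds, int(np.bincount(y).min()))
            search = GridSearchCV(
                SVC(kernel="rbf", tol=self.tol), grid, scoring="roc_auc",
                cv=StratifiedKFold(max(folds, 2), shuffle=True,
                                   random_state=self.random_state),
            )
            search.fit(Xsel, y)
            C, gamma = search.best_params_["C"], search.best_params_["gamma"]
        self.C_, self.gamma_ = float(C), float(gamma)
        self.svm_ = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_,
                        tol=self.tol).fit(Xsel, y)
        return self

    def _transform(self, X):
        X = validate_data(self, X, reset=False)
        Xs = self.scaler_.transform(X)
        if self.selector_ is not None:
            Xs = Xs[:, self.selector_.support_]
        return Xs

    def decision_function(self, X):
        """Raw SVM decision values x (positive favours the second class)."""
        check_is_fitted(self)
        return self.svm_.decision_function(self._transform(X))

    def predict_proba(self, X):
        """Columns [1 − Pi, Pi] with Pi = sigmoid(decision value)."""
        pi = sigmoid_probability(self.decision_function(X))
        return np.column_stack([1.0 - pi, pi])

    def signature(self, X):
        """The Pi score as a flat array."""
        return sigmoid_probability(self.decision_function(X))

    def predict(self, X):
        pi = self.signature(X)
        return self.classes_[(pi >= 0.5).astype(int)]


@dataclass
class CrossValidationPlan:
    """Repeated stratified k-fold plan; each case is validated once per repeat."""

    n_repeats: int = 10
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")


def cross_validate_signature(table: pd.DataFrame, labels=None,
                             plan: CrossValidationPlan | None = None,
                             select: bool = True, rfe_stop: float = 0.80,
                             C=None, gamma=None,
                             fold_assignments: np.ndarray | None = None
                             ) -> pd.DataFrame:
    """Out-of-fold signature predictions under repeated stratified k-fold CV.

    Parameters
    ----------
    table : cases×features DataFrame; a ``label`` column is used when
        ``labels`` is None.
    plan : CrossValidationPlan (default 10 repeats × 10 folds).
    select, rfe_stop, C, gamma : passed to :class:`RadiomicsSignature`;
        everything (scaling, selection, grid search) is re-fit per training
        split.
    fold_assignments : optional (n_repeats, n_cases) int array overriding
        the stratified assignment (used for leakage audits).

    Returns
    -------
    DataFrame with one row per case × repeat:
    ``case_id, label, repeat, fold, x, pi``.
    """
    plan = plan or CrossValidationPlan()
    if labels is None:
        if "label" not in table.columns:
            raise ParameterError("no labels given and no 'label' column present")
        labels = table["label"].to_numpy()
        table = table.drop(columns="label")
    y = np.asarray(labels, dtype=int)
    if np.bincount(y).min() < plan.n_folds:
        raise ParameterError(
            f"smallest class ({np.bincount(y).min()}) cannot fill "
            f"{plan.n_folds} stratified folds"
        )
    case_ids = (table.index.astype(str) if table.index.name == "case_id"
                else pd.Index([f"case{k:04d}" for k in range(len(table))]))

    records = []
    for rep in range(plan.n_repeats):
        if fold_assignments is not None:
            folds = np.asarray(fold_assignments[rep])
            splits = [(np.flatnonzero(folds != f), np.flatnonzero(folds == f))
                      for f in np.unique(folds)]
        else:
            kf = StratifiedKFold(plan.n_folds, shuffle=True,
                                 random_state=(plan.seed + rep) % (2 ** 31))
            splits = list(kf.split(table, y))
        for fold_id, (tr, va) in enumerate(splits):
            model = RadiomicsSignature(
                C=C, gamma=gamma, select=select, rfe_stop=rfe_stop,
                random_state=(plan.seed + rep) % (2 ** 31),
            )
            model.fit(table.iloc[tr], y[tr])
            x = model.decision_function(table.iloc[va])
            pi = sigmoid_probability(x)
            for i, xi, pii in zip(va, x, pi):
                records.append((case_ids[i], int(y[i]), rep, fold_id,
                                float(xi), float(pii)))
    return pd.DataFrame(records,
                        columns=["case_id", "label", "repeat", "fold", "x", "pi"])


def aggregate_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-case mean Pi (and mean x) over repeats; one row per case."""
    agg = predictions.groupby("case_id", sort=False).agg(
        label=("label", "first"), x=("x", "mean"), pi=("pi", "mean")
    )
    return agg.reset_index()


@dataclass
class CutoffResult:
    pi_cutoff: float
    roc_cutoff: float  # same point on the decision scale: logit(pi_cutoff)
    youden: float
    informative: bool


def roc_cutoff(pi, labels) -> CutoffResult:
    """Youden-optimal Pi cut-off (rule: predict positive when Pi ≥ cutoff).

    Candidate cut-offs are midpoints between adjacent distinct Pi values
    plus sentinels below/above the observed range; among Youden-maximal
    candidates the one with the higher specificity (then the higher value)
    wins.  When all scores are equal the cut-off is non-informative.
    """
    pi = np.asarray(pi, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ParameterError("roc_cutoff requires both classes")
    uniq = np.unique(pi)
    if uniq.size == 1:
        return CutoffResult(float(uniq[0]), float(logit(np.clip(uniq[0], 1e-12, 1 - 1e-12))),
                            0.0, informative=False)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1e-9], mids, [uniq[-1] + 1e-9]))
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best = None
    for c in candidates:
        pred = pi >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        key = (sens + spec - 1.0, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    (youden, _, _), cut, _, _ = best
    cut_clipped = float(np.clip(cut, 1e-12, 1 - 1e-12))
    return CutoffResult(float(cut), float(logit(cut_clipped)), float(youden),
                        informative=youden > 0)


def stratify(pi, pi_cutoff: float) -> np.ndarray:
    """Assign risk groups: Pi ≥ cutoff → 'high', else 'low'."""
    pi = np.asarray(pi, dtype=float)
    return np.where(pi >= pi_cutoff, "high", "low")
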