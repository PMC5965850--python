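"""The SRSA individual-differences estimator.

Each participant is summarized by the mean of their per-trial successor
representations — a point in the 25-dimensional SR space.  The estimator
mean-centers these vectors, reduces them to 5 principal components, and
regresses the individual-difference score on the component projections by
ordinary least squares.  The regression solution mapped back into SR space,

    W = sum_k b_k * PC_k   (reshaped 5 x 5),

is the *prediction weight matrix*: entry (r, c) says how an excess of
discounted future visits to receiver r from sender c pushes the predicted
score up or down.  W is invariant to the arbitrary sign of each principal
component (flipping PC_k flips b_k).

Goodness of fit is the squared Pearson correlation between fitted and
observed scores (R^2).  Generalization is estimated by leave-one-out
cross-validation with PCA and regression refit on every training fold
(centering recomputed per fold, so no information leaks from the held-out
participant); Rcv^2 is the squared Pearson correlation between observed
scores and the held-out predictions.  A grid search over the TD parameters
(alpha, gamma) recomputes all trial SRs per cell and selects the cell
maximizing Rcv^2 (ties: smaller gamma, then smaller alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateFitError, UndefinedCorrelationError
from .sr import participant_mean_srs, trial_srs

DEFAULT_N_COMPONENTS = 5

#: default two-decimal parameter grid: 0.01 then 0.05 steps up to 1.00
DEFAULT_GRID = (0.01,) + tuple(round(0.05 * k, 2) for k in range(1, 21))


def _safe_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def weight_correlation(w1: np.ndarray, w2: np.ndarray) -> float:
    """Pearson correlation between two flattened 5 x 5 weight matrices."""
    a = np.asarray(w1, dtype=float).ravel()
    b = np.asarray(w2, dtype=float).ravel()
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise UndefinedCorrelationError(
            "correlation with a constant matrix is undefined"
        )
    return float(np.corrcoef(a, b)[0, 1])


class SRSARegressor(RegressorMixin, BaseEstimator):
    """PCA-reduced linear regression from mean SR matrices to scores.

    Parameters
    ----------
    n_components : int, default 5
        Number of principal components retained from the flattened
        (participant x 25) mean-SR matrix.

    Attributes
    ----------
    pca_ : fitted :class:`sklearn.decomposition.PCA`
    regressor_ : fitted :class:`sklearn.linear_model.LinearRegression`
    coef_ : ndarray (n_components,) — regression weights on the projections
    intercept_ : float
    components_matrices_ : ndarray (n_components, 5, 5) — PCs in SR space
    weight_matrix_ : ndarray (5, 5) — sum of PCs scaled by their coefficients
    r_squared_ : float — in-sample squared correlation of fitted vs observed
    """

    def __init__(self, n_components: int = DEFAULT_N_COMPONENTS):
        self.n_components = n_components

    @staticmethod
    def _as_design(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:  # stack of square matrices
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2:
            raise ValueError("X must be (n, d) vectors or (n, k, k) matrices")
        return X

    def fit(self, X, y):
        X = self._as_design(X)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        self._side = int(round(np.sqrt(d)))
        # mathematical minimum: n_components + 1 points determine the
        # OLS-on-projections fit; fit_srsa() asks for one more for slack
        if n < self.n_components + 1:
            raise DegenerateFitError(
                f"need at least n_components + 1 = {self.n_components + 1} "
                f"samples, got {n}"
            )
        centered = X - X.mean(axis=0)
        if np.linalg.matrix_rank(centered) < self.n_components:
            raise DegenerateFitError(
                "fewer distinct SR patterns than requested components"
            )
        self.pca_ = PCA(n_components=self.n_components)
        Z = self.pca_.fit_transform(X)
        self.regressor_ = LinearRegression().fit(Z, y)
        self.coef_ = self.regressor_.coef_.copy()
        self.intercept_ = float(self.regressor_.intercept_)
        w = self.coef_ @ self.pca_.components_
        if self._side * self._side == d:  # SR-space features: expose as matrices
            self.components_matrices_ = self.pca_.components_.reshape(
                self.n_components, self._side, self._side
            )
            self.weight_matrix_ = w.reshape(self._side, self._side)
        else:
            self.components_matrices_ = self.pca_.components_
            self.weight_matrix_ = w
        fitted = self.regressor_.predict(Z)
        self.r_squared_ = _safe_r2(fitted, y)
        return self

    def transform(self, X) -> np.ndarray:
        """Project mean SRs onto the fitted principal components."""
        check_is_fitted(self, "pca_")
        return self.pca_.transform(self._as_design(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "regressor_")
        return self.regressor_.predict(self.transform(X))


# ---------------------------------------------------------------------------
# functional wrappers operating on {participant_id: matrix} mappings
# ---------------------------------------------------------------------------


@dataclass
class SRSAFit:
    """In-sample SRSA fit for one measure."""

    participant_ids: list
    estimator: SRSARegressor
    r_squared: float
    weight_matrix: np.ndarray
    component_loadings: np.ndarray  # (n_components, 5, 5)
    coefficients: np.ndarray
    intercept: float
    fitted: pd.Series


@dataclass
class CVResult:
    """Leave-one-out cross-validated SRSA result."""

    participant_ids: list
    predictions: pd.Series  # held-out prediction per participant
    rcv_squared: float  # squared-correlation form (canonical)
    rcv_squared_sse: float  # 1 - SSE/SST alternative, for reference
    fold_weights: dict  # held-out pid -> training-fold weight matrix
    mean_weights: np.ndarray


def _align(mean_srs: Mapping, scores: Mapping | pd.Series):
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    pids = sorted(set(mean_srs) & set(scores))
    if len(pids) < len(mean_srs) or len(pids) < len(scores):
        missing = sorted(set(mean_srs) ^ set(scores))
        if not pids:
            raise DegenerateFitError("no participants shared between SRs and scores")
        import warnings

        warnings.warn(
            f"participants without both SRs and scores excluded: {missing}",
            stacklevel=3,
        )
    X = np.stack([np.asarray(mean_srs[p], dtype=float).ravel() for p in pids])
    y = np.array([scores[p] for p in pids], dtype=float)
    return pids, X, y


def fit_srsa(
    mean_srs: Mapping,
    scores: Mapping | pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> SRSAFit:
    """Fit the PCA + OLS model in-sample on participant mean SRs."""
    pids, X, y = _align(mean_srs, scores)
    if len(pids) < n_components + 2:
        raise DegenerateFitError(
            f"need at least n_components + 2 = {n_components + 2} participants, "
            f"got {len(pids)}"
        )
    est = SRSARegressor(n_components=n_components).fit(X, y)
    return SRSAFit(
        participant_ids=pids,
        estimator=est,
        r_squared=est.r_squared_,
        weight_matrix=est.weight_matrix_,
        component_loadings=est.components_matrices_,
        coefficients=est.coef_,
        intercept=est.intercept_,
        fitted=pd.Series(est.predict(X), index=pids, name="fitted"),
    )


def loocv_srsa(
    mean_srs: Mapping,
    scores: Mapping | pd.Series,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> CVResult:
    """Leave-one-out cross-validation with per-fold PCA + OLS refit."""
    pids, X, y = _align(mean_srs, scores)
    n = len(pids)
    if n < max(7, n_components + 2):
        raise DegenerateFitError(f"leave-one-out needs >= 7 participants, got {n}")
    preds = np.empty(n)
    fold_weights = {}
    for i in range(n):
        mask = np.arange(n) != i
        est = SRSARegressor(n_components=n_components).fit(X[mask], y[mask])
        preds[i] = est.predict(X[i : i + 1])[0]
        fold_weights[pids[i]] = est.weight_matrix_
    rcv2 = _safe_r2(y, preds)
    sst = float(np.sum((y - y.mean()) ** 2))
    rcv2_sse = 1.0 - float(np.sum((y - preds) ** 2)) / sst if sst > 0 else 0.0
    return CVResult(
        participant_ids=pids,
        predictions=pd.Series(preds, index=pids, name="prediction"),
        rcv_squared=rcv2,
        rcv_squared_sse=rcv2_sse,
        fold_weights=fold_weights,
        mean_weights=np.mean(np.stack(list(fold_weights.values())), axis=0),
    )


@dataclass
class GridSearchResult:
    """Full (alpha, gamma) grid of SRSA fits for one state space + measure."""

    best_alpha: float
    best_gamma: float
    best_r_squared: float
    best_rcv_squared: float
    table: pd.DataFrame  # alpha, gamma, r2, r2cv
    best_fit: SRSAFit = field(repr=False, default=None)
    best_cv: CVResult = field(repr=False, default=None)


def grid_search(
    sequences: Mapping,
    scores: Mapping | pd.Series,
    alpha_grid: Sequence[float] = DEFAULT_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GRID,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> GridSearchResult:
    """Exhaustive search over TD parameters maximizing leave-one-out Rcv^2.

    For every grid cell the per-trial SRs, participant means, in-sample fit
    and leave-one-out CV are recomputed from the raw state sequences.  Ties
    are broken toward the least temporally extended model: smaller gamma,
    then smaller alpha.
    """
    alphas = sorted(set(float(a) for a in alpha_grid))
    gammas = sorted(set(float(g) for g in gamma_grid))
    if not alphas or not gammas:
        raise ValueError("alpha_grid and gamma_grid must be non-empty")
    rows = []
    best = None  # (rcv2, -gamma, -alpha) maximization key
    best_cell = None
    for gamma in gammas:
        for alpha in alphas:
            mats = participant_mean_srs(trial_srs(sequences, alpha, gamma))
            fit = fit_srsa(mats, scores, n_components)
            cv = loocv_srsa(mats, scores, n_components)
            rows.append(
                {
                    "alpha": alpha,
                    "gamma": gamma,
                    "r2": fit.r_squared,
                    "r2cv": cv.rcv_squared,
                }
            )
            key = (cv.rcv_squared, -gamma, -alpha)
            if best is None or key > best:
                best = key
                best_cell = (alpha, gamma, fit, cv)
    alpha, gamma, fit, cv = best_cell
    return GridSearchResult(
        best_alpha=alpha,
        best_gamma=gamma,
        best_r_squared=fit.r_squared,
        best_rcv_squared=cv.rcv_squared,
        table=pd.DataFrame(rows, columns=["alpha", "gamma", "r2", "r2cv"]),
        best_fit=fit,
        best_cv=cv,
    )
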