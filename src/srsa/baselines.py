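"""Comparison models: traditional eye metrics and first-order transitions.

Two reference models bracket what the successor representation adds:

* the *traditional* model regresses scores on six per-participant summary
  statistics (mean/SD of fixation duration, saccade amplitude, fixation
  count per trial) — no sequential information at all;
* the *first-order* model replaces each trial SR with the trial's 5 x 5
  transition relative-frequency matrix (sender column -> receiver row,
  normalized to sum to 1 per trial to remove the trial-length confound),
  then runs the identical PCA + OLS + leave-one-out machinery.

Both use the same leave-one-out fold structure as SRSA (folds are the
sorted participant ids), so all three Rcv^2 values are directly comparable.
With gamma = 0 and alpha = 1, a trial SR of a sequence that visits each
transition at most once equals the unnormalized transition count matrix —
the first-order model is the memoryless limit of SRSA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .exceptions import DegenerateFitError
from .pipeline import CVResult, SRSAFit, _safe_r2, fit_srsa, loocv_srsa
from .preprocessing import METRIC_COLUMNS
from .sr import N_STATES


def transition_matrix(
    states: Iterable[int], normalize: bool = True, n_states: int = N_STATES
) -> np.ndarray:
    """First-order transition matrix of one state sequence.

    Columns are senders, rows receivers (SR convention).  With
    ``normalize=True`` entries are relative frequencies summing to 1 over
    the whole matrix; transition-free sequences give the zero matrix.
    """
    seq = np.asarray(list(states), dtype=np.int64)
    M = np.zeros((n_states, n_states))
    if seq.size < 2:
        return M
    np.add.at(M, (seq[1:] - 1, seq[:-1] - 1), 1.0)
    if normalize:
        M /= M.sum()
    return M


def participant_mean_transitions(
    sequences: Mapping, normalize: bool = True, n_states: int = N_STATES
) -> dict:
    """Per-participant mean of per-trial transition frequency matrices."""
    by_pid: dict = {}
    for (pid, _tid), seq in sequences.items():
        by_pid.setdefault(pid, []).append(transition_matrix(seq, normalize, n_states))
    return {pid: np.mean(np.stack(ms), axis=0) for pid, ms in by_pid.items()}


@dataclass
class BaselineResult:
    """R^2 / Rcv^2 of a comparison model, on SRSA's fold structure."""

    model: str
    r_squared: float
    rcv_squared: float
    predictions: pd.Series
    fit: object = None
    cv: object = None


def traditional_model(
    metrics: pd.DataFrame, scores: Mapping | pd.Series
) -> BaselineResult:
    """OLS of scores on the six traditional eye metrics, with leave-one-out CV.

    ``metrics`` is the table from :func:`srsa.preprocessing.traditional_metrics`.
    Collinear or constant predictor columns are flagged with a warning; the
    least-squares solver handles rank deficiency via the pseudo-inverse.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    m = metrics.set_index("participant_id")[METRIC_COLUMNS]
    pids = sorted(set(m.index) & set(scores))
    n = len(pids)
    if n < len(METRIC_COLUMNS) + 2:
        raise DegenerateFitError(
            f"traditional model needs >= {len(METRIC_COLUMNS) + 2} participants"
        )
    X = m.loc[pids].to_numpy(dtype=float)
    y = np.array([scores[p] for p in pids], dtype=float)
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        warnings.warn(
            "rank-deficient predictor matrix (constant or collinear metrics); "
            "fitting with the pseudo-inverse",
            stacklevel=2,
        )
    reg = LinearRegression().fit(X, y)
    r2 = _safe_r2(reg.predict(X), y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        fold = LinearRegression().fit(X[mask], y[mask])
        preds[i] = fold.predict(X[i : i + 1])[0]
    return BaselineResult(
        model="traditional",
        r_squared=r2,
        rcv_squared=_safe_r2(y, preds),
        predictions=pd.Series(preds, index=pids, name="prediction"),
        fit=reg,
    )


def first_order_model(
    sequences: Mapping,
    scores: Mapping | pd.Series,
    n_components: int = 5,
    normalize: bool = True,
) -> BaselineResult:
    """First-order transition-frequency analogue of the SRSA pipeline."""
    mats = participant_mean_transitions(sequences, normalize=normalize)
    fit: SRSAFit = fit_srsa(mats, scores, n_components)
    cv: CVResult = loocv_srsa(mats, scores, n_components)
    return BaselineResult(
        model="first_order",
        r_squared=fit.r_squared,
        rcv_squared=cv.rcv_squared,
        predictions=cv.predictions,
        fit=fit,
        cv=cv,
    )
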