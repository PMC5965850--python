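"""Successor representations of scanpaths by temporal-difference learning.

For a state sequence s_1, s_2, ..., each observed transition i -> j updates
the sender column M_i of a 5 x 5 matrix M:

    M_i <- M_i + alpha * (e_j + gamma * M_j - M_i)

where e_j is the j-th standard basis column, alpha in (0, 1] is the learning
rate and gamma in [0, 1] the temporal discount.  M is initialized to zeros at
the start of every trial and updated transition-by-transition in temporal
order, each update reading the current matrix (standard online TD learning).
Self-transitions (i == j) are ordinary updates; dwelling in a state is part
of the signal.  The converged expectation of this rule under a fixed
column-stochastic transition law T is the discounted occupancy matrix

    M* = T (I - gamma * T)^{-1},

whose columns each sum to 1 / (1 - gamma); :func:`sr_fixed_point` computes it
analytically and serves as an independent oracle for the learner.

Matrix convention (throughout the package): entry ``M[r-1, c-1]`` is receiver
state r given sender state c — columns are senders, rows are receivers.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .exceptions import EmptyDatasetError, InvalidStateError

N_STATES = 5


def _check_params(alpha: float, gamma: float) -> None:
    # Closed upper bounds: grid searches legitimately select alpha = 1 and
    # gamma = 1 (gamma = 1 disables discounting; the analytic fixed point
    # then diverges, but finite-sequence TD learning remains well defined).
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")


def trial_sr(
    states: Iterable[int],
    alpha: float,
    gamma: float,
    n_states: int = N_STATES,
) -> np.ndarray:
    """Learn one trial's successor representation from its state sequence.

    Parameters
    ----------
    states
        Sequence of state labels in 1..n_states (a mapped scanpath).
    alpha, gamma
        TD learning rate and temporal discount.

    Returns
    -------
    ndarray of shape (n_states, n_states); the zero matrix for sequences
    with fewer than 2 fixations (no transitions).
    """
    _check_params(alpha, gamma)
    seq = np.asarray(list(states), dtype=np.int64)
    if seq.size and (seq.min() < 1 or seq.max() > n_states):
        raise InvalidStateError(
            f"states must lie in 1..{n_states}, got range "
            f"[{seq.min()}, {seq.max()}]"
        )
    M = np.zeros((n_states, n_states))
    if seq.size < 2:
        return M
    idx = seq - 1
    for t in range(seq.size - 1):
        i, j = idx[t], idx[t + 1]
        target = gamma * M[:, j].copy()
        target[j] += 1.0
        M[:, i] += alpha * (target - M[:, i])
    return M


def trial_srs(
    sequences: Mapping, alpha: float, gamma: float, n_states: int = N_STATES
) -> dict:
    """Compute a trial SR for every ``(participant, trial) -> sequence``."""
    return {
        key: trial_sr(seq, alpha, gamma, n_states) for key, seq in sequences.items()
    }


def mean_sr(matrices: Iterable[np.ndarray]) -> np.ndarray:
    """Entrywise mean of a collection of trial SR matrices."""
    mats = list(matrices)
    if not mats:
        raise EmptyDatasetError("mean_sr needs at least one trial SR")
    return np.mean(np.stack(mats), axis=0)


def participant_mean_srs(trial_mats: Mapping) -> dict:
    """Average trial SRs ``{(pid, tid): M}`` into per-participant means."""
    by_pid: dict = {}
    for (pid, _tid), M in trial_mats.items():
        by_pid.setdefault(pid, []).append(M)
    return {pid: mean_sr(ms) for pid, ms in by_pid.items()}


def sr_fixed_point(T: np.ndarray, gamma: float) -> np.ndarray:
    """Analytic TD fixed point M* = T (I - gamma T)^{-1}.

    ``T`` must be column-stochastic (columns are senders, matching the SR
    convention); requires gamma < 1 so the geometric series converges.
    Every column of M* sums to exactly 1 / (1 - gamma).
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be a square matrix")
    if np.any(T < -1e-12) or not np.allclose(T.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("T must be column-stochastic (columns sum to 1)")
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"fixed point requires 0 <= gamma < 1, got {gamma}")
    n = T.shape[0]
    return T @ np.linalg.inv(np.eye(n) - gamma * T)
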