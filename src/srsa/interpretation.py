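"""Finding illustrative scan patterns for a fitted SRSA model.

The prediction weight matrix is interpretable but abstract; to ground it,
the participants with the k highest and k lowest scores are selected, their
per-trial SRs (at the optimal TD parameters) are correlated with the mean
cross-validated prediction weights, and the scene with the greatest
difference between the two groups' mean correlations is picked.  Within
that scene the single most positively correlated high-group trial and most
negatively correlated low-group trial illustrate what high- and low-scoring
scanning actually looks like.  Positive correlation with the weights marks
a scan pattern predictive of a higher score.

Transition-free trials have a constant (zero) SR; their correlation is
undefined and they are excluded from the per-scene aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, NoCommonSceneError


def extreme_groups(scores: pd.Series | Mapping, k: int = 10) -> tuple[list, list]:
    """The k highest-scoring and k lowest-scoring participants.

    Boundary ties are broken deterministically by participant-id order
    (ascending id wins a tie for the low group; among equal scores at the
    high boundary the smaller id is likewise preferred).
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(scores)
    n = len(scores)
    if n < 2 * k:
        raise InsufficientDataError(f"need >= 2k = {2 * k} participants, got {n}")
    df = scores.rename("score").rename_axis("participant_id").reset_index()
    low = df.sort_values(["score", "participant_id"]).head(k)
    high = df.sort_values(["score", "participant_id"], ascending=[False, True]).head(k)
    return list(high["participant_id"]), list(low["participant_id"])


def trial_weight_correlations(
    trial_mats: Mapping, mean_weights: np.ndarray
) -> pd.DataFrame:
    """Correlate each trial SR with the mean prediction weight matrix.

    ``trial_mats`` maps ``(participant_id, trial_id) -> 5 x 5 SR``.  Returns
    a frame with columns ``participant_id, trial_id, r``; constant (e.g.
    zero-transition) trial SRs get ``r = NaN``.
    """
    w = np.asarray(mean_weights, dtype=float).ravel()
    if np.std(w) == 0.0:
        raise ValueError("mean_weights must be non-constant")
    rows = []
    for (pid, tid), M in trial_mats.items():
        v = np.asarray(M, dtype=float).ravel()
        r = np.nan if np.std(v) == 0.0 else float(np.corrcoef(v, w)[0, 1])
        rows.append({"participant_id": pid, "trial_id": tid, "r": r})
    return pd.DataFrame(rows, columns=["participant_id", "trial_id", "r"])


@dataclass
class IllustrativeTrial:
    """The most group-discriminating scene and its extreme trials."""

    scene: object  # trial_id of the argmax-delta scene
    high_participant: object
    low_participant: object
    high_r: float
    low_r: float
    deltas: pd.DataFrame  # per-scene: trial_id, mean_r_high, mean_r_low, delta


def select_illustrative_trial(
    correlations: pd.DataFrame,
    high_group: list,
    low_group: list,
    flat_tol: float = 1e-12,
) -> IllustrativeTrial:
    """Pick the scene maximizing (mean high-group r) - (mean low-group r).

    Within the winning scene, the high-group trial with maximal r and the
    low-group trial with minimal r are returned.  Ties in the per-scene
    delta are broken by trial-id order; if all deltas are (numerically)
    equal a flat-delta warning is emitted and the first scene returned.
    """
    c = correlations.dropna(subset=["r"])
    hi = c[c["participant_id"].isin(high_group)]
    lo = c[c["participant_id"].isin(low_group)]
    mh = hi.groupby("trial_id")["r"].mean().rename("mean_r_high")
    ml = lo.groupby("trial_id")["r"].mean().rename("mean_r_low")
    deltas = pd.concat([mh, ml], axis=1, join="inner")
    if len(deltas) == 0:
        raise NoCommonSceneError(
            "no scene has non-missing correlations in both groups"
        )
    deltas["delta"] = deltas["mean_r_high"] - deltas["mean_r_low"]
    deltas = deltas.sort_index().reset_index()
    if float(deltas["delta"].max() - deltas["delta"].min()) <= flat_tol:
        warnings.warn(
            "group difference is flat across scenes; selection is arbitrary",
            stacklevel=2,
        )
    scene = deltas.loc[deltas["delta"].idxmax(), "trial_id"]
    hi_scene = hi[hi["trial_id"] == scene].sort_values(["r", "participant_id"])
    lo_scene = lo[lo["trial_id"] == scene].sort_values(["r", "participant_id"])
    best_hi = hi_scene.iloc[-1]
    best_lo = lo_scene.iloc[0]
    return IllustrativeTrial(
        scene=scene,
        high_participant=best_hi["participant_id"],
        low_participant=best_lo["participant_id"],
        high_r=float(best_hi["r"]),
        low_r=float(best_lo["r"]),
        deltas=deltas,
    )
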