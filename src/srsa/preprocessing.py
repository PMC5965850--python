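"""Data-quality filtering and traditional eye-movement summary metrics.

The pipeline starts from fixation events (not raw gaze samples).  Quality
control mirrors common eye-tracking practice: participants whose mean
per-trial tracking-signal percentage falls below a threshold (default 75%)
are excluded, and the first fixation of every trial — always at the display
center because of the pretrial fixation cross — is removed as uninformative.

Traditional metrics summarize each participant by the mean and sample SD
(over trials) of per-trial mean fixation duration, per-trial mean saccade
amplitude, and per-trial fixation count.  Saccade amplitude is the Euclidean
distance between consecutive fixation centers, converted from pixels to
degrees of visual angle by a configurable scale (default from the display
geometry: a 1024-px-wide scene subtending ~29 degrees, i.e. ~35.3 px/deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, InsufficientDataError

#: default pixels-per-degree from the display geometry (1024 px ~ 29 deg)
DEFAULT_PX_PER_DEGREE = 1024.0 / 29.0

#: default minimum mean tracking-signal percentage for inclusion
DEFAULT_SIGNAL_THRESHOLD = 75.0

METRIC_COLUMNS = [
    "mean_fix_dur",
    "sd_fix_dur",
    "mean_sacc_amp",
    "sd_sacc_amp",
    "mean_fix_n",
    "sd_fix_n",
]


@dataclass(frozen=True)
class SignalFilterResult:
    """Outcome of the tracking-signal participant filter."""

    retained: list
    excluded: list
    report: pd.DataFrame  # participant_id, mean_signal, retained


def filter_participants_by_signal(
    signal: pd.DataFrame, threshold: float = DEFAULT_SIGNAL_THRESHOLD
) -> SignalFilterResult:
    """Retain participants whose mean trial signal percentage meets ``threshold``.

    ``signal`` needs columns ``participant_id, trial_id, signal_percent``.
    """
    if len(signal) == 0:
        raise EmptyDatasetError("signal table is empty")
    means = (
        signal.groupby("participant_id")["signal_percent"].mean().rename("mean_signal")
    )
    report = means.reset_index()
    report["retained"] = report["mean_signal"] >= threshold
    retained = sorted(report.loc[report["retained"], "participant_id"])
    excluded = sorted(report.loc[~report["retained"], "participant_id"])
    return SignalFilterResult(retained=retained, excluded=excluded, report=report)


def drop_first_fixation(fixations: pd.DataFrame) -> pd.DataFrame:
    """Remove each trial's first fixation and renumber orders from 1.

    Works on a whole fixation table at once; empty trials pass through.
    """
    if len(fixations) == 0:
        return fixations.copy()
    fx = fixations.sort_values(["participant_id", "trial_id", "order"]).copy()
    grp = fx.groupby(["participant_id", "trial_id"], sort=False)
    fx = fx.loc[grp.cumcount() > 0].copy()
    fx["order"] = (
        fx.groupby(["participant_id", "trial_id"], sort=False).cumcount() + 1
    )
    return fx.reset_index(drop=True)


def _trial_summaries(fixations: pd.DataFrame, px_per_degree: float) -> pd.DataFrame:
    fx = fixations.sort_values(["participant_id", "trial_id", "order"])
    g = fx.groupby(["participant_id", "trial_id"], sort=True)
    dur = g["duration_ms"].mean().rename("fix_dur")
    n = g.size().rename("fix_n")
    dx = g["x"].diff()
    dy = g["y"].diff()
    amp = np.hypot(dx, dy) / px_per_degree
    sacc = (
        amp.groupby([fx["participant_id"], fx["trial_id"]]).mean().rename("sacc_amp")
    )
    return pd.concat([dur, sacc, n], axis=1).reset_index()


def traditional_metrics(
    fixations: pd.DataFrame, px_per_degree: float = DEFAULT_PX_PER_DEGREE
) -> pd.DataFrame:
    """Per-participant traditional eye-metric table.

    Returns one row per participant with the mean and sample SD (n-1
    denominator, taken over trials) of fixation duration (ms), saccade
    amplitude (degrees), and fixation count per trial.  Requires at least
    2 trials per participant for the SDs to be defined.
    """
    if len(fixations) == 0:
        raise EmptyDatasetError("fixation table is empty")
    trials = _trial_summaries(fixations, px_per_degree)
    counts = trials.groupby("participant_id").size()
    if (counts < 2).any():
        bad = sorted(counts.index[counts < 2])
        raise InsufficientDataError(
            f"participants with < 2 trials (SD undefined): {bad}"
        )
    g = trials.groupby("participant_id")
    out = pd.DataFrame(
        {
            "mean_fix_dur": g["fix_dur"].mean(),
            "sd_fix_dur": g["fix_dur"].std(ddof=1),
            "mean_sacc_amp": g["sacc_amp"].mean(),
            "sd_sacc_amp": g["sacc_amp"].std(ddof=1),
            "mean_fix_n": g["fix_n"].mean().astype(float),
            "sd_fix_n": g["fix_n"].std(ddof=1),
        }
    )
    return out.reset_index()
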