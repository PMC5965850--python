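"""Seeded synthetic scene-viewing cohorts with planted trait structure.

The generator emulates the data shape of a scene-encoding eye-tracking
study — 40 participants x 40 scene trials x ~36 fixations per trial on a
1024 x 768 display — together with the statistical structure the SRSA
pipeline assumes, so every stage is testable without real recordings:

* each participant carries a latent trait z ~ N(0, 1); questionnaire
  scores are affine maps of z onto each measure's printed scale
  (attention-deficit 0-96, autism quotient 0-50, dyslexia 0-20), rounded
  to integers;
* scanpaths are state sequences in the vertical 5-state space.  Under
  ``effect_order="first_order"`` the sender-conditional transition law
  T(z) interpolates between a "low" matrix (broad vertical excursions)
  and a "high" matrix (sticky central states 2-3, short transitions) with
  weight effect_size * Phi(z), so the trait is visible in first-order
  statistics.  Under ``effect_order="second_order"`` all participants
  share one first-order law T0 and the trait modulates only the tendency
  to return to the state visited two steps back, so only temporally
  extended statistics carry signal;
* fixation coordinates are drawn uniformly within the assigned state's
  region; the first fixation of every trial sits at the display center
  (exercising first-fixation removal); durations are lognormal with a
  ~281 ms mean; designated dropout participants get per-trial tracking
  signal below the 75% inclusion threshold.

Ground truth (z, T(z), generator parameters) is returned separately and
written to a sidecar JSON so the analysis pipeline cannot read it by
accident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigError
from .state_spaces import StateSpace, build_state_space

# Transition laws, SR convention: columns are senders, rows receivers.
# "Low"-trait law: broad vertical excursions across bands 1-4, occasional
# border visits — written column-by-column, then transposed.
T_LOW = np.array(
    [
        [0.10, 0.20, 0.25, 0.35, 0.10],  # from state 1
        [0.25, 0.10, 0.25, 0.30, 0.10],  # from state 2
        [0.30, 0.25, 0.10, 0.25, 0.10],  # from state 3
        [0.35, 0.25, 0.20, 0.10, 0.10],  # from state 4
        [0.225, 0.225, 0.225, 0.225, 0.10],  # from state 5 (border)
    ]
).T

# "High"-trait law: strong pull toward the central bands 2-3 regardless of
# sender — sticky, short-transition scanning.  The pull is deliberately
# asymmetric (band 2 over band 3): the two central bands are mirror images
# about the display center, so this asymmetry is visible to the vertical
# geometry but not to the radiating one.
T_HIGH = np.tile(np.array([[0.06, 0.50, 0.32, 0.06, 0.06]]).T, (1, 5))

#: printed scale (lo, hi) and generating affine map (mean, sd) per measure
MEASURE_SCALES = {
    "attention_deficit": {"lo": 0, "hi": 96, "mean": 45.0, "sd": 15.0},
    "autism_quotient": {"lo": 0, "hi": 50, "mean": 18.0, "sd": 6.0},
    "dyslexia": {"lo": 0, "hi": 20, "mean": 7.0, "sd": 3.5},
}


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for one synthetic cohort."""

    n_participants: int = 40
    n_trials: int = 40
    mean_fixations_per_trial: float = 36.0
    display: tuple = (1024, 768)
    state_space_kind: str = "vertical"
    border_fraction: float = 0.10
    effect_size: float = 1.0
    effect_order: str = "first_order"
    #: restrict the trait effect to these trial ids (None = all trials)
    effect_trials: Optional[Sequence[int]] = None
    measures: tuple = ("attention_deficit", "autism_quotient", "dyslexia")
    duration_mean_ms: float = 281.0
    duration_sigma: float = 0.4
    signal_dropout: float = 0.0
    signal_threshold: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise ConfigError("participant and trial counts must be positive")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ConfigError("effect_size must be in [0, 1]")
        if self.effect_order not in ("first_order", "second_order"):
            raise ConfigError(f"unknown effect_order {self.effect_order!r}")
        if not (0.0 <= self.signal_dropout <= 1.0):
            raise ConfigError("signal_dropout must be in [0, 1]")
        if self.mean_fixations_per_trial < 2:
            raise ConfigError("mean_fixations_per_trial must be >= 2")
        unknown = set(self.measures) - set(MEASURE_SCALES)
        if unknown:
            raise ConfigError(f"unknown measures: {sorted(unknown)}")


@dataclass
class Cohort:
    """Generated cohort: analysis inputs plus sealed ground truth."""

    config: CohortConfig
    fixations: pd.DataFrame
    scores: pd.DataFrame
    signal: pd.DataFrame
    ground_truth: dict = field(repr=False)

    def score_series(self, measure: str) -> pd.Series:
        s = self.scores[self.scores["measure"] == measure]
        return s.set_index("participant_id")["score"].astype(float)

    def write(self, out_dir) -> dict:
        """Write fixations/scores/signal CSVs plus the ground-truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fixations": out / "fixations.csv",
            "scores": out / "scores.csv",
            "signal": out / "signal.csv",
            "ground_truth": out / "ground_truth.json",
        }
        self.fixations.to_csv(paths["fixations"], index=False)
        self.scores.to_csv(paths["scores"], index=False)
        self.signal.to_csv(paths["signal"], index=False)
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a column-stochastic chain (power method)."""
    pi = np.full(T.shape[0], 1.0 / T.shape[0])
    for _ in range(200):
        nxt = T @ pi
        if np.max(np.abs(nxt - pi)) < 1e-13:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def markov_law(config: CohortConfig, z: float) -> np.ndarray:
    """The first-order transition law T(z) a participant's trials follow.

    Under ``second_order`` the first-order law is the shared base chain,
    independent of z by construction.
    """
    if config.effect_order == "second_order":
        return 0.5 * (T_LOW + T_HIGH)
    w = config.effect_size * float(norm.cdf(z))
    return (1.0 - w) * T_LOW + w * T_HIGH


def _second_order_kernel(T0: np.ndarray, c: float) -> np.ndarray:
    """P(r | sender j, two-back k) with a trait-scaled return-to-k bonus.

    ``c`` is signed: positive plants a tendency to return to the state
    visited two steps back, negative a tendency to avoid it.  Built so
    that averaging over the base chain's reverse kernel pi0(k | j)
    recovers T0 exactly (residual mismatch O(c^2) once the realized
    chain's reverse kernel shifts; because the trait enters with both
    signs across the cohort, that even-order residual is essentially
    uncorrelated with the trait).  Returns a (r, j, k) tensor.
    """
    n = T0.shape[0]
    pi = stationary_distribution(T0)
    # pi0[k, j] = P(s_{t-2} = k | s_{t-1} = j)
    pi0 = (T0 * pi[None, :]).T
    pi0 /= pi0.sum(axis=0, keepdims=True)
    m = np.einsum("kj,kj->j", pi0, T0)  # E_k[T0[k, j]]
    P = np.empty((n, n, n))
    for k in range(n):
        for j in range(n):
            bracket = 1.0 + c * ((np.arange(n) == k) - T0[k, j] - pi0[:, j] + m[j])
            P[:, j, k] = T0[:, j] * bracket
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=0, keepdims=True)
    return P


def _participant_sequence(
    rng: np.random.Generator,
    n_steps: int,
    cdf_first: np.ndarray,
    pi_cdf: np.ndarray,
    cdf_second: Optional[np.ndarray],
) -> np.ndarray:
    """One trial's 0-based state sequence of length n_steps."""
    seq = np.empty(n_steps, dtype=np.int64)
    u = rng.random(n_steps)
    seq[0] = np.searchsorted(pi_cdf, u[0])
    for t in range(1, n_steps):
        j = seq[t - 1]
        if cdf_second is None or t < 2:
            seq[t] = np.searchsorted(cdf_first[:, j], u[t])
        else:
            seq[t] = np.searchsorted(cdf_second[:, j, seq[t - 2]], u[t])
    return seq


def _sample_points_in_states(
    space: StateSpace, states: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside each fixation's state region (vectorized)."""
    xs = np.empty(states.size)
    ys = np.empty(states.size)
    direct = space.kind in ("vertical", "horizontal")
    for state in range(1, space.n_states + 1):
        idx = np.flatnonzero(states == state)
        if idx.size == 0:
            continue
        x0, x1, y0, y1 = space.state_bounds(state)
        if direct and state < space.n_states:
            xs[idx] = rng.uniform(x0, x1, idx.size)
            ys[idx] = rng.uniform(y0, y1, idx.size)
            continue
        # annular regions (radiating rings, border): rejection sampling
        # from the bounding box of the outer boundary
        need = idx.size
        got_x = np.empty(need)
        got_y = np.empty(need)
        filled = 0
        while filled < need:
            m = max(64, 3 * (need - filled))
            cx = rng.uniform(x0, x1, m)
            cy = rng.uniform(y0, y1, m)
            ok = space.map_points(cx, cy) == state
            take = min(need - filled, int(ok.sum()))
            got_x[filled : filled + take] = cx[ok][:take]
            got_y[filled : filled + take] = cy[ok][:take]
            filled += take
        xs[idx] = got_x
        ys[idx] = got_y
    return xs, ys


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one seeded cohort (fixations, scores, signal, ground truth)."""
    rng = np.random.default_rng(config.seed)
    width, height = config.display
    space = build_state_space(
        config.state_space_kind, width, height, config.border_fraction
    )
    n = config.n_participants
    pad = max(2, len(str(n)))
    pids = [f"P{k:0{pad}d}" for k in range(1, n + 1)]
    z = rng.standard_normal(n)

    n_drop = int(round(config.signal_dropout * n))
    drop_idx = set(rng.choice(n, size=n_drop, replace=False).tolist())

    # scores on each questionnaire's printed scale
    score_rows = []
    for measure in config.measures:
        sc = MEASURE_SCALES[measure]
        vals = np.clip(np.rint(sc["mean"] + sc["sd"] * z), sc["lo"], sc["hi"])
        for pid, v in zip(pids, vals):
            score_rows.append(
                {"participant_id": pid, "measure": measure, "score": int(v)}
            )

    T0 = 0.5 * (T_LOW + T_HIGH)
    pi0_cdf = np.cumsum(stationary_distribution(T0))
    effect_trials = (
        None if config.effect_trials is None else set(config.effect_trials)
    )

    mu_dur = np.log(config.duration_mean_ms) - config.duration_sigma**2 / 2.0
    cx, cy = space.center

    fix_rows_pid = []
    fix_rows_tid = []
    fix_order = []
    fix_states = []  # 0 marks the forced central first fixation
    fix_dur = []
    signal_rows = []
    truth_participants = {}

    for p, pid in enumerate(pids):
        second = config.effect_order == "second_order"
        if second:
            # signed return/avoid coefficient for the two-back dependence
            w = config.effect_size * float(2.0 * norm.cdf(z[p]) - 1.0)
        else:
            w = config.effect_size * float(norm.cdf(z[p]))
        T_eff = markov_law(config, z[p])
        cdf_eff = np.cumsum(T_eff, axis=0)
        pi_eff_cdf = np.cumsum(stationary_distribution(T_eff))
        cdf2_eff = _second_order_kernel(T0, w).cumsum(axis=0) if second else None
        # effect-free law used on trials outside effect_trials: the
        # population-average law, so only designated scenes carry signal
        T_null = markov_law(config, 0.0)
        cdf_null = np.cumsum(T_null, axis=0)
        pi_null_cdf = np.cumsum(stationary_distribution(T_null))
        cdf2_null = (
            _second_order_kernel(T0, 0.0).cumsum(axis=0) if second else None
        )
        dropout = p in drop_idx
        for tid in range(1, config.n_trials + 1):
            n_fix = max(2, int(rng.poisson(config.mean_fixations_per_trial)))
            active = effect_trials is None or tid in effect_trials
            seq0 = _participant_sequence(
                rng,
                n_fix - 1,
                cdf_eff if active else cdf_null,
                pi_eff_cdf if active else pi_null_cdf,
                (cdf2_eff if active else cdf2_null) if second else None,
            )
            fix_rows_pid.extend([pid] * n_fix)
            fix_rows_tid.extend([tid] * n_fix)
            fix_order.extend(range(1, n_fix + 1))
            fix_states.append(np.concatenate(([0], seq0 + 1)))
            fix_dur.append(rng.lognormal(mu_dur, config.duration_sigma, n_fix))
            sig = rng.uniform(40.0, 70.0) if dropout else rng.uniform(85.0, 99.0)
            signal_rows.append(
                {
                    "participant_id": pid,
                    "trial_id": tid,
                    "signal_percent": round(float(sig), 2),
                }
            )
        truth_participants[pid] = {
            "z": float(z[p]),
            "effect_weight": w,
            "dropout": bool(dropout),
            "transition_law": np.round(T_eff, 10).tolist(),
        }

    states = np.concatenate(fix_states)
    xs = np.empty(states.size)
    ys = np.empty(states.size)
    central = states == 0
    xs[central], ys[central] = cx, cy
    xs[~central], ys[~central] = _sample_points_in_states(
        space, states[~central], rng
    )

    fixations = pd.DataFrame(
        {
            "participant_id": fix_rows_pid,
            "trial_id": fix_rows_tid,
            "order": fix_order,
            "x": np.round(xs, 3),
            "y": np.round(ys, 3),
            "duration_ms": np.round(np.concatenate(fix_dur), 1),
        }
    )
    scores = pd.DataFrame(score_rows, columns=["participant_id", "measure", "score"])
    signal = pd.DataFrame(
        signal_rows, columns=["participant_id", "trial_id", "signal_percent"]
    )
    ground_truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "participants": truth_participants,
        "t_low": T_LOW.tolist(),
        "t_high": T_HIGH.tolist(),
        "t_base_second_order": T0.tolist(),
    }
    return Cohort(
        config=config,
        fixations=fixations,
        scores=scores,
        signal=signal,
        ground_truth=ground_truth,
    )
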