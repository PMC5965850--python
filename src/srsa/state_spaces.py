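"""AOI state spaces for scene-viewing scanpaths.

A state space partitions the display into 5 labeled areas of interest
(AOIs): 4 inner regions plus an outer border (state 5) that captures the
central fixation bias — viewers rarely fixate the outer margin of a scene.
Three geometries are supported:

* ``radiating`` — 4 nested concentric rectangles from the scene center to
  the inner-rectangle edge (state 1 innermost), sensitive to center vs.
  periphery scanning;
* ``vertical`` — 4 equal-height horizontal bands (state 1 topmost),
  sensitive to vertical scanning;
* ``horizontal`` — 4 equal-width vertical columns (state 1 leftmost),
  sensitive to horizontal scanning.

Coordinates follow the display convention: origin at the top-left corner,
x rightward, y downward, in pixels.  All region intervals are half-open
``[lo, hi)``; any point outside the inner rectangle (including outside the
display) maps to border state 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    InconsistentTrialError,
    InvalidCoordinateError,
    UnsupportedStateSpaceError,
)

KINDS = ("radiating", "vertical", "horizontal")
N_STATES = 5

#: canonical fixation-table columns
FIXATION_COLUMNS = ["participant_id", "trial_id", "order", "x", "y", "duration_ms"]


@dataclass(frozen=True)
class StateSpace:
    """A 5-state partition of the display.

    Parameters
    ----------
    kind
        One of ``radiating``, ``vertical``, ``horizontal``.
    display_width, display_height
        Display size in pixels (default 1024 x 768).
    border_fraction
        Margin on each side assigned to border state 5, as a fraction of the
        display extent; must lie in (0, 0.5).
    """

    kind: str
    display_width: float = 1024.0
    display_height: float = 768.0
    border_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise UnsupportedStateSpaceError(
                f"unknown state-space kind {self.kind!r}; expected one of {KINDS}"
            )
        if not (0.0 < self.border_fraction < 0.5):
            raise ValueError(
                f"border_fraction must be in (0, 0.5), got {self.border_fraction}"
            )
        if self.display_width <= 0 or self.display_height <= 0:
            raise ValueError("display dimensions must be positive")

    # ---- derived geometry -------------------------------------------------

    @property
    def n_states(self) -> int:
        return N_STATES

    @property
    def inner_x(self) -> tuple[float, float]:
        """Half-open x-extent [lo, hi) of the inner (non-border) rectangle."""
        w, bf = self.display_width, self.border_fraction
        return (w * bf, w * (1.0 - bf))

    @property
    def inner_y(self) -> tuple[float, float]:
        h, bf = self.display_height, self.border_fraction
        return (h * bf, h * (1.0 - bf))

    @property
    def center(self) -> tuple[float, float]:
        return (self.display_width / 2.0, self.display_height / 2.0)

    # ---- mapping ----------------------------------------------------------

    def map_points(self, x, y) -> np.ndarray:
        """Vectorized map of coordinates to states 1-5.

        Any point outside the inner rectangle — including off-display
        points from tracker noise — maps to border state 5.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidCoordinateError("fixation coordinates must be finite")
        x0, x1 = self.inner_x
        y0, y1 = self.inner_y
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        states = np.full(np.broadcast(x, y).shape, N_STATES, dtype=np.int64)
        if self.kind == "vertical":
            band_h = (y1 - y0) / 4.0
            idx = np.floor((y - y0) / band_h).astype(np.int64)
            states[inside] = np.clip(idx[inside], 0, 3) + 1
        elif self.kind == "horizontal":
            col_w = (x1 - x0) / 4.0
            idx = np.floor((x - x0) / col_w).astype(np.int64)
            states[inside] = np.clip(idx[inside], 0, 3) + 1
        else:  # radiating
            cx, cy = self.center
            half_w = (x1 - x0) / 2.0
            half_h = (y1 - y0) / 2.0
            # Chebyshev-like distance normalized to the inner half-extent:
            # ring boundaries at fractions 1/4, 2/4, 3/4, 4/4.
            u = np.maximum(np.abs(x - cx) / half_w, np.abs(y - cy) / half_h)
            idx = np.floor(u * 4.0).astype(np.int64)
            states[inside] = np.clip(idx[inside], 0, 3) + 1
        return states

    def map_point(self, x: float, y: float) -> int:
        """Map a single (x, y) coordinate to its state (1-5)."""
        return int(self.map_points(np.atleast_1d(x), np.atleast_1d(y))[0])

    def state_bounds(self, state: int) -> tuple[float, float, float, float]:
        """Bounding rectangle (x_lo, x_hi, y_lo, y_hi) of a state region.

        For radiating states 2-4 and border state 5 the region is an annular
        frame; the bounding box of its outer boundary is returned (used for
        rejection sampling).
        """
        if not 1 <= state <= N_STATES:
            raise ValueError(f"state must be 1..{N_STATES}")
        x0, x1 = self.inner_x
        y0, y1 = self.inner_y
        if state == N_STATES:
            return (0.0, self.display_width, 0.0, self.display_height)
        if self.kind == "vertical":
            band_h = (y1 - y0) / 4.0
            return (x0, x1, y0 + (state - 1) * band_h, y0 + state * band_h)
        if self.kind == "horizontal":
            col_w = (x1 - x0) / 4.0
            return (x0 + (state - 1) * col_w, x0 + state * col_w, y0, y1)
        cx, cy = self.center
        hw = (x1 - x0) / 2.0 * state / 4.0
        hh = (y1 - y0) / 2.0 * state / 4.0
        return (cx - hw, cx + hw, cy - hh, cy + hh)


def build_state_space(
    kind: str,
    display_width: float = 1024.0,
    display_height: float = 768.0,
    border_fraction: float = 0.10,
) -> StateSpace:
    """Construct one of the three a-priori 5-state display partitions."""
    return StateSpace(kind, display_width, display_height, border_fraction)


def map_fixation(space: StateSpace, x: float, y: float) -> int:
    """Map one fixation position to its state (1-5)."""
    return space.map_point(x, y)


def map_scanpath(space: StateSpace, fixations: pd.DataFrame) -> np.ndarray:
    """Map a single trial's ordered fixations to a state sequence.

    ``fixations`` must hold a single (participant, trial); rows are taken in
    ``order`` order. Returns an int array of states, one per fixation.
    """
    if len(fixations) == 0:
        return np.empty(0, dtype=np.int64)
    if fixations["trial_id"].nunique() > 1 or fixations["participant_id"].nunique() > 1:
        raise InconsistentTrialError("map_scanpath expects fixations from a single trial")
    fx = fixations.sort_values("order")
    return space.map_points(fx["x"].to_numpy(), fx["y"].to_numpy())


def map_all_scanpaths(space: StateSpace, fixations: pd.DataFrame) -> dict:
    """Map every (participant, trial) group to a state sequence.

    Returns ``{(participant_id, trial_id): np.ndarray of states}``. This is
    the bulk entry point the pipeline uses; states for all rows are computed
    in one vectorized pass.
    """
    fx = fixations.sort_values(["participant_id", "trial_id", "order"])
    states = space.map_points(fx["x"].to_numpy(), fx["y"].to_numpy())
    out: dict = {}
    for key, grp_idx in fx.groupby(["participant_id", "trial_id"], sort=True).indices.items():
        out[key] = states[np.sort(grp_idx)]
    return out


def sequences_to_frame(sequences: dict) -> pd.DataFrame:
    """Serialize state sequences to the dash-joined CSV schema."""
    rows = [
        {
            "participant_id": pid,
            "trial_id": tid,
            "states": "-".join(str(int(s)) for s in seq),
        }
        for (pid, tid), seq in sequences.items()
    ]
    return pd.DataFrame(rows, columns=["participant_id", "trial_id", "states"])


def frame_to_sequences(frame: pd.DataFrame) -> dict:
    """Parse the dash-joined state-sequence schema back into arrays."""
    out = {}
    for row in frame.itertuples(index=False):
        s = str(row.states)
        seq = np.array([int(t) for t in s.split("-")] if s else [], dtype=np.int64)
        out[(row.participant_id, row.trial_id)] = seq
    return out
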