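import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srsa.exceptions import (
    InconsistentTrialError,
    InvalidCoordinateError,
    UnsupportedStateSpaceError,
)
from srsa.state_spaces import (
    build_state_space,
    frame_to_sequences,
    map_fixation,
    map_scanpath,
    sequences_to_frame,
)


class TestGeometry:
    def test_vertical_band_edges(self):
        sp = build_state_space("vertical", 1024, 768, 0.10)
        assert sp.inner_y == pytest.approx((76.8, 691.2))
        x0, x1, y0, y1 = sp.state_bounds(1)
        assert (y1 - y0) == pytest.approx(153.6)

    def test_horizontal_column_edges(self):
        sp = build_state_space("horizontal", 1024, 768, 0.10)
        assert sp.inner_x == pytest.approx((102.4, 921.6))
        x0, x1, _, _ = sp.state_bounds(3)
        assert (x1 - x0) == pytest.approx(204.8)

    def test_radiating_ring_half_heights(self):
        sp = build_state_space("radiating", 1024, 768, 0.10)
        for state, hh in zip(range(1, 5), (76.8, 153.6, 230.4, 307.2)):
            _, _, y0, y1 = sp.state_bounds(state)
            assert (y1 - y0) / 2 == pytest.approx(hh)
            assert (y0 + y1) / 2 == pytest.approx(384.0)

    @pytest.mark.parametrize("bad_bf", [0.0, 0.5, -0.1, 0.7])
    def test_border_fraction_domain(self, bad_bf):
        with pytest.raises(ValueError):
            build_state_space("vertical", border_fraction=bad_bf)

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnsupportedStateSpaceError):
            build_state_space("diagonal")


class TestMapFixation:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (512, 100, 1),  # inside topmost band
            (512, 400, 3),  # floor((400-76.8)/153.6) = 2 -> state 3
            (10, 384, 5),  # x in the left border margin
            (512, -50, 5),  # off-display maps to border
        ],
    )
    def test_vertical_examples(self, vertical_space, x, y, expected):
        assert map_fixation(vertical_space, x, y) == expected

    def test_half_open_boundaries(self, vertical_space):
        """A point on a shared edge belongs to the region below/right of it."""
        y0, y1 = vertical_space.inner_y
        assert vertical_space.map_point(512, y0) == 1  # inner lower edge
        assert vertical_space.map_point(512, y1) == 5  # outer edge -> border
        band_h = (y1 - y0) / 4
        assert vertical_space.map_point(512, y0 + band_h) == 2

    def test_radiating_center_and_corner(self):
        sp = build_state_space("radiating")
        assert sp.map_point(512, 384) == 1
        assert sp.map_point(0, 0) == 5
        assert sp.map_point(512, 384 + 200) == 3  # u = 200/307.2 in [2/4, 3/4)

    def test_non_finite_rejected(self, vertical_space):
        with pytest.raises(InvalidCoordinateError):
            vertical_space.map_point(np.nan, 100)
        with pytest.raises(InvalidCoordinateError):
            vertical_space.map_point(10, np.inf)


class TestMapScanpath:
    def test_sequence_example(self, vertical_space):
        fx = pd.DataFrame(
            {
                "participant_id": ["p"] * 3,
                "trial_id": [1] * 3,
                "order": [1, 2, 3],
                "x": [512, 512, 10],
                "y": [100, 400, 384],
                "duration_ms": [200.0] * 3,
            }
        )
        np.testing.assert_array_equal(map_scanpath(vertical_space, fx), [1, 3, 5])

    def test_empty_and_constant(self, vertical_space):
        empty = pd.DataFrame(
            columns=["participant_id", "trial_id", "order", "x", "y", "duration_ms"]
        )
        assert len(map_scanpath(vertical_space, empty)) == 0
        rep = pd.DataFrame(
            {
                "participant_id": ["p"] * 4,
                "trial_id": [1] * 4,
                "order": [1, 2, 3, 4],
                "x": [512.0] * 4,
                "y": [400.0] * 4,
                "duration_ms": [100.0] * 4,
            }
        )
        assert set(map_scanpath(vertical_space, rep)) == {3}

    def test_mixed_trials_rejected(self, vertical_space):
        fx = pd.DataFrame(
            {
                "participant_id": ["p", "p"],
                "trial_id": [1, 2],
                "order": [1, 1],
                "x": [10, 10],
                "y": [10, 10],
                "duration_ms": [100.0, 100.0],
            }
        )
        with pytest.raises(InconsistentTrialError):
            map_scanpath(vertical_space, fx)


class TestTilingProperties:
    @pytest.mark.parametrize("kind", ["radiating", "vertical", "horizontal"])
    def test_border_mass_matches_area(self, kind, rng):
        """Uniform points hit state 5 with probability 1 - (1 - 2 bf)^2."""
        bf = 0.10
        sp = build_state_space(kind, border_fraction=bf)
        n = 10_000
        x = rng.uniform(0, 1024, n)
        y = rng.uniform(0, 768, n)
        states = sp.map_points(x, y)
        assert set(np.unique(states)) <= {1, 2, 3, 4, 5}
        p5 = 1 - (1 - 2 * bf) ** 2
        se = np.sqrt(p5 * (1 - p5) / n)
        assert abs((states == 5).mean() - p5) < 3 * se

    def test_vertical_inner_states_equal_mass(self, vertical_space, rng):
        n = 40_000
        x = rng.uniform(0, 1024, n)
        y = rng.uniform(0, 768, n)
        states = vertical_space.map_points(x, y)
        counts = np.bincount(states, minlength=6)[1:5]
        inner = counts.sum()
        # 4 equal bands: each 1/4 of inner mass within binomial error
        se = np.sqrt(0.25 * 0.75 * inner)
        assert np.all(np.abs(counts - inner / 4) < 4 * se)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.floats(0, 1023.999),
        y=st.floats(0, 767.999),
    )
    def test_reflection_symmetry(self, x, y):
        """x -> width - x maps horizontal state k to 5 - k; border is fixed."""
        hsp = build_state_space("horizontal")
        vsp = build_state_space("vertical")
        s = hsp.map_point(x, y)
        s_ref = hsp.map_point(1024 - x - 1e-9, y)
        assert s_ref == (5 - s if s != 5 else 5)
        t = vsp.map_point(x, y)
        t_ref = vsp.map_point(x, 768 - y - 1e-9)
        assert t_ref == (5 - t if t != 5 else 5)


def test_sequence_roundtrip_csv_schema():
    seqs = {("p1", 1): np.array([1, 3, 5]), ("p1", 2): np.array([], dtype=int)}
    frame = sequences_to_frame(seqs)
    assert list(frame["states"]) == ["1-3-5", ""]
    back = frame_to_sequences(frame)
    np.testing.assert_array_equal(back[("p1", 1)], [1, 3, 5])
    assert len(back[("p1", 2)]) == 0
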