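import numpy as np
import pandas as pd
import pytest

from srsa.baselines import participant_mean_transitions
from srsa.exceptions import ConfigError
from srsa.preprocessing import drop_first_fixation, filter_participants_by_signal
from srsa.sr import participant_mean_srs, trial_srs
from srsa.state_spaces import build_state_space, map_all_scanpaths
from srsa.synthetic import (
    CohortConfig,
    MEASURE_SCALES,
    T_HIGH,
    T_LOW,
    generate_cohort,
    markov_law,
    stationary_distribution,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_participants": 0},
            {"effect_size": 1.5},
            {"effect_order": "third_order"},
            {"signal_dropout": -0.1},
            {"measures": ("iq",)},
            {"mean_fixations_per_trial": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CohortConfig(**kwargs)


class TestGeneratedShape:
    def test_fixation_totals_near_target(self, default_cohort):
        cfg = default_cohort.config
        totals = default_cohort.fixations.groupby("participant_id").size()
        target = cfg.n_trials * cfg.mean_fixations_per_trial
        assert abs(totals.mean() - target) / target < 0.10

    def test_first_fixation_at_center(self, default_cohort):
        firsts = default_cohort.fixations.query("order == 1")
        assert (firsts["x"] == 512.0).all()
        assert (firsts["y"] == 384.0).all()

    def test_durations_near_target_mean(self, default_cohort):
        dur = default_cohort.fixations["duration_ms"]
        assert dur.mean() == pytest.approx(281.0, rel=0.05)
        assert (dur > 0).all()

    def test_scores_on_printed_scales(self, default_cohort):
        for measure, sc in MEASURE_SCALES.items():
            vals = default_cohort.scores.query("measure == @measure")["score"]
            assert vals.between(sc["lo"], sc["hi"]).all()
            assert (vals == vals.astype(int)).all()

    def test_coordinates_match_assigned_states(self, default_cohort):
        """Mapping generated coordinates back recovers the generating states."""
        fx = drop_first_fixation(default_cohort.fixations)
        space = build_state_space("vertical")
        states = space.map_points(fx["x"].to_numpy(), fx["y"].to_numpy())
        # the generating chain visits every state
        assert set(np.unique(states)) == {1, 2, 3, 4, 5}


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_participants=4, n_trials=3, mean_fixations_per_trial=8, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        pa, pb = a.write(d1), b.write(d2)
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_participants=4, n_trials=2, seed=1))
        b = generate_cohort(CohortConfig(n_participants=4, n_trials=2, seed=2))
        assert not a.fixations.equals(b.fixations)


class TestPlantedStructure:
    def test_transition_frequencies_converge_to_law(self):
        """Empirical transitions approach T(z) columnwise (TV < 0.05)."""
        cfg = CohortConfig(
            n_participants=2, n_trials=8, mean_fixations_per_trial=1300, seed=21
        )
        cohort = generate_cohort(cfg)
        fx = drop_first_fixation(cohort.fixations)
        seqs = map_all_scanpaths(build_state_space("vertical"), fx)
        for pid, truth in cohort.ground_truth["participants"].items():
            T = np.array(truth["transition_law"])
            counts = np.zeros((5, 5))
            for (p, _t), seq in seqs.items():
                if p == pid:
                    np.add.at(counts, (seq[1:] - 1, seq[:-1] - 1), 1.0)
            emp = counts / counts.sum(axis=0, keepdims=True)
            tv = 0.5 * np.abs(emp - T).sum(axis=0).max()
            assert tv < 0.05

    def test_null_effect_carries_no_signal(self):
        """effect_size = 0: per-entry SR/score correlations average to ~0."""
        per_entry = []
        for seed in range(10):
            cohort = generate_cohort(CohortConfig(seed=500 + seed, effect_size=0.0))
            fx = drop_first_fixation(cohort.fixations)
            seqs = map_all_scanpaths(build_state_space("vertical"), fx)
            mats = participant_mean_srs(trial_srs(seqs, 0.7, 0.5))
            y = cohort.score_series("attention_deficit")
            pids = sorted(mats)
            X = np.stack([mats[p].ravel() for p in pids])
            yv = y.loc[pids].to_numpy()
            rs = np.array(
                [
                    np.corrcoef(X[:, k], yv)[0, 1] if np.std(X[:, k]) > 0 else 0.0
                    for k in range(25)
                ]
            )
            per_entry.append(rs)
        mean_abs = np.abs(np.mean(per_entry, axis=0))
        assert mean_abs.max() < 0.15

    def test_second_order_matches_first_order_marginals(self):
        """Trait leaves per-participant first-order frequencies ~unchanged."""
        cohort = generate_cohort(
            CohortConfig(seed=17, effect_order="second_order")
        )
        fx = drop_first_fixation(cohort.fixations)
        seqs = map_all_scanpaths(build_state_space("vertical"), fx)
        freqs = participant_mean_transitions(seqs)
        y = cohort.score_series("attention_deficit")
        pids = sorted(freqs)
        X = np.stack([freqs[p].ravel() for p in pids])
        yv = y.loc[pids].to_numpy()
        rs = [
            abs(np.corrcoef(X[:, k], yv)[0, 1])
            for k in range(25)
            if np.std(X[:, k]) > 0
        ]
        # every entry's |r| within what chance alone produces at n = 40
        assert np.median(rs) < 0.2 and max(rs) < 0.6

    def test_dropout_participants_fail_signal_filter(self):
        cohort = generate_cohort(
            CohortConfig(
                n_participants=12,
                n_trials=4,
                mean_fixations_per_trial=8,
                signal_dropout=0.25,
                seed=6,
            )
        )
        filt = filter_participants_by_signal(cohort.signal, 75.0)
        truth_drop = sorted(
            p
            for p, v in cohort.ground_truth["participants"].items()
            if v["dropout"]
        )
        assert filt.excluded == truth_drop
        assert len(truth_drop) == 3

    def test_effect_trials_restrict_coupling(self):
        """With the effect confined to one scene, other scenes share one law."""
        cohort = generate_cohort(
            CohortConfig(
                n_participants=6,
                n_trials=3,
                mean_fixations_per_trial=2000,
                effect_trials=[2],
                seed=30,
            )
        )
        fx = drop_first_fixation(cohort.fixations)
        seqs = map_all_scanpaths(build_state_space("vertical"), fx)
        T_null = markov_law(cohort.config, 0.0)
        pooled: dict = {}
        for (pid, tid), seq in seqs.items():
            if tid == 2:
                continue
            counts = pooled.setdefault(pid, np.zeros((5, 5)))
            np.add.at(counts, (seq[1:] - 1, seq[:-1] - 1), 1.0)
        for pid, counts in pooled.items():
            emp = counts / counts.sum(axis=0, keepdims=True)
            tv = 0.5 * np.abs(emp - T_null).sum(axis=0).max()
            assert tv < 0.1  # null scenes follow the shared law for everyone


def test_markov_law_interpolates():
    cfg = CohortConfig()
    np.testing.assert_allclose(markov_law(cfg, -50.0), T_LOW, atol=1e-8)
    np.testing.assert_allclose(markov_law(cfg, 50.0), T_HIGH, atol=1e-8)
    mid = markov_law(cfg, 0.0)
    np.testing.assert_allclose(mid, 0.5 * (T_LOW + T_HIGH), atol=1e-12)


def test_stationary_distribution_fixed_point():
    pi = stationary_distribution(T_LOW)
    np.testing.assert_allclose(T_LOW @ pi, pi, atol=1e-10)
    assert pi.sum() == pytest.approx(1.0)
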