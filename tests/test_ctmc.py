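"""Continuous-time Markov model: probabilities, compression, likelihood, fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from evoqg import ctmc

rate_arrays = st.lists(
    st.floats(0.01, 5.0, allow_nan=False), min_size=6, max_size=6
).map(np.array)


def naive_log_likelihood(Q: ctmc.RateMatrix, tracks: pd.DataFrame) -> float:
    """Independent oracle: per-pair sum of log transition probabilities,
    computed track by track with exactly-rounded summation."""
    terms = []
    for _, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("time_s")
        s = sub["state"].map(ctmc.STATE_INDEX).to_numpy()
        t = sub["time_s"].to_numpy()
        for a, b, dt in zip(s[:-1], s[1:], np.diff(t)):
            terms.append(math.log(expm(dt * Q.q)[a, b]))
    return math.fsum(terms)


class TestRateMatrix:
    def test_row_sums_zero(self):
        q = ctmc.RateMatrix(np.arange(1.0, 7.0)).q
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ctmc.InvalidRateMatrixError, match="SB"):
            ctmc.RateMatrix(np.array([1, -0.5, 1, 1, 1, 1.0]))

    def test_round_trip_from_q(self):
        theta = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert np.allclose(ctmc.RateMatrix.from_q(ctmc.RateMatrix(theta).q).theta, theta)


class TestTransitionProbability:
    def test_dt_zero_is_identity(self, q_example):
        assert np.allclose(ctmc.transition_probability(q_example, 0.0), np.eye(3))

    def test_symmetric_closed_form(self):
        # all off-diagonal rates r=1: p_ii = 1/3 + (2/3) e^{-3 r dt};
        # dt = ln(2)/3 gives p_ii = 2/3, p_ij = 1/6 exactly
        Q = ctmc.RateMatrix(np.ones(6))
        p = ctmc.transition_probability(Q, np.log(2.0) / 3.0)
        assert np.allclose(np.diag(p), 2.0 / 3.0, atol=1e-12)
        assert np.allclose(p[~np.eye(3, dtype=bool)], 1.0 / 6.0, atol=1e-12)

    def test_long_time_limit_is_stationary(self, q_example):
        p = ctmc.transition_probability(q_example, 1e3)
        f = ctmc.stationary_distribution(q_example)
        assert np.allclose(p, np.tile(f, (3, 1)), atol=1e-8)

    def test_negative_dt_rejected(self, q_example):
        with pytest.raises(ValueError):
            ctmc.transition_probability(q_example, -0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(theta=rate_arrays, dt1=st.floats(0.01, 2.0), dt2=st.floats(0.01, 2.0))
    def test_chapman_kolmogorov(self, theta, dt1, dt2):
        Q = ctmc.RateMatrix(theta)
        lhs = ctmc.transition_probability(Q, dt1 + dt2)
        rhs = ctmc.transition_probability(Q, dt1) @ ctmc.transition_probability(Q, dt2)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(theta=rate_arrays, dt=st.floats(0.01, 5.0))
    def test_rows_are_distributions(self, theta, dt):
        p = ctmc.transition_probability(ctmc.RateMatrix(theta), dt)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((p >= 0) & (p <= 1))


class TestStationaryDistribution:
    def test_symmetric_rates_uniform(self):
        f = ctmc.stationary_distribution(ctmc.RateMatrix(np.ones(6)))
        assert np.allclose(f, 1.0 / 3.0)

    def test_matches_null_space_oracle(self):
        # q_SF=q_SB=2, others 1: solve f Q = 0 by generic linear algebra
        Q = ctmc.RateMatrix(np.array([2.0, 2.0, 1.0, 1.0, 1.0, 1.0]))
        f = ctmc.stationary_distribution(Q)
        from scipy.linalg import null_space

        ns = null_space(Q.q.T)[:, 0]
        oracle = ns / ns.sum()
        assert np.allclose(f, oracle, atol=1e-10)
        assert np.allclose(f @ Q.q, 0.0, atol=1e-12)

    def test_consistent_with_long_time_probability(self, q_example):
        f = ctmc.stationary_distribution(q_example)
        p = ctmc.transition_probability(q_example, 1e4)
        assert np.allclose(p[0], f, atol=1e-6)

    def test_absorbing_state_rejected(self):
        # B never leaves: chain reducible
        Q = ctmc.RateMatrix(np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="reducible"):
            ctmc.stationary_distribution(Q)


class TestCompressTracks:
    def test_hand_counted_single_track(self):
        tracks = pd.DataFrame(
            {
                "track_id": ["a"] * 3,
                "plate_id": ["p"] * 3,
                "time_s": [0.0, 0.25, 0.5],
                "state": ["S", "S", "F"],
            }
        )
        tensor = ctmc.compress_tracks(tracks)
        assert len(tensor.dts) == 1 and tensor.dts[0] == 0.25
        expected = np.zeros((3, 3))
        expected[0, 0] = 1  # S->S
        expected[0, 1] = 1  # S->F
        assert np.array_equal(tensor.counts[0], expected)

    def test_empty_input(self):
        tensor = ctmc.compress_tracks(pd.DataFrame(columns=["track_id", "time_s", "state"]))
        assert tensor.total == 0

    def test_total_equals_pair_count(self, small_tracks):
        tensor = ctmc.compress_tracks(small_tracks)
        n_pairs = sum(len(g) - 1 for _, g in small_tracks.groupby("track_id"))
        assert tensor.total == n_pairs

    def test_non_increasing_timestamps_named(self):
        bad = pd.DataFrame(
            {"track_id": ["t7"] * 2, "time_s": [1.0, 1.0], "state": ["S", "F"]}
        )
        with pytest.raises(ValueError, match="t7"):
            ctmc.compress_tracks(bad)

    def test_dt_merge_tolerance(self):
        tracks = pd.DataFrame(
            {
                "track_id": ["a", "a", "b", "b"],
                "time_s": [0.0, 0.25, 0.0, 0.25 + 1e-9],
                "state": ["S", "F", "F", "B"],
            }
        )
        merged = ctmc.compress_tracks(tracks, dt_tolerance=1e-6)
        assert len(merged.dts) == 1
        split = ctmc.compress_tracks(tracks, dt_tolerance=0.0)
        assert len(split.dts) == 2


class TestLogLikelihood:
    def test_single_count_is_log_p(self, q_example):
        dt = 0.25
        counts = np.zeros((1, 3, 3))
        counts[0, 0, 1] = 1  # one S->F observation
        tensor = ctmc.TransitionCountTensor(np.array([dt]), counts)
        p = ctmc.transition_probability(q_example, dt)
        assert ctmc.log_likelihood(q_example, tensor) == pytest.approx(np.log(p[0, 1]))

    def test_impossible_transition_is_minus_inf(self):
        # zero rate matrix: off-diagonal transitions have probability 0
        Q = ctmc.RateMatrix(np.zeros(6))
        counts = np.zeros((1, 3, 3))
        counts[0, 0, 1] = 1
        tensor = ctmc.TransitionCountTensor(np.array([0.25]), counts)
        assert ctmc.log_likelihood(Q, tensor) == -np.inf

    def test_matches_per_pair_oracle(self, q_example, small_tracks):
        tensor = ctmc.compress_tracks(small_tracks)
        compressed = ctmc.log_likelihood(q_example, tensor)
        naive = naive_log_likelihood(q_example, small_tracks)
        assert abs(compressed - naive) < 1e-10

    def test_invariant_to_track_splitting(self, q_example, small_tracks):
        # relabel the second half of each track as a new track: the pair at
        # the split is lost, so add its contribution back; the likelihood of
        # the remaining pairs is unchanged
        tracks = small_tracks.copy()
        full = ctmc.log_likelihood(q_example, ctmc.compress_tracks(tracks))
        lost = 0.0
        pieces = []
        for tid, sub in tracks.groupby("track_id"):
            sub = sub.sort_values("time_s").reset_index(drop=True)
            k = len(sub) // 2
            if 0 < k < len(sub):
                a = sub.loc[k - 1, "state"]
                b = sub.loc[k, "state"]
                dt = sub.loc[k, "time_s"] - sub.loc[k - 1, "time_s"]
                p = ctmc.transition_probability(q_example, dt)
                lost += np.log(p[ctmc.STATE_INDEX[a], ctmc.STATE_INDEX[b]])
            sub.loc[: k - 1, "track_id"] = f"{tid}_head"
            sub.loc[k:, "track_id"] = f"{tid}_tail"
            pieces.append(sub)
        split = ctmc.log_likelihood(
            q_example, ctmc.compress_tracks(pd.concat(pieces))
        )
        assert split + lost == pytest.approx(full, abs=1e-8)


class TestFitTransitionRates:
    def test_map_recovery(self, q_example, small_tracks):
        tensor = ctmc.compress_tracks(small_tracks)
        post = ctmc.fit_transition_rates(tensor, seed=0)
        # ~6000 observation pairs: per-rate sampling error is several percent
        assert np.all(np.abs(post.map_rates / q_example.theta - 1) < 0.20)

    def test_deterministic_given_seed(self, small_tracks):
        tensor = ctmc.compress_tracks(small_tracks)
        a = ctmc.fit_transition_rates(tensor, seed=3)
        b = ctmc.fit_transition_rates(tensor, seed=3)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_unvisited_state_prior_dominated(self):
        # tracks that never enter B: rates out of B shrink to the prior scale
        tracks = pd.DataFrame(
            {
                "track_id": np.repeat([f"t{i}" for i in range(20)], 5),
                "time_s": np.tile(np.arange(5) * 0.25, 20),
                "state": np.tile(["S", "F", "S", "F", "S"], 20),
            }
        )
        tensor = ctmc.compress_tracks(tracks)
        with pytest.warns(UserWarning, match="prior-dominated"):
            post = ctmc.fit_transition_rates(tensor, seed=0)
        # BS, BF (indices 4, 5) are only weakly identified (multi-jump paths
        # through B contribute a little); modes stay inside the prior's
        # 95% range around ln 2
        assert np.all(np.abs(np.log(post.map_rates[4:]) - np.log(2.0)) < 1.2)

    def test_posterior_contracts_with_data(self, q_example):
        from evoqg import synthetic

        widths = []
        for n_tracks in (20, 80, 320):
            cfg = synthetic.TrackSimConfig(
                Q_true=q_example, n_tracks=n_tracks, mean_track_duration=20.0,
                burn_in_discard=0.0, seed=2,
            )
            tensor = ctmc.compress_tracks(synthetic.simulate_tracks(cfg))
            s = ctmc.fit_transition_rates(tensor, seed=0).summary()
            widths.append(np.mean(s["q97.5"] - s["q2.5"]))
        assert widths[0] > widths[1] > widths[2]

    def test_mcmc_agrees_with_laplace(self, small_tracks):
        tensor = ctmc.compress_tracks(small_tracks)
        lap = ctmc.fit_transition_rates(tensor, seed=0)
        mcmc = ctmc.fit_transition_rates(
            tensor, method="mcmc", seed=0, mcmc_steps=600, mcmc_burn=200
        )
        assert np.allclose(mcmc.samples.mean(axis=0), lap.samples.mean(axis=0), rtol=0.05)


class TestPredictedStateFrequencies:
    def test_single_state_tracks(self):
        Q = ctmc.RateMatrix(np.ones(6))
        tracks = pd.DataFrame(
            {
                "track_id": ["a"] * 4,
                "plate_id": ["p"] * 4,
                "time_s": np.arange(4) * 0.25,
                "state": ["F"] * 4,
            }
        )
        table, _ = ctmc.predicted_state_frequencies(Q, tracks)
        obs_f = table.loc[table["state"] == "F", "observed"].iloc[0]
        assert obs_f == 1.0

    def test_model_data_on_identity_line(self, q_example, small_tracks):
        table, summary = ctmc.predicted_state_frequencies(q_example, small_tracks)
        assert summary["rank_correlation"] > 0.9
        assert abs(summary["slope"] - 1.0) < 0.1

    def test_mismatched_model_detected(self, q_example, small_tracks):
        # a Q whose stationary distribution is far from the data's occupancy
        # must produce a slope away from 1 (the diagnostic's purpose)
        wrong = ctmc.RateMatrix(np.array([0.1, 0.1, 3.0, 0.1, 3.0, 0.1]))
        _, summary = ctmc.predicted_state_frequencies(wrong, small_tracks)
        assert abs(summary["slope"] - 1.0) > 0.1

    def test_semi_markov_dwell_times_still_near_identity(self):
        # gamma dwell times (strongly non-exponential) barely perturb the
        # occupancy-vs-stationary relation: the fitted chain absorbs the
        # dwell-time misspecification into effective rates
        rng = np.random.default_rng(4)
        rows = []
        mean_dwell = {"S": 0.5, "F": 1.0, "B": 0.25}
        for tid in range(100):
            t, state = 0.0, rng.choice(["S", "F", "B"])
            events = []
            while t < 30.0:
                events.append((t, state))
                t += rng.gamma(8.0, mean_dwell[state] / 8.0)
                state = rng.choice([s for s in "SFB" if s != state])
            times = np.arange(0, 30.0, 0.25)
            keep = rng.random(len(times)) >= 0.4
            times = times[keep]
            et = np.array([e[0] for e in events])
            es = [e[1] for e in events]
            idx = np.searchsorted(et, times, side="right") - 1
            for tt, i in zip(times, idx):
                rows.append((f"t{tid}", "p0", tt, es[i]))
        tracks = pd.DataFrame(rows, columns=["track_id", "plate_id", "time_s", "state"])
        tensor = ctmc.compress_tracks(tracks)
        post = ctmc.fit_transition_rates(tensor, seed=0)
        _, summary = ctmc.predicted_state_frequencies(post.map_matrix, tracks)
        assert summary["rank_correlation"] > 0.9
        assert abs(summary["slope"] - 1.0) < 0.05
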