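"""Monitoring engine: peers, ideal trajectories, z-scores, event chances."""

import numpy as np
import pandas as pd
import pytest

import mklabour as m
from mklabour.embedding import Trajectory
from mklabour.monitoring import (
    INFINITE_Z, NO_REFERENCE, REFERENCE_EXPIRED, TrajectoryIndex, deviation_z,
    estimate_ideal_trajectory, event_chance, event_time_distribution, find_peers,
    summarise_scores,
)


def _make_index(trajs, outcomes=None, events=None):
    ids = [t.subject_id for t in trajs]
    if outcomes is None:
        outcomes = pd.DataFrame(
            {"outcome_label": "uncomplicated", "cs_flag": False,
             "delivery_time": [t.times[-1] + 5.0 for t in trajs]},
            index=ids,
        )
    if events is None:
        events = pd.DataFrame(columns=["subject_id", "event", "t_event"])
    return TrajectoryIndex(trajs, outcomes, events)


def _line_traj(sid, x0, slope, times, dims=2):
    coords = np.zeros((len(times), dims))
    coords[:, 0] = x0 + slope * np.asarray(times)
    return Trajectory(sid, np.asarray(times, dtype=float), coords)


class TestFindPeers:
    def test_coincident_point_distance_zero(self):
        idx = _make_index([_line_traj("a", 0.0, 1.0, [0, 2, 4])])
        ps = find_peers(idx, np.array([2.0, 0.0]), t=2.0, radius=0.5, min_peers=0)
        assert ps.peer_ids == ["a"]
        assert ps.distances[0] == pytest.approx(0.0)

    def test_small_radius_empty(self):
        idx = _make_index([_line_traj("a", 0.0, 1.0, [0, 2, 4])])
        ps = find_peers(idx, np.array([100.0, 0.0]), t=2.0, radius=0.1, min_peers=0)
        assert len(ps) == 0 and not ps.expanded

    def test_expansion_flag(self):
        trajs = [_line_traj(f"s{i}", i, 0.0, [0, 5]) for i in range(5)]
        idx = _make_index(trajs)
        ps = find_peers(idx, np.array([0.0, 0.0]), t=1.0, radius=0.1, min_peers=3)
        assert ps.expanded and len(ps) >= 3

    def test_matches_brute_force(self, mid_pipeline):
        """Vectorised peer query equals a per-subject linear-scan oracle."""
        cohort, train_ids, test_ids, results, index = mid_pipeline
        rng = np.random.default_rng(0)
        out = cohort.outcomes
        for sid in test_ids[:5]:
            times, mat = cohort.state_matrix(sid)
            t = float(times[min(1, len(times) - 1)])
            q = results.project(mat[min(1, len(times) - 1)][None, :])[0]
            radius = index.default_radius * 3
            ps = find_peers(index, q, t=t, radius=radius, min_peers=0)
            # oracle: plain python interpolation over every training subject
            expected = {}
            for j, tid in enumerate(index.subject_ids):
                tt, tm = cohort.state_matrix(tid)
                if t > out.loc[tid, "delivery_time"] or t < tt[0]:
                    continue
                coords = results.project(tm)
                pos = np.array(
                    [np.interp(t, tt, coords[:, p]) for p in range(coords.shape[1])]
                )
                d = np.linalg.norm(pos - q)
                if d <= radius:
                    expected[tid] = d
            assert set(ps.peer_ids) == set(expected)
            for pid, d in zip(ps.peer_ids, ps.distances):
                assert d == pytest.approx(expected[pid], abs=1e-9)

    def test_peer_symmetry_identical_queries(self, mid_pipeline):
        _, _, _, _, index = mid_pipeline
        q = np.zeros(index.n_dims)
        a = find_peers(index, q, t=1.0, min_peers=5)
        b = find_peers(index, q, t=1.0, min_peers=5)
        assert a.peer_ids == b.peer_ids

    def test_empty_training_set_rejected(self):
        with pytest.raises(m.ValidationError):
            TrajectoryIndex([], pd.DataFrame(), pd.DataFrame())


class TestIdealTrajectory:
    def test_identical_peers_zero_dispersion(self):
        trajs = [_line_traj(f"s{i}", 1.0, 0.5, [0, 1, 2, 3]) for i in range(12)]
        idx = _make_index(trajs)
        ps = find_peers(idx, np.array([1.0, 0.0]), t=0.0, min_peers=12)
        ideal = estimate_ideal_trajectory(idx, ps, support_floor=10)
        assert ideal.available
        e, s, flag = ideal.at(1.0)
        assert flag is None
        assert e[0] == pytest.approx(1.5)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_two_constant_peers_midpoint_and_halfspread(self):
        trajs = [_line_traj("a", 1.0, 0.0, [0, 1, 2]), _line_traj("b", 3.0, 0.0, [0, 1, 2])]
        idx = _make_index(trajs)
        ps = find_peers(idx, np.array([2.0, 0.0]), t=0.0, min_peers=2)
        ideal = estimate_ideal_trajectory(idx, ps, support_floor=2)
        e, s, _ = ideal.at(1.0)
        assert e[0] == pytest.approx(2.0)
        assert s[0] == pytest.approx(1.0)  # |c1 - c2| / 2, population convention

    def test_crop_time_at_support_halving(self):
        """40 peers, 21 delivering before t = 9 h -> crop time 9 h."""
        trajs, deliveries = [], []
        for i in range(40):
            early = i < 21
            end = 8.9 if early else 20.0
            trajs.append(_line_traj(f"s{i}", 0.0, 0.1, [0, 4, 8]))
            deliveries.append(end)
        outcomes = pd.DataFrame(
            {"outcome_label": "uncomplicated", "cs_flag": False, "delivery_time": deliveries},
            index=[t.subject_id for t in trajs],
        )
        idx = _make_index(trajs, outcomes=outcomes)
        ps = find_peers(idx, np.array([0.0, 0.0]), t=0.0, min_peers=40)
        ideal = estimate_ideal_trajectory(idx, ps, grid_step=0.5, support_floor=2)
        assert ideal.support[0] == 40
        assert ideal.crop_time == pytest.approx(9.0)
        assert ideal.times[-1] < 9.0

    def test_no_uncomplicated_peers_flagged(self):
        trajs = [_line_traj(f"s{i}", 0.0, 1.0, [0, 1]) for i in range(12)]
        outcomes = pd.DataFrame(
            {"outcome_label": "adverse", "cs_flag": False, "delivery_time": 10.0},
            index=[t.subject_id for t in trajs],
        )
        idx = _make_index(trajs, outcomes=outcomes)
        ps = find_peers(idx, np.zeros(2), t=0.0, min_peers=12)
        ideal = estimate_ideal_trajectory(idx, ps)
        assert not ideal.available and ideal.flag == NO_REFERENCE


class TestDeviationZ:
    def _ideal(self, mean, sd, times=(0.0, 10.0), crop=np.inf):
        g = len(times)
        P = len(np.atleast_1d(mean))
        return m.IdealTrajectory(
            times=np.asarray(times, dtype=float),
            mean=np.tile(np.atleast_1d(mean), (g, 1)),
            sd=np.tile(np.atleast_1d(sd), (g, 1)),
            support=np.full(g, 30), crop_time=crop,
        )

    def test_zero_at_expected_position(self):
        z = deviation_z(np.array([2.0]), 1.0, self._ideal([2.0], [1.0]))
        assert z.value == 0.0 and z.valid

    def test_one_dimensional_definition(self):
        z = deviation_z(np.array([4.0]), 1.0, self._ideal([2.0], [1.0]))
        assert z.value == pytest.approx(2.0)

    def test_multidimensional_matches_formula(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=4)
        mean = rng.normal(size=4)
        sd = rng.uniform(0.5, 2.0, 4)
        z = deviation_z(q, 1.0, self._ideal(mean, sd))
        expected = np.linalg.norm(np.abs(q - mean) / sd) / np.sqrt(4)
        assert z.value == pytest.approx(expected)

    def test_scale_equivariance(self):
        q, mean, sd = np.array([3.0, 1.0]), np.array([1.0, 0.0]), np.array([1.0, 2.0])
        z1 = deviation_z(q, 1.0, self._ideal(mean, sd))
        z2 = deviation_z(q, 1.0, self._ideal(mean, 2 * sd))
        assert z2.value == pytest.approx(z1.value / 2)

    def test_zero_dispersion_nonzero_offset_infinite(self):
        z = deviation_z(np.array([1.0]), 1.0, self._ideal([0.0], [0.0]))
        assert np.isinf(z.value) and z.flag == INFINITE_Z

    def test_beyond_crop_expired(self):
        z = deviation_z(np.array([0.0]), 6.0, self._ideal([0.0], [1.0], crop=5.0))
        assert z.flag == REFERENCE_EXPIRED


class TestEventChance:
    def _idx_with_events(self, event_times):
        trajs = [_line_traj(f"s{i}", 0.0, 1.0, [0, 1]) for i in range(len(event_times))]
        rows = [
            {"subject_id": f"s{i}", "event": "ev", "t_event": t}
            for i, t in enumerate(event_times)
            if t is not None
        ]
        events = pd.DataFrame(rows, columns=["subject_id", "event", "t_event"])
        return _make_index(trajs, events=events)

    def test_all_future_chance_one(self):
        idx = self._idx_with_events([5.0] * 10)
        ps = find_peers(idx, np.zeros(2), t=0.0, min_peers=10)
        assert event_chance(idx, ps, "ev", 0.0).value == 1.0

    def test_no_events_chance_zero(self):
        idx = self._idx_with_events([None] * 10)
        ps = find_peers(idx, np.zeros(2), t=0.0, min_peers=10)
        assert event_chance(idx, ps, "ev", 0.0).value == 0.0

    def test_counting_oracle(self):
        times = [1.0] * 13 + [9.0] * 7  # 7 of 20 after t = 5
        idx = self._idx_with_events(times)
        ps = find_peers(idx, np.zeros(2), t=0.5, min_peers=20)
        assert event_chance(idx, ps, "ev", 5.0).value == pytest.approx(0.35)

    def test_removing_future_event_peer_never_increases(self):
        times = [1.0] * 5 + [9.0] * 5
        idx = self._idx_with_events(times)
        ps = find_peers(idx, np.zeros(2), t=0.5, min_peers=10)
        full = event_chance(idx, ps, "ev", 5.0).value
        # drop one peer whose event lies ahead
        drop = next(i for i, pid in enumerate(ps.peer_ids) if pid in [f"s{j}" for j in range(5, 10)])
        ps.peer_indices = np.delete(ps.peer_indices, drop)
        ps.peer_ids = [p for k, p in enumerate(ps.peer_ids) if k != drop]
        reduced = event_chance(idx, ps, "ev", 5.0).value
        assert reduced <= full

    def test_empty_peerset_flagged(self):
        idx = self._idx_with_events([1.0])
        ps = find_peers(idx, np.array([50.0, 0.0]), t=0.0, radius=0.1, min_peers=0)
        assert not event_chance(idx, ps, "ev", 0.0).valid


class TestEventTimeDistribution:
    def _ps(self, idx):
        return find_peers(idx, np.zeros(2), t=0.0, min_peers=idx.n)

    def test_single_event_step(self):
        idx = TestEventChance()._idx_with_events([5.0])
        dist = event_time_distribution(idx, self._ps(idx), "ev")
        support, cdf = dist.cdf
        np.testing.assert_allclose(support, [5.0])
        np.testing.assert_allclose(cdf, [1.0])
        assert dist.cdf_at(4.9) == 0.0 and dist.cdf_at(5.0) == 1.0

    def test_cdf_monotone_ends_at_one(self):
        idx = TestEventChance()._idx_with_events([3.0, 1.0, 7.0, 2.0])
        dist = event_time_distribution(idx, self._ps(idx), "ev")
        _, cdf = dist.cdf
        assert np.all(np.diff(cdf) >= 0) and cdf[-1] == 1.0

    def test_median_matches_numpy(self):
        times = [3.0, 1.0, 7.0, 2.0, 9.0]
        idx = TestEventChance()._idx_with_events(times)
        dist = event_time_distribution(idx, self._ps(idx), "ev")
        assert dist.median() == pytest.approx(np.median(times))

    def test_no_occurrences_flagged(self):
        idx = TestEventChance()._idx_with_events([None, None])
        dist = event_time_distribution(idx, self._ps(idx), "ev")
        assert dist.flag is not None


class TestScores:
    def test_zero_z_zeroes_products(self):
        times = np.array([0.0, 2.0])
        vpi, vpiz, vpizt = summarise_scores(
            times, np.array([0.4, 0.6]), np.array([0.0, 0.0]), [None, None], [None, None]
        )
        assert (vpi, vpiz, vpizt) == (0.6, 0.0, 0.0)

    def test_single_followup_arithmetic(self):
        vpi, vpiz, vpizt = summarise_scores(
            np.array([4.0]), np.array([0.5]), np.array([1.2]), [None], [None]
        )
        assert vpi == pytest.approx(0.5)
        assert vpiz == pytest.approx(0.6)
        assert vpizt == pytest.approx(2.4)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0, 10, 6))
        pi = rng.uniform(0, 1, 6)
        z = rng.uniform(0, 3, 6)
        vpi, vpiz, vpizt = summarise_scores(times, pi, z, [None] * 6, [None] * 6)
        assert vpi == pytest.approx(pi.max())
        assert vpiz == pytest.approx((pi * z).max())
        assert vpizt == pytest.approx((pi * z * times).max())

    def test_flagged_entries_excluded(self):
        times = np.array([0.0, 1.0])
        vpi, vpiz, vpizt = summarise_scores(
            times, np.array([0.9, 0.2]), np.array([np.inf, 1.0]),
            [None, None], ["infinite_z", None],
        )
        assert vpi == pytest.approx(0.9)
        assert vpiz == pytest.approx(0.2)

    def test_prospective_validity(self, mid_pipeline):
        """Scores at follow-up k are unchanged by truncating later follow-ups."""
        cohort, train_ids, test_ids, results, index = mid_pipeline
        session = m.MonitoringSession(results, index, min_peers=10)
        sid = test_ids[0]
        states = cohort.subject_states(sid)
        if len(states) < 2:
            pytest.skip("subject has a single follow-up")
        full = session.score_subject(states)
        trunc = session.score_subject(states[:2])
        np.testing.assert_allclose(full.pi[:2], trunc.pi[:2], equal_nan=True)
        np.testing.assert_allclose(full.z[:2], trunc.z[:2], equal_nan=True)

    def test_session_log_and_cohort_scores(self, mid_pipeline):
        cohort, train_ids, test_ids, results, index = mid_pipeline
        session = m.MonitoringSession(results, index, min_peers=10)
        scores = session.score_cohort(cohort, test_ids[:5])
        assert list(scores.columns) == ["vpi", "vpiz", "vpizt"]
        assert len(scores) == 5
        log = session.session_log()
        assert {"subject_id", "t", "n_peers", "pi", "z"} <= set(log.columns)
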