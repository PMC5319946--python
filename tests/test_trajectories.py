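import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rataffect import trajectories as tj
from tests.conftest import make_trajectory


def circle_path(radius, duration, speed, n_per_s=10, t0=0.0, start_angle=0.0):
    """(times, xy) breakpoints along a circle at constant speed."""
    n = max(int(duration * n_per_s), 2)
    t = np.linspace(0, duration, n)
    theta = start_angle + speed * t / radius
    return t0 + t, np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)


class TestPathLength:
    def test_unit_square_once(self, of_arena):
        xy = [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)]
        traj = make_trajectory([0, 10, 20, 30, 40], xy, of_arena)
        assert tj.path_length(traj) == pytest.approx(4.0)

    def test_stationary_is_zero(self, of_arena):
        traj = make_trajectory([0, 150, 300], [(5, 5)] * 3, of_arena)
        assert tj.path_length(traj) == 0.0

    def test_single_sample_warns(self, of_arena):
        traj = make_trajectory([0], [(0, 0)], of_arena)
        with pytest.warns(UserWarning):
            assert tj.path_length(traj) == 0.0

    def test_matches_per_segment_oracle(self, of_arena, rng):
        n = 200
        xy = rng.uniform(-30, 30, size=(n, 2))
        times = np.sort(rng.uniform(0, 300, size=n))
        times += np.arange(n) * 1e-9  # enforce strict increase
        traj = make_trajectory(times, xy, of_arena)
        oracle = sum(
            math.dist(xy[i], xy[i + 1]) for i in range(n - 1)
        ) / 100.0
        assert tj.path_length(traj) == pytest.approx(oracle)


class TestOFMetrics:
    def test_entirely_inner(self, of_arena):
        t, xy = circle_path(15.0, 300.0, 5.0)
        m = tj.of_metrics(make_trajectory(t, xy, of_arena))
        assert m.it_pct == pytest.approx(100.0)
        assert m.id_pct == pytest.approx(100.0)
        assert m.inner_distance_m == pytest.approx(m.total_distance_m)

    def test_entirely_in_annulus(self, of_arena):
        t, xy = circle_path(40.0, 300.0, 5.0)
        m = tj.of_metrics(make_trajectory(t, xy, of_arena))
        assert m.it_pct == 0.0
        assert m.id_pct == 0.0

    def test_two_phase_trajectory_exact_fifty_fifty(self, of_arena):
        # closed-form construction at constant speed v = 4 cm/s:
        # 600 cm inside the inner circle (150 s), a single radial
        # crossing split exactly at the 30-cm boundary, 600 cm in the
        # annulus (150 s) -> IT% = ID% = 50 exactly.
        v = 4.0
        times, xy = [0.0], [(0.0, 0.0)]

        def leg(x, y):
            d = math.dist(xy[-1], (x, y))
            times.append(times[-1] + d / v)
            xy.append((x, y))

        for k in range(39):  # 39 x 15 cm = 585 cm inner, ends at x = 15
            leg(15.0 if k % 2 == 0 else 0.0, 0.0)
        leg(40.0, 0.0)  # crossing: 15 cm inner + 10 cm outer
        for k in range(196):  # 196 x 3 cm = 588 cm outer
            leg(43.0 if k % 2 == 0 else 40.0, 0.0)
        leg(42.0, 0.0)  # final 2 cm -> outer total 588 + 10 + 2 = 600
        assert times[-1] == pytest.approx(300.0)
        m = tj.of_metrics(make_trajectory(times, xy, of_arena, duration=300.0))
        assert m.it_pct == pytest.approx(50.0, abs=1e-6)
        assert m.id_pct == pytest.approx(50.0, abs=1e-6)
        assert m.total_distance_m == pytest.approx(12.0, abs=1e-9)

    def test_stationary_trial_flagged_zero_id(self, of_arena):
        traj = make_trajectory([0, 300], [(0, 0), (0, 0)], of_arena)
        m = tj.of_metrics(traj)
        assert m.id_pct == 0.0
        assert "stationary" in m.flags
        assert m.it_pct == pytest.approx(100.0)  # parked at the centre

    def test_truncated_trace_flag_and_strict(self, of_arena):
        t, xy = circle_path(20.0, 100.0, 5.0)
        traj = make_trajectory(t, xy, of_arena)
        m = tj.of_metrics(traj)
        assert "truncated_trace" in m.flags
        with pytest.raises(ValueError):
            tj.of_metrics(traj, strict=True)

    def test_it_denominator_is_fixed_300(self, of_arena):
        # 100 s entirely inner out of a 300-s trial: IT% uses /300
        t, xy = circle_path(10.0, 100.0, 3.0)
        m = tj.of_metrics(make_trajectory(t, xy, of_arena))
        assert m.it_pct == pytest.approx(100.0 * 100.0 / 300.0, rel=1e-6)

    def test_rotation_invariance(self, of_arena, rng):
        n = 400
        steps = rng.normal(scale=2.0, size=(n, 2))
        xy = np.cumsum(steps, axis=0)
        xy = xy / max(1.0, np.hypot(*xy.T).max() / 44.0)  # keep in arena
        times = np.linspace(0, 300, n)
        base = tj.of_metrics(make_trajectory(times, xy, of_arena))
        a = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        rotated = tj.of_metrics(make_trajectory(times, xy @ rot.T, of_arena))
        assert rotated.total_distance_m == pytest.approx(base.total_distance_m)
        assert rotated.inner_distance_m == pytest.approx(base.inner_distance_m)
        assert rotated.inner_time_s == pytest.approx(base.inner_time_s)

    def test_inner_never_exceeds_total(self, of_arena, rng):
        for _ in range(20):
            n = 100
            xy = rng.uniform(-44, 44, size=(n, 2))
            xy = xy[np.hypot(*xy.T) <= 44.5]
            if len(xy) < 2:
                continue
            times = np.linspace(0, 300, len(xy))
            m = tj.of_metrics(make_trajectory(times, xy, of_arena))
            assert 0.0 <= m.inner_distance_m <= m.total_distance_m + 1e-12
            assert 0.0 <= m.inner_time_s <= 300.0 + 1e-9

    def test_zone_times_sum_to_trial(self, of_arena, rng):
        n = 500
        xy = np.cumsum(rng.normal(scale=1.5, size=(n, 2)), axis=0)
        xy = xy / max(1.0, np.hypot(*xy.T).max() / 40.0)
        times = np.linspace(0, 300, n)
        m = tj.of_metrics(make_trajectory(times, xy, of_arena))
        outer_time = 300.0 - m.inner_time_s
        assert 0.0 <= outer_time <= 300.0


class TestEPM:
    def _visit_path(self, epm_arena, visits, dwell=10.0, gap=2.0):
        """Scripted path: centre, then a list of 'open'/'closed' visits."""
        dt = 0.5
        times, xy, labels = [], [], []
        t = 0.0

        def emit(pos, dur, lab):
            nonlocal t
            for _ in range(int(dur / dt)):
                times.append(t)
                xy.append(pos)
                labels.append(lab)
                t += dt

        emit((0.0, 0.0), gap, "centre")
        for z in visits:
            pos = (20.0, 0.0) if z == "open" else (0.0, 20.0)
            emit(pos, dwell, z)
            emit((0.0, 0.0), gap, "centre")
        return make_trajectory(times, xy, epm_arena, duration=300.0), labels

    def test_never_leaves_centre(self, epm_arena):
        traj = make_trajectory(
            np.linspace(0, 300, 601), np.tile([(1.0, -1.0)], (601, 1)), epm_arena
        )
        m = tj.epm_metrics(traj)
        assert m.open_time_s == 0.0
        assert m.open_entries == 0 and m.closed_entries == 0
        assert m.oe_pct is None
        assert "no_entries" in m.flags

    def test_three_open_three_closed_gives_fifty(self, epm_arena):
        traj, _ = self._visit_path(
            epm_arena, ["open", "closed", "open", "closed", "open", "closed"]
        )
        m = tj.epm_metrics(traj)
        assert m.open_entries == 3 and m.closed_entries == 3
        assert m.oe_pct == pytest.approx(50.0)

    def test_ot_denominator_fixed_300(self, epm_arena):
        traj, _ = self._visit_path(epm_arena, ["open"], dwell=30.0)
        m = tj.epm_metrics(traj)
        assert m.ot_pct == pytest.approx(100.0 * 30.0 / 300.0)

    def test_zone_labels(self, epm_arena):
        labels = tj.epm_zone_labels(
            np.array([[0, 0], [20, 0], [-20, 2], [0, 20], [3, -20]]), epm_arena
        )
        assert list(labels) == ["centre", "open", "open", "closed", "closed"]

    def test_outside_position_rejected(self, epm_arena):
        with pytest.raises(ValueError):
            tj.epm_zone_labels(np.array([[20.0, 20.0]]), epm_arena)

    def test_zone_times_sum_to_covered_duration(self, epm_arena):
        traj, _ = self._visit_path(epm_arena, ["open", "closed", "open"])
        m = tj.epm_metrics(traj)
        covered = traj.times[-1] - traj.times[0]
        total = m.open_time_s + m.closed_time_s + m.centre_time_s
        assert total == pytest.approx(covered, abs=0.5 + 1e-9)


class TestCountEntries:
    def test_centre_open_centre_open(self):
        labels = ["centre"] * 4 + ["open"] * 4 + ["centre"] * 4 + ["open"] * 4
        times = np.arange(len(labels), dtype=float)
        assert tj.count_entries(labels, times, debounce=0)["open"] == 2

    def test_flicker_below_debounce_not_counted(self):
        labels = ["centre"] * 10 + ["open"] + ["centre"] * 10
        times = np.arange(len(labels)) * 0.1
        counts = tj.count_entries(labels, times, debounce=0.5)
        assert counts.get("open", 0) == 0

    def test_debounce_zero_equals_naive_transition_count(self, rng):
        for _ in range(25):
            labels = list(rng.choice(["open", "closed", "centre"], size=60))
            times = np.arange(60, dtype=float)
            counts = tj.count_entries(labels, times, debounce=0)
            naive = {}
            for prev, cur in zip(labels, labels[1:]):
                if cur != prev:
                    naive[cur] = naive.get(cur, 0) + 1
            for z in ("open", "closed", "centre"):
                assert counts.get(z, 0) == naive.get(z, 0)

    def test_rle_oracle_on_scripted_sequence(self, rng):
        # entries equal a run-length-encoding count of arm visits
        seq = ["centre", "open", "centre", "closed", "closed", "centre",
               "open", "open", "closed", "centre", "open"]
        labels = [z for z in seq for _ in range(4)]  # each run 4 s > debounce
        times = np.arange(len(labels), dtype=float)
        counts = tj.count_entries(labels, times, debounce=0.5)
        runs = [seq[0]] + [b for a, b in zip(seq, seq[1:]) if b != a]
        assert counts["open"] == sum(
            1 for a, b in zip(runs, runs[1:]) if b == "open"
        )
        assert counts["closed"] == sum(
            1 for a, b in zip(runs, runs[1:]) if b == "closed"
        )


class TestTrajectoryValidation:
    def test_times_must_increase(self, of_arena):
        with pytest.raises(ValueError):
            make_trajectory([0, 0], [(0, 0), (1, 1)], of_arena)

    def test_times_within_trial(self, of_arena):
        with pytest.raises(ValueError):
            make_trajectory([0, 301], [(0, 0), (1, 1)], of_arena)

    def test_arena_geometry_validated(self):
        with pytest.raises(ValueError):
            tj.OpenFieldArena(outer_diameter=50, inner_diameter=60)
        with pytest.raises(ValueError):
            tj.EPMArena(arm_width=0)

    def test_wrong_arena_kind_rejected(self, of_arena, epm_arena):
        t, xy = circle_path(20.0, 300.0, 5.0)
        with pytest.raises(ValueError):
            tj.epm_metrics(make_trajectory(t, xy, of_arena))
        traj = make_trajectory(
            np.linspace(0, 300, 10), np.zeros((10, 2)) + 0.1, epm_arena
        )
        with pytest.raises(ValueError):
            tj.of_metrics(traj)
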