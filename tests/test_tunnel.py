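"""Space-time tunnels, 3-D intersection and the exposure index."""

import warnings

import numpy as np
import pandas as pd
import pytest

from expocube import StudyConfig
from expocube.cube import build_cube, refine_cube, to_point_cloud
from expocube.preprocess import Trajectory, flag_valid_days, impute_gaps
from expocube.tunnel import (
    build_tunnel,
    ecei,
    intersect,
    participant_ecei,
    point_weight,
    standardize,
)

from conftest import make_day_trajectory
from test_decay import registry_at


@pytest.fixture(scope="module")
def cfg():
    return StudyConfig(grid_extent=(0.0, 0.0, 2000.0, 2000.0),
                       spatial_resolutions=(100.0,))


@pytest.fixture(scope="module")
def cube_24h(cfg):
    return build_cube(registry_at([(500, 500), (1200, 1500)]), "weekday",
                      "NEDD", 100.0, 500.0, cfg)


def stationary_traj(x, y, date="2009-08-03"):
    pos = np.tile([x, y], (1440, 1))
    return make_day_trajectory("P", date, pos)


class TestPointWeight:
    @pytest.mark.parametrize("v,w", [(0.0, 1.0), (1.0, 0.5), (2.0, 0.25)])
    def test_velocity_mode_halves_per_unit_speed(self, v, w):
        assert point_weight(v, "velocity") == pytest.approx(w)

    @pytest.mark.parametrize("v", [0.0, 1.0, 7.3, 100.0])
    def test_constant_mode_always_one(self, v):
        assert point_weight(v, "constant") == 1.0

    def test_negative_velocity_fatal(self):
        with pytest.raises(ValueError, match="non-negative"):
            point_weight(-1.0, "velocity")


class TestEcei:
    def test_single_point(self):
        pts = pd.DataFrame({"value": [2.0], "weight": [1.0]})
        assert ecei(pts, T=1.0) == 2.0

    def test_uniform_cloud_closed_form(self):
        c, n, T = 0.7, 40, 5.0
        pts = pd.DataFrame({"value": np.full(n, c), "weight": np.ones(n)})
        assert ecei(pts, T) == pytest.approx(c * n / T)

    def test_matches_resummation_oracle(self):
        rng = np.random.default_rng(21)
        pts = pd.DataFrame({"value": rng.uniform(0, 5, 300),
                            "weight": rng.uniform(0, 1, 300)})
        oracle = sum(v * w for v, w in zip(pts["value"], pts["weight"])) / 3.0
        assert ecei(pts, 3.0) == pytest.approx(oracle, rel=1e-12)

    def test_non_positive_T_fatal(self):
        with pytest.raises(ValueError, match="T"):
            ecei(pd.DataFrame({"value": [1.0], "weight": [1.0]}), 0.0)


class TestStandardize:
    def test_closed_form_three_values(self):
        recs = pd.DataFrame({"method_key": "A", "ecei_raw": [1.0, 2.0, 3.0]})
        out = standardize(recs)
        np.testing.assert_allclose(out["ecei_z"], [-1.0, 0.0, 1.0])

    def test_single_participant_degenerate(self):
        recs = pd.DataFrame({"method_key": "A", "ecei_raw": [5.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            out = standardize(recs)
        assert out["ecei_z"].iloc[0] == 0.0

    def test_cohort_moments(self):
        rng = np.random.default_rng(22)
        recs = pd.DataFrame({"method_key": "A",
                             "ecei_raw": rng.uniform(0, 9, 46)})
        out = standardize(recs)
        assert abs(out["ecei_z"].mean()) < 1e-12
        assert abs(out["ecei_z"].std(ddof=1) - 1.0) < 1e-12


class TestTunnelGeometry:
    def test_stationary_day_gives_full_cylinder_coverage(self, cfg):
        t = stationary_traj(550.0, 550.0)
        tun = build_tunnel(t, "weekday", br=100.0)
        assert tun.n_days == 1
        assert tun.observed_minutes() == 1440

    def test_stationary_at_centroid_intersects_one_column(self, cfg, cube_24h):
        # br below half the cell size: only the occupied cell's centroid hits
        t = stationary_traj(550.0, 550.0)
        tun = build_tunnel(t, "weekday", br=40.0)
        fine = refine_cube(cube_24h, 10)
        hits = intersect(tun, to_point_cloud(fine))
        assert len(hits) == 144
        assert (hits["x"] == 550.0).all()
        assert (hits["y"] == 550.0).all()

    def test_empty_tunnel_empty_intersection(self, cfg, cube_24h):
        t = stationary_traj(550.0, 550.0)
        with pytest.warns(UserWarning, match="no valid saturday"):
            tun = build_tunnel(t, "saturday", br=100.0)
        assert len(intersect(tun, to_point_cloud(cube_24h))) == 0

    def test_unimputed_gap_is_a_temporal_hole(self):
        # fixes 00:00-09:59 and 11:30-23:59 with a 90-min dropout between
        minutes = np.concatenate([np.arange(600), np.arange(690, 1440)])
        pos = np.zeros((len(minutes), 2))
        pos[600:, 0] = 800.0
        raw = pd.DataFrame({
            "timestamp": pd.Timestamp("2009-08-03")
            + pd.to_timedelta(minutes, unit="min"),
            "x": pos[:, 0], "y": pos[:, 1],
        })
        t = flag_valid_days(impute_gaps(Trajectory.from_raw("P", raw)))
        tun = build_tunnel(t, "weekday", br=100.0)
        date = list(tun.day_positions)[0]
        for m in range(601, 690):
            assert tun.position_at(date, float(m)) is None
        assert tun.position_at(date, 599.0) is not None
        assert tun.position_at(date, 690.0) is not None
        assert tun.observed_minutes() == 1350

    def test_br_monotonicity(self, cfg, cube_24h):
        rng = np.random.default_rng(30)
        pos = np.cumsum(rng.normal(0, 20, size=(1440, 2)), axis=0) + 1000.0
        t = make_day_trajectory("P", "2009-08-03", pos)
        cloud = to_point_cloud(cube_24h)
        sets = []
        for br in (50.0, 100.0, 200.0):
            hits = intersect(build_tunnel(t, "weekday", br), cloud)
            sets.append(set(zip(hits["x"], hits["y"], hits["t"])))
        assert sets[0] <= sets[1] <= sets[2]

    def test_zero_cube_zero_ecei(self, cfg):
        closed = build_cube(registry_at([(500, 500)], hours=None), "weekday",
                            "ISDD", 100.0, 100.0, cfg)
        t = stationary_traj(550.0, 550.0)
        rec = participant_ecei(t, {"weekday": closed}, br=100.0)
        assert rec["ecei_raw"] == 0.0


class TestIntersectionOracle:
    def test_matches_brute_force_all_pairs(self, cfg, cube_24h):
        """Set equality with an exhaustive cloud-point x day distance check."""
        rng = np.random.default_rng(31)
        trajs = []
        for date in ("2009-08-03", "2009-08-04"):
            pos = np.cumsum(rng.normal(0, 15, size=(1440, 2)), axis=0) + 900.0
            ts = pd.Timestamp(date) + pd.to_timedelta(np.arange(1440), unit="min")
            trajs.append(pd.DataFrame({"timestamp": ts, "x": pos[:, 0],
                                       "y": pos[:, 1]}))
        raw = pd.concat(trajs, ignore_index=True)
        t = flag_valid_days(Trajectory.from_raw("P", raw))
        br = 150.0
        tun = build_tunnel(t, "weekday", br)
        cloud = to_point_cloud(cube_24h)  # 20x20x48 = 19200 points
        hits = intersect(tun, cloud)

        # brute force: every cloud point against every day's position
        expected = set()
        for date, pos_arr in tun.day_positions.items():
            for _, row in cloud.points.iterrows():
                m = int(row["t"])  # slot midpoints are whole minutes
                px, py = pos_arr[m, 0], pos_arr[m, 1]
                if np.isfinite(px) and np.hypot(row["x"] - px,
                                                row["y"] - py) <= br:
                    expected.add((row["x"], row["y"], row["t"], date))
        got = set(zip(hits["x"], hits["y"], hits["t"], hits["date"]))
        assert got == expected

    def test_vectorized_ecei_equals_pointwise_route(self, cfg, cube_24h):
        """The fast layer-sum path agrees with intersect() + ecei()."""
        rng = np.random.default_rng(32)
        pos = np.cumsum(rng.normal(0, 10, size=(1440, 2)), axis=0) + 1000.0
        t = make_day_trajectory("P", "2009-08-03", pos)
        tun = build_tunnel(t, "weekday", br=120.0)
        hits = intersect(tun, to_point_cloud(cube_24h), weight_mode="velocity")
        slow = ecei(hits, T=tun.observed_minutes() / 60.0)
        rec = participant_ecei(t, {"weekday": cube_24h}, br=120.0,
                               weight_mode="velocity")
        assert rec["ecei_raw"] == pytest.approx(slow, rel=1e-12)
        assert rec["n_points"] == len(hits)


class TestDayTypeAggregation:
    def test_valid_day_weighted_mean_invariant_to_duplicate_days(self, cfg,
                                                                 cube_24h):
        """Repeating identical days changes day counts but not the index."""
        pos = np.tile([550.0, 550.0], (1440, 1))
        frames = []
        for date in ("2009-08-03", "2009-08-04", "2009-08-05"):
            ts = pd.Timestamp(date) + pd.to_timedelta(np.arange(1440), unit="min")
            frames.append(pd.DataFrame({"timestamp": ts, "x": pos[:, 0],
                                        "y": pos[:, 1]}))
        one = flag_valid_days(Trajectory.from_raw(
            "P", frames[0]))
        three = flag_valid_days(Trajectory.from_raw(
            "P", pd.concat(frames, ignore_index=True)))
        r1 = participant_ecei(one, {"weekday": cube_24h}, br=100.0)
        r3 = participant_ecei(three, {"weekday": cube_24h}, br=100.0)
        assert r3["ecei_raw"] == pytest.approx(r1["ecei_raw"], rel=1e-12)

    def test_span_denominator_mode(self, cfg, cube_24h):
        t = stationary_traj(550.0, 550.0)
        r_obs = participant_ecei(t, {"weekday": cube_24h}, br=100.0,
                                 t_mode="observed")
        r_span = participant_ecei(t, {"weekday": cube_24h}, br=100.0,
                                  t_mode="span")
        # full-day stationary coverage: span equals observed time
        assert r_span["ecei_raw"] == pytest.approx(r_obs["ecei_raw"], rel=1e-12)
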