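"""COP trajectories, time normalization, comparison metrics and Procrustes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from elefoot.cop import (
    COPTrajectory,
    compare_feet,
    compare_untransformed,
    cop_frame,
    cop_trajectory,
    mean_trajectory,
    procrustes_opa,
    time_normalize,
)
from elefoot.errors import DegenerateShapeError
from elefoot.pressure_io import PlateSpec
from elefoot.segment import FootstepSeries, segment_steps

SPEC = PlateSpec()


def _traj(points, foot="FL") -> COPTrajectory:
    pts = np.asarray(points, float)
    return COPTrajectory(
        points=pts, times=np.linspace(0, 1, len(pts)), foot_label=foot
    )


class TestCopFrame:
    def test_single_cell_centre(self):
        frame = np.zeros(SPEC.shape)
        frame[20, 10] = 123.0
        x, y = cop_frame(frame, 5.0, SPEC)
        assert x == pytest.approx((10 + 0.5) * SPEC.pitch_x_m)
        assert y == pytest.approx((20 + 0.5) * SPEC.pitch_y_m)

    def test_two_equal_cells_midpoint(self):
        frame = np.zeros(SPEC.shape)
        c1 = int(round(0.1 / SPEC.pitch_x_m - 0.5))
        c2 = int(round(0.3 / SPEC.pitch_x_m - 0.5))
        frame[50, c1] = 40.0
        frame[50, c2] = 40.0
        x, y = cop_frame(frame, 5.0, SPEC)
        assert x == pytest.approx(((c1 + c2) / 2 + 0.5) * SPEC.pitch_x_m)

    def test_inactive_frame_is_none(self):
        assert cop_frame(np.zeros(SPEC.shape), 5.0, SPEC) is None

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_centroid(self, seed):
        rng = np.random.default_rng(seed)
        frame = np.zeros(SPEC.shape)
        n = rng.integers(1, 40)
        rows = rng.integers(0, SPEC.n_rows, n)
        cols = rng.integers(0, SPEC.n_cols, n)
        frame[rows, cols] = rng.uniform(6, 300, n)
        x, y = cop_frame(frame, 5.0, SPEC)
        num_x = num_y = den = 0.0
        for r in range(SPEC.n_rows):
            for cc in range(SPEC.n_cols):
                p = frame[r, cc]
                if p >= 5.0:
                    num_x += p * (cc + 0.5) * SPEC.pitch_x_m
                    num_y += p * (r + 0.5) * SPEC.pitch_y_m
                    den += p
        assert x == pytest.approx(num_x / den)
        assert y == pytest.approx(num_y / den)


class TestCopTrajectory:
    def test_recovers_generator_truth_within_half_pitch(self, quiet_trial, quiet_steps):
        """Measured COP matches the dense-integration truth on shared frames.

        The first/last stance frames carry <1% of peak load, where the 5 kPa
        cut acts on a handful of cells; those two boundary frames get a
        relaxed two-pitch bound, all interior frames the half-pitch one.
        """
        _, truth = quiet_trial
        half_pitch = max(SPEC.pitch_x_m, SPEC.pitch_y_m) / 2
        for step in quiet_steps:
            traj = cop_trajectory(step, 5.0)
            st = min(
                truth.steps, key=lambda s: abs(int(s.cop_frames.min()) - step.onset_frame)
            )
            truth_xy = {int(f): xy for f, xy in zip(st.cop_frames, st.cop_xy_m)}
            shared = [i for i, f in enumerate(traj.frames) if int(f) in truth_xy]
            assert len(shared) >= len(traj) - 2
            err = np.array(
                [
                    np.hypot(*(traj.points[i] - truth_xy[int(traj.frames[i])]))
                    for i in shared
                ]
            )
            assert err[1:-1].max() < half_pitch
            assert err.max() < 4 * half_pitch

    def test_reversed_time_reverses_trajectory(self, quiet_steps):
        step = quiet_steps[0]
        t_max = step.voxels[:, 0].max()
        rev = FootstepSeries(
            spec=step.spec,
            voxels=np.column_stack(
                (t_max - step.voxels[:, 0], step.voxels[:, 1], step.voxels[:, 2])
            ),
            pressures=step.pressures,
            n_record_frames=step.n_record_frames,
        )
        fwd = cop_trajectory(step, 5.0)
        bwd = cop_trajectory(rev, 5.0)
        assert np.allclose(bwd.points, fwd.points[::-1])

    def test_too_few_active_frames_rejected(self):
        step = FootstepSeries(
            spec=SPEC, voxels=[(0, 5, 5)], pressures=[50.0], n_record_frames=2
        )
        with pytest.raises(ValueError):
            cop_trajectory(step, 5.0)


class TestTimeNormalize:
    def test_already_uniform_unchanged(self):
        traj = _traj(np.random.default_rng(0).uniform(0, 1, (11, 2)))
        out = time_normalize(traj, 11)
        assert np.allclose(out.points, traj.points)

    def test_two_point_midpoint(self):
        traj = _traj([[0.0, 0.0], [1.0, 2.0]])
        out = time_normalize(traj, 3)
        assert np.allclose(out.points[1], [0.5, 1.0])
        assert np.allclose(out.points[[0, 2]], traj.points)  # endpoints exact

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(1)
        times = np.sort(np.concatenate(([0.0, 1.0], rng.uniform(0, 1, 6))))
        pts = rng.uniform(0, 2, (8, 2))
        traj = COPTrajectory(points=pts, times=times)
        out = time_normalize(traj, 21)
        for k, f in enumerate(np.linspace(0, 1, 21)):
            assert out.points[k, 0] == pytest.approx(np.interp(f, times, pts[:, 0]))
            assert out.points[k, 1] == pytest.approx(np.interp(f, times, pts[:, 1]))


class TestMeanTrajectory:
    def test_identical_inputs(self):
        traj = _traj(np.random.default_rng(2).uniform(0, 1, (11, 2)))
        assert np.allclose(mean_trajectory([traj, traj]).points, traj.points)

    def test_mirror_pair_averages_to_axis(self):
        pts = np.random.default_rng(3).uniform(-1, 1, (11, 2))
        mirrored = pts * np.array([-1.0, 1.0])  # mirror about x=0
        out = mean_trajectory([_traj(pts), _traj(mirrored)])
        assert np.allclose(out.points[:, 0], 0.0)
        assert np.allclose(out.points[:, 1], pts[:, 1])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            mean_trajectory([_traj(np.zeros((5, 2)) + [[i, 0] for i in range(5)]),
                             _traj([[0, 0], [1, 1], [2, 2]])])


class TestCompareUntransformed:
    def test_self_comparison(self):
        traj = _traj(np.random.default_rng(4).uniform(0, 1, (11, 2)))
        x_r, y_r, rmse = compare_untransformed(traj, traj)
        assert (x_r, y_r) == (pytest.approx(1.0), pytest.approx(1.0))
        assert rmse == pytest.approx(0.0)

    def test_negated_x_flips_x_correlation(self):
        pts = np.random.default_rng(5).uniform(-1, 1, (11, 2))
        a = _traj(pts)
        b = _traj(pts * np.array([-1.0, 1.0]))
        x_r, y_r, _ = compare_untransformed(a, b)
        assert x_r == pytest.approx(-1.0)
        assert y_r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        pa = rng.uniform(0, 1, (15, 2))
        pb = rng.uniform(0, 1, (15, 2))
        a, b = _traj(pa), _traj(pb)
        x_r, y_r, rmse = compare_untransformed(a, b)
        ca, cb = pa - pa.mean(axis=0), pb - pb.mean(axis=0)

        def pearson(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return float((u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum()))

        assert x_r == pytest.approx(pearson(ca[:, 0], cb[:, 0]))
        assert y_r == pytest.approx(pearson(ca[:, 1], cb[:, 1]))
        assert rmse == pytest.approx(float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, 1)))))


def opa_grid_oracle(a: np.ndarray, b: np.ndarray, scale: bool, reflect: bool) -> float:
    """Dense grid over rotation x reflection; per-rotation least-squares scale.

    For a fixed rotation the squared error is quadratic in the scale, so its
    minimizer is dot(a, b_rot)/||b_rot||^2 by elementary calculus — no SVD
    involved, keeping the oracle independent of the implementation route.
    """
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    best = np.inf
    mirrors = [np.eye(2)] + ([np.diag([-1.0, 1.0])] if reflect else [])
    for mirror in mirrors:
        for theta in np.linspace(0, 2 * np.pi, 3600, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            bb = b0 @ mirror @ rot
            beta = float((a0 * bb).sum() / (bb * bb).sum()) if scale else 1.0
            d = a0 - beta * bb
            best = min(best, float((d * d).sum()))
    return float(np.sqrt(best / len(a)))


class TestProcrustes:
    def test_self_superimposition_zero(self):
        pts = np.random.default_rng(7).uniform(0, 1, (10, 2))
        _, rmsd = procrustes_opa(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_similarity_transformed_copy_zero(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (12, 2))
        theta = 0.73
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        b = 2.4 * (a @ np.diag([-1.0, 1.0]) @ rot) + np.array([3.0, -1.0])
        _, rmsd = procrustes_opa(a, b, scale=True, reflect=True)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("scale,reflect", [(True, True), (True, False), (False, False)])
    def test_matches_grid_search_oracle(self, seed, scale, reflect):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        a = rng.uniform(0, 1, (n, 2))
        b = rng.uniform(0, 1, (n, 2))
        _, rmsd = procrustes_opa(a, b, scale=scale, reflect=reflect)
        oracle = opa_grid_oracle(a, b, scale=scale, reflect=reflect)
        assert rmsd == pytest.approx(oracle, abs=1e-4)

    @given(st.integers(0, 10_000))
    def test_invariant_under_rigid_motion_of_source(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (9, 2))
        b = rng.uniform(0, 1, (9, 2))
        _, rmsd = procrustes_opa(a, b)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = rng.uniform(0.2, 5.0) * b @ rot + rng.uniform(-3, 3, 2)
        _, rmsd2 = procrustes_opa(a, moved)
        assert rmsd2 == pytest.approx(rmsd, abs=1e-9)

    def test_feasible_set_ordering(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.uniform(0, 1, (8, 2))
            b = rng.uniform(0, 1, (8, 2))
            _, r_both = procrustes_opa(a, b, scale=True, reflect=True)
            _, r_scale = procrustes_opa(a, b, scale=True, reflect=False)
            _, r_none = procrustes_opa(a, b, scale=False, reflect=False)
            assert r_both <= r_scale + 1e-12
            assert r_scale <= r_none + 1e-12

    def test_degenerate_configuration_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(DegenerateShapeError):
            procrustes_opa(pts, np.random.default_rng(0).uniform(0, 1, (5, 2)))


class TestCompareFeet:
    def test_identical_pair_row(self):
        traj = _traj(np.random.default_rng(10).uniform(0, 1, (11, 2)), foot="FL")
        table = compare_feet({"FL": traj, "FR": traj}, ["FL-FR"])
        row = table.iloc[0]
        assert row["x_r"] == pytest.approx(1.0)
        assert row["y_r"] == pytest.approx(1.0)
        assert row["rmse"] == pytest.approx(0.0)
        assert row["rmsd"] == pytest.approx(0.0)

    def test_mirror_pair_needs_reflection(self):
        pts = np.random.default_rng(11).uniform(0, 1, (11, 2))
        left = _traj(pts, foot="FL")
        right = _traj(pts * np.array([-1.0, 1.0]), foot="FR")
        with_reflect = compare_feet({"FL": left, "FR": right}, ["FL-FR"], reflect=True)
        without = compare_feet({"FL": left, "FR": right}, ["FL-FR"], reflect=False)
        assert with_reflect.iloc[0]["rmsd"] == pytest.approx(0.0, abs=1e-9)
        assert without.iloc[0]["rmsd"] > 1e-3

    def test_missing_label_raises(self):
        traj = _traj(np.random.default_rng(12).uniform(0, 1, (11, 2)))
        with pytest.raises(KeyError):
            compare_feet({"FL": traj}, ["FL-HR"])

    def test_rmsd_grows_with_noise(self):
        """Distorting one trajectory with growing noise grows the RMSD."""
        rng = np.random.default_rng(13)
        base = np.column_stack((np.sin(np.linspace(0, 2, 21)), np.linspace(0, 1, 21)))
        rmsds = []
        for sd in (0.0, 0.05, 0.2):
            vals = []
            for rep in range(5):
                noisy = base + rng.normal(0, sd, base.shape)
                _, rmsd = procrustes_opa(base, noisy)
                vals.append(rmsd)
            rmsds.append(np.mean(vals))
        assert rmsds[0] < rmsds[1] < rmsds[2]
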