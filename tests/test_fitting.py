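"""Pose normalization, least-squares objective, and parameter recovery."""

import numpy as np
import pytest

import gielisleaf as gl
from gielisleaf.fitting import _residual_rss


def make_noisy_curve(l, n, pose, noise_sd, seed, num_points=1000):
    return gl.make_leaf(
        gl.GielisParams(l, n), pose, noise_sd=noise_sd,
        num_points=num_points, seed=seed,
    )


class TestPose:
    def test_identity_pose_is_noop(self, noiseless_curve):
        out = gl.normalize_pose(noiseless_curve, gl.PoseParams())
        assert np.array_equal(out.points, noiseless_curve.points)

    def test_apply_then_normalize_round_trip(self, noiseless_curve, pose):
        back = gl.normalize_pose(gl.apply_pose(noiseless_curve, pose), pose)
        assert np.allclose(back.points, noiseless_curve.points, atol=1e-12)

    def test_normalization_puts_tip_on_positive_x(self, lanceolate):
        posed = gl.boundary(lanceolate, 512, pose=gl.PoseParams(0, 0, 0.7))
        norm = gl.normalize_pose(posed, gl.PoseParams(0, 0, 0.7))
        tip = norm.points[np.argmax(np.hypot(norm.x, norm.y))]
        assert tip[0] == pytest.approx(lanceolate.l, rel=1e-12)
        assert abs(tip[1]) < 1e-10

    def test_theta_wrapping(self):
        assert gl.PoseParams(0, 0, 3 * np.pi).theta_wrapped == pytest.approx(np.pi)
        assert gl.PoseParams(0, 0, -np.pi).theta_wrapped == pytest.approx(np.pi)
        assert gl.PoseParams(0, 0, 0.3).theta_wrapped == pytest.approx(0.3)


class TestToPolar:
    @pytest.mark.parametrize(
        "pt, expected",
        [((1.0, 0.0), (0.0, 1.0)), ((0.0, -2.0), (-np.pi / 2, 2.0))],
    )
    def test_known_points(self, pt, expected):
        curve = gl.BoundaryCurve(np.array([pt, (5.0, 0.1), (0.1, 5.0)]))
        phi, r = gl.to_polar(curve)
        assert (phi[0], r[0]) == pytest.approx(expected, rel=1e-15)

    def test_round_trip(self, noiseless_curve):
        phi, r = gl.to_polar(noiseless_curve)
        back = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        assert np.allclose(back, noiseless_curve.points, atol=1e-12)

    def test_origin_point_rejected(self):
        curve = gl.BoundaryCurve(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="polar origin"):
            gl.to_polar(curve)


class TestRSquared:
    def test_perfect_prediction(self):
        r = np.array([1.0, 2.0, 3.0])
        assert gl.r_squared(r, r) == 1.0

    def test_mean_prediction_scores_zero(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        assert gl.r_squared(r, np.full(4, r.mean())) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_four_points(self):
        r_obs = np.array([1.0, 2.0, 4.0, 5.0])
        r_pred = np.array([1.5, 2.5, 3.5, 4.5])
        # RSS = 0.25*4 + (4-3.5)^2... worked by hand: (0.5^2)*4 = 1.0
        # TSS about mean 3: 4 + 1 + 1 + 4 = 10
        assert gl.r_squared(r_obs, r_pred) == pytest.approx(1 - 1.0 / 10.0, abs=1e-15)

    def test_constant_observations_undefined(self):
        with pytest.raises(ZeroDivisionError):
            gl.r_squared(np.ones(5), np.ones(5))


class TestObjective:
    def test_zero_at_truth(self, lanceolate):
        p = gl.GielisParams(1.0, 0.06)
        curve = gl.boundary(p, 500, pose=gl.PoseParams(0.3, -0.2, 0.9))
        assert gl.objective(curve, 1.0, 0.06, 0.3, -0.2, 0.9) < 1e-18

    def test_strictly_positive_off_truth(self, noiseless_curve, lanceolate, pose):
        at_truth = gl.objective(
            noiseless_curve, lanceolate.l, lanceolate.n, pose.x0, pose.y0, pose.theta
        )
        perturbed = gl.objective(
            noiseless_curve,
            lanceolate.l * 1.01,
            lanceolate.n,
            pose.x0,
            pose.y0,
            pose.theta,
        )
        assert perturbed > at_truth

    def test_matches_explicit_loop(self, pose):
        curve = make_noisy_curve(8.0, 0.05, pose, noise_sd=0.01, seed=5, num_points=64)
        vec = gl.objective(curve, 7.5, 0.055, pose.x0, pose.y0, pose.theta)
        norm = gl.normalize_pose(curve, pose)
        total = 0.0
        for x, y in norm.points:
            phi, r_obs = np.arctan2(y, x), np.hypot(x, y)
            total += (r_obs - gl.radius(phi, gl.GielisParams(7.5, 0.055))) ** 2
        assert vec == total

    def test_invalid_parameters_rejected(self, noiseless_curve):
        with pytest.raises(ValueError):
            gl.objective(noiseless_curve, -1.0, 0.05, 0, 0, 0)


class TestInitialize:
    def test_theta_near_truth_on_synthetic_leaf(self):
        curve = gl.boundary(
            gl.GielisParams(10, 0.05), 1000, pose=gl.PoseParams(3, -2, 0.4)
        )
        l0, n0, x0, y0, th0 = gl.initialize(curve)
        assert abs(th0 - 0.4) < 0.3
        assert n0 == 0.06

    def test_symmetric_leaf_centroid_on_axis(self, lanceolate):
        curve = gl.boundary(lanceolate, 1000)
        _, _, _, y0, _ = gl.initialize(curve)
        assert abs(y0) < 1e-10

    def test_exact_ties_break_to_lowest_index(self):
        # four corners at exactly equal distance from an exactly-zero
        # centroid; the first corner in point order must win
        inner = [
            (0.5, 0.0), (0.0, 0.5), (-0.5, 0.0), (0.0, -0.5),
            (0.25, 0.25), (-0.25, 0.25), (-0.25, -0.25), (0.25, -0.25),
            (0.75, 0.0), (0.0, 0.75), (-0.75, 0.0), (0.0, -0.75),
        ]
        corners = [(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)]
        pts = np.array(
            inner[:2] + corners[:1] + inner[2:6] + corners[1:] + inner[6:]
        )
        _, _, _, _, th0 = gl.initialize(gl.BoundaryCurve(pts))
        # lowest-index corner is (-1, -1)
        assert th0 == np.arctan2(-1.0, -1.0)

    def test_partial_arc_rejected(self):
        t = np.linspace(0, np.pi / 2, 20)
        arc = gl.BoundaryCurve(np.column_stack([np.cos(t), np.sin(t)]))
        with pytest.raises(ValueError, match="spans less than"):
            gl.fit(arc)


class TestFit:
    def test_noiseless_recovery_all_five_parameters(self, noiseless_curve, pose):
        res = gl.fit(noiseless_curve)
        assert res.converged
        assert res.params.l == pytest.approx(10.0, rel=1e-3)
        assert res.params.n == pytest.approx(0.06, rel=1e-3)
        assert res.pose.x0 == pytest.approx(pose.x0, rel=1e-3)
        assert res.pose.y0 == pytest.approx(pose.y0, rel=1e-3)
        assert res.pose.theta == pytest.approx(pose.theta, rel=1e-3)
        assert res.r_squared >= 1 - 1e-8

    def test_rigid_motion_leaves_shape_estimates_unchanged(self, noiseless_curve):
        res0 = gl.fit(noiseless_curve)
        moved = gl.apply_pose(noiseless_curve, gl.PoseParams(-7.0, 4.0, 1.1))
        res1 = gl.fit(moved)
        assert res1.params.l == pytest.approx(res0.params.l, rel=1e-6)
        assert res1.params.n == pytest.approx(res0.params.n, rel=1e-6)

    def test_noise_robustness_small_batch(self, pose):
        errs, r2s = [], []
        for seed in range(10):
            curve = make_noisy_curve(10.0, 0.06, pose, noise_sd=0.01, seed=seed)
            res = gl.fit(curve)
            errs.append(abs(res.params.n - 0.06) / 0.06)
            r2s.append(res.r_squared)
        assert np.median(errs) <= 0.05
        assert min(r2s) >= 0.99

    def test_r2_monotone_degradation_with_noise(self, pose):
        r2 = []
        for sd in (0.0, 0.005, 0.01, 0.02):
            curve = make_noisy_curve(10.0, 0.06, pose, noise_sd=sd, seed=123)
            r2.append(gl.fit(curve).r_squared)
        assert all(a >= b for a, b in zip(r2, r2[1:]))

    def test_one_sided_bulge_lowers_r2(self, pose):
        control = gl.make_leaf(
            gl.GielisParams(10, 0.06), pose, noise_sd=0.005, num_points=800, seed=9
        )
        bumped = gl.make_leaf(
            gl.GielisParams(10, 0.06),
            pose,
            noise_sd=0.005,
            asymmetry=0.05,
            num_points=800,
            seed=9,
        )
        assert gl.fit(bumped).r_squared < gl.fit(control).r_squared

    def test_result_serialization(self, noiseless_curve):
        import json

        d = json.loads(gl.fit(noiseless_curve).to_json())
        assert {
            "l", "n", "x0", "y0", "theta", "r_squared", "rss",
            "length", "width", "aspect_ratio", "area", "converged",
        } <= set(d)


def test_boundary_csv_round_trip(tmp_path, noiseless_curve):
    path = tmp_path / "leaf.csv"
    gl.write_boundary_csv(noiseless_curve, path)
    back = gl.read_boundary_csv(path)
    assert np.allclose(back.points, noiseless_curve.points, atol=1e-12)


def test_boundary_csv_requires_header(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b\n1,2\n3,4\n5,6\n")
    with pytest.raises(ValueError, match="lacks columns"):
        gl.read_boundary_csv(path)
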