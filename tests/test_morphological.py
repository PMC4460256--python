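import numpy as np
import pytest

from acuhead.catalog import load_catalog
from acuhead.landmarks import LandmarkSet
from acuhead.morphological import (
    CurveError,
    CurvePath,
    candidate_curve,
    compute_all_morphological,
    distance_functional,
    minimize_on_curve,
    solve_on_curve,
    solve_morph_rule,
)


@pytest.fixture(scope="module")
def catalog():
    return load_catalog()


def standard_curve(rule, side, points_per_segment=40):
    """Synthetic polyline through the printed standard positions, control to
    control, with the printed coordinates kept as exact vertices."""
    waypoints = (
        [rule.standard_point(rule.control_a, side)]
        + [rule.standard_point(t, side) for t in rule.targets]
        + [rule.standard_point(rule.control_b, side)]
    )
    return CurvePath.from_waypoints(waypoints, points_per_segment)


def brute_force_argmin(curve, p_prime, q_prime, p, q, r):
    """Independent per-vertex loop (no vectorization, no shared helper)."""
    import math

    best_idx, best_val = None, None
    sp = math.dist(tuple(r), tuple(p))
    sq = math.dist(tuple(r), tuple(q))
    for idx, x in enumerate(curve.points):
        val = (math.dist(tuple(x), tuple(p_prime)) - sp) ** 2 + (
            math.dist(tuple(x), tuple(q_prime)) - sq
        ) ** 2
        if best_val is None or val < best_val:
            best_idx, best_val = idx, val
    return best_idx, best_val


class TestCurvePath:
    def test_arc_length_strictly_increasing(self, catalog):
        curve = standard_curve(catalog.morph_rules[0], "left")
        assert (np.diff(curve.arc_length) > 0).all()

    def test_needs_two_vertices(self):
        with pytest.raises(CurveError):
            CurvePath(np.zeros((1, 3)))

    def test_waypoints_preserved(self, catalog):
        rule = catalog.morph_rules[0]
        curve = standard_curve(rule, "left", points_per_segment=7)
        vertex_set = {tuple(p) for p in curve.points}
        for name in rule.targets:
            assert tuple(rule.standard_point(name, "left")) in vertex_set


class TestCandidateCurve:
    def test_sphere_section(self, sphere_pipeline, run_config):
        mesh = sphere_pipeline["mesh_model"]
        lms = sphere_pipeline["landmarks_model"]
        p = lms.point("TE17", "left")
        q = lms.point("TE20", "left")
        center = mesh.vertices.mean(axis=0)
        curve = candidate_curve(mesh, p, q, center, run_config.alpha)
        normal = np.cross(p - center, q - center)
        normal /= np.linalg.norm(normal)
        dists = np.abs((curve.points - center) @ normal)
        # all but the force-included endpoint vertices lie in the widened band
        assert np.median(dists) <= run_config.alpha
        assert np.percentile(dists, 95) <= 16 * run_config.alpha

    def test_endpoints_are_nearest_vertices(self, sphere_pipeline, run_config):
        mesh = sphere_pipeline["mesh_model"]
        lms = sphere_pipeline["landmarks_model"]
        p = lms.point("GB9", "right")
        q = lms.point("GB12", "right")
        curve = candidate_curve(
            mesh, p, q, mesh.vertices.mean(axis=0), run_config.alpha
        )
        for control, endpoint in ((p, curve.points[0]), (q, curve.points[-1])):
            nearest = mesh.vertices[
                np.argmin(np.linalg.norm(mesh.vertices - control, axis=1))
            ]
            assert np.allclose(endpoint, nearest)

    def test_arc_length_at_least_chord(self, sphere_pipeline, run_config):
        mesh = sphere_pipeline["mesh_model"]
        lms = sphere_pipeline["landmarks_model"]
        p = lms.point("ST8", "left") if ("ST8", "left") in lms else lms.point("GB7", "left")
        q = lms.point("GB9", "left")
        curve = candidate_curve(
            mesh, p, q, mesh.vertices.mean(axis=0), run_config.alpha
        )
        assert curve.arc_length[-1] >= np.linalg.norm(
            curve.points[-1] - curve.points[0]
        ) - 1e-12

    def test_coincident_controls_error(self, sphere_pipeline, run_config):
        mesh = sphere_pipeline["mesh_model"]
        p = mesh.vertices[0]
        with pytest.raises(CurveError, match="coincide"):
            candidate_curve(mesh, p, p, mesh.vertices.mean(axis=0), run_config.alpha)

    def test_degenerate_plane_error(self, sphere_pipeline, run_config):
        mesh = sphere_pipeline["mesh_model"]
        center = mesh.vertices.mean(axis=0)
        p = center + np.array([0.1, 0.0, 0.0])
        q = center + np.array([0.2, 0.0, 0.0])
        with pytest.raises(CurveError, match="degenerate"):
            candidate_curve(mesh, p, q, center, run_config.alpha)


class TestDistanceFunctional:
    def test_zero_at_exact_correspondence(self, catalog):
        rule = catalog.morph_rules[0]
        p = rule.standard_point("ST8", "left")
        q = rule.standard_point("GB7", "left")
        r = rule.standard_point("GB4", "left")
        assert distance_functional(r, p, q, p, q, r) == 0.0

    def test_positive_off_solution(self, catalog):
        rule = catalog.morph_rules[0]
        p = rule.standard_point("ST8", "left")
        q = rule.standard_point("GB7", "left")
        r = rule.standard_point("GB4", "left")
        assert distance_functional(r + [0.05, 0, 0], p, q, p, q, r) > 0

    def test_hand_computed_printed_values(self):
        # left-side printed coordinates, substituted by hand
        st8 = np.array([-0.447, 0.278, -1.026])
        gb7 = np.array([-0.641, 0.155, -0.474])
        gb4 = np.array([-0.539, 0.274, -0.912])
        assert distance_functional(gb4, st8, gb7, st8, gb7, gb4) == 0.0

    def test_rigid_invariance(self, catalog, rng):
        rule = catalog.morph_rules[1]
        p = rule.standard_point("GB9", "left")
        q = rule.standard_point("GB12", "left")
        r = rule.standard_point("GB10", "left")
        x = r + rng.normal(scale=0.05, size=3)
        # random rotation + translation
        a = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(a)
        shift = rng.normal(size=3)
        before = distance_functional(x, p, q, p, q, r)
        after = distance_functional(
            rot @ x + shift, rot @ p + shift, rot @ q + shift, p, q, r
        )
        assert after == pytest.approx(before, abs=1e-12)


class TestSolveOnCurve:
    @pytest.mark.parametrize("rule_index", [0, 1, 2])
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_identity_recovery_exact(self, catalog, rule_index, side):
        rule = catalog.morph_rules[rule_index]
        curve = standard_curve(rule, side)
        sols = solve_on_curve(
            rule, curve,
            rule.standard_point(rule.control_a, side),
            rule.standard_point(rule.control_b, side),
            side,
        )
        for sol in sols:
            expected = rule.standard_point(sol.target, side)
            assert np.array_equal(sol.array, expected), sol.target
            assert sol.L_value < 1e-30

    def test_matches_brute_force_oracle(self, catalog, rng):
        rule = catalog.morph_rules[0]
        curve = standard_curve(rule, "left")
        # perturbed target controls: production must equal brute force
        p_prime = rule.standard_point("ST8", "left") + rng.normal(scale=0.03, size=3)
        q_prime = rule.standard_point("GB7", "left") + rng.normal(scale=0.03, size=3)
        p = rule.standard_point("ST8", "left")
        q = rule.standard_point("GB7", "left")
        for target in rule.targets:
            r = rule.standard_point(target, "left")
            got_idx, got_val = minimize_on_curve(curve, p_prime, q_prime, p, q, r)
            exp_idx, exp_val = brute_force_argmin(curve, p_prime, q_prime, p, q, r)
            assert got_idx == exp_idx
            assert got_val == pytest.approx(exp_val)

    def test_scaled_copy_stays_between_controls(self, catalog):
        # no scale normalization is applied, so a scaled copy only recovers
        # points approximately; they must stay on the curve between controls
        rule = catalog.morph_rules[0]
        base = standard_curve(rule, "left")
        curve = CurvePath(1.5 * base.points)
        sols = solve_on_curve(
            rule, curve, curve.points[0], curve.points[-1], "left"
        )
        span = curve.arc_length[-1]
        for sol in sols:
            exact = 1.5 * rule.standard_point(sol.target, "left")
            assert 0 < sol.curve_index < len(curve) - 1
            assert np.linalg.norm(sol.array - exact) < 0.15 * span

    def test_monotone_residual(self, catalog, rng):
        rule = catalog.morph_rules[2]
        curve = standard_curve(rule, "right")
        p_prime = rule.standard_point("TE17", "right") + rng.normal(scale=0.02, size=3)
        q_prime = rule.standard_point("TE20", "right") + rng.normal(scale=0.02, size=3)
        sols = solve_on_curve(rule, curve, p_prime, q_prime, "right")
        for sol in sols:
            r = rule.standard_point(sol.target, "right")
            p = rule.standard_point("TE17", "right")
            q = rule.standard_point("TE20", "right")
            for endpoint in (curve.points[0], curve.points[-1]):
                assert sol.L_value <= distance_functional(
                    endpoint, p_prime, q_prime, p, q, r
                ) + 1e-15

    def test_arc_order_matches_standard_order(self, catalog):
        rule = catalog.morph_rules[0]
        curve = standard_curve(rule, "left")
        sols = solve_on_curve(
            rule, curve,
            rule.standard_point("ST8", "left"),
            rule.standard_point("GB7", "left"),
            "left",
        )
        indices = [s.curve_index for s in sols]  # GB4, GB5, GB6
        assert indices == sorted(indices)


@pytest.fixture(scope="module")
def morph_points(sphere_pipeline, sphere_proportional, catalog):
    combined = LandmarkSet(
        list(sphere_pipeline["landmarks_model"])
        + [lm for lm in sphere_proportional if lm.name != "AUX"]
    )
    curves = {}
    pts = compute_all_morphological(
        sphere_pipeline["mesh_model"], combined, catalog,
        collect_curves=curves,
    )
    return pts, curves, combined


class TestOnPhantom:
    def test_seven_names_both_sides(self, morph_points):
        pts, _, _ = morph_points
        names = {lm.name for lm in pts}
        assert names == {"GB4", "GB5", "GB6", "GB10", "GB11", "TE18", "TE19"}
        assert len(pts) == 14

    def test_points_lie_on_their_curves(self, morph_points, catalog):
        pts, curves, _ = morph_points
        for lm in pts:
            rule = catalog.morph_rule_for(lm.name)
            curve = curves[(rule.control_a, rule.control_b, lm.side)]
            assert any(np.allclose(lm.array, p) for p in curve.points), lm.name

    def test_missing_control_error(self, sphere_pipeline, morph_points, catalog):
        _, _, combined = morph_points
        incomplete = LandmarkSet(lm for lm in combined if lm.name != "GB9")
        with pytest.raises(CurveError, match="GB9"):
            compute_all_morphological(
                sphere_pipeline["mesh_model"], incomplete, catalog
            )

    def test_rigid_invariance_of_solutions(self, sphere_pipeline, morph_points, catalog):
        pts, _, combined = morph_points
        rng = np.random.default_rng(9)
        a = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(a)
        if np.linalg.det(rot) < 0:
            rot[:, 0] = -rot[:, 0]
        shift = rng.normal(size=3) * 0.1

        def rigid(x):
            return np.asarray(x) @ rot.T + shift

        mesh_r = sphere_pipeline["mesh_model"].transformed(rigid, "model")
        moved = combined.transformed(rigid, "model")
        pts_r = compute_all_morphological(mesh_r, moved, catalog)
        for lm in pts:
            expected = rigid(lm.array)
            got = pts_r.point(lm.name, lm.side)
            # float jitter at the band boundary can admit/drop curve vertices
            # under rotation, moving flat minima by a few voxels; the
            # functional itself is exactly rigid
            # (see test_rigid_invariance_exact_on_curve)
            assert np.linalg.norm(got - expected) <= 3 * 4.0 / 512.0, lm.name

    def test_rigid_invariance_exact_on_curve(self, catalog, rng):
        rule = catalog.morph_rules[0]
        curve = standard_curve(rule, "left")
        p_prime = rule.standard_point("ST8", "left") + rng.normal(scale=0.02, size=3)
        q_prime = rule.standard_point("GB7", "left") + rng.normal(scale=0.02, size=3)
        base = solve_on_curve(rule, curve, p_prime, q_prime, "left")
        a = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(a)
        shift = rng.normal(size=3)
        curve_r = CurvePath(curve.points @ rot.T + shift)
        moved = solve_on_curve(
            rule, curve_r, rot @ p_prime + shift, rot @ q_prime + shift, "left"
        )
        for s0, s1 in zip(base, moved):
            assert s0.curve_index == s1.curve_index
            assert np.allclose(s1.array, rot @ s0.array + shift)

    def test_solve_morph_rule_single(self, sphere_pipeline, morph_points, catalog):
        _, _, combined = morph_points
        rule = catalog.morph_rule_for("GB10")
        sols = solve_morph_rule(
            rule, sphere_pipeline["mesh_model"], combined, "left"
        )
        assert [s.target for s in sols] == ["GB10", "GB11"]
        assert all(s.side == "left" for s in sols)
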