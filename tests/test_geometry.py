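"""Landmark correspondence and the three-landmark rigid transform."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from petstitch.geometry import (
    CongruenceWarning,
    DegenerateLandmarksError,
    LandmarkSet,
    StitchTransform,
    apply_transform,
    check_nondegenerate,
    match_landmarks,
    solve_transform,
)


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent least-squares superposition oracle: R, t with dst ~ R.src + t."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, dc - r @ sc


def det3_cofactor(m: np.ndarray) -> float:
    """Brute-force 3x3 determinant by cofactor expansion."""
    return (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )


def random_triangle(rng, scale=50.0) -> LandmarkSet:
    while True:
        pts = rng.uniform(-scale, scale, size=(3, 3))
        try:
            lm = LandmarkSet(pts)
        except DegenerateLandmarksError:
            continue
        if check_nondegenerate(lm) > 1e-3:
            return lm


class TestCheckNondegenerate:
    def test_collinear_is_zero_and_degenerate(self):
        lm = LandmarkSet(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        assert check_nondegenerate(lm) == pytest.approx(0.0, abs=1e-12)

    def test_unit_right_triangle_raw_determinant(self):
        # (0,0,0), (1,0,0), (0,1,0): the raw edge-matrix determinant is 1;
        # the returned value divides by the cube of the RMS side length.
        lm = LandmarkSet(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float))
        rms = np.sqrt((1.0 + 1.0 + 2.0) / 3.0)
        assert check_nondegenerate(lm) * rms**3 == pytest.approx(1.0, abs=1e-12)

    def test_matches_cofactor_expansion_oracle(self, rng):
        for _ in range(20):
            lm = random_triangle(rng)
            u = lm.a - lm.b
            v = lm.c - lm.b
            m = np.array([u, v, np.cross(u, v)])
            sides = lm.distance_matrix()[np.triu_indices(3, 1)]
            rms = np.sqrt(np.mean(sides**2))
            assert check_nondegenerate(lm) == pytest.approx(
                abs(det3_cofactor(m)) / rms**3, rel=1e-12
            )

    def test_duplicate_point_raises(self):
        with pytest.raises(DegenerateLandmarksError, match="already been chosen"):
            LandmarkSet(np.array([[0, 0, 0], [0, 0, 0], [0, 1, 0]], float))


class TestMatchLandmarks:
    def test_identity(self, rng):
        lm = random_triangle(rng)
        perm, res = match_landmarks(lm, lm)
        assert perm == (0, 1, 2)
        assert res == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("shift", list(itertools.permutations(range(3))))
    def test_any_pick_order_recovered(self, rng, shift):
        lm1 = random_triangle(rng)
        lm2 = lm1.permuted(shift)
        perm, res = match_landmarks(lm1, lm2)
        assert res == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(lm2.permuted(perm).points, lm1.points)

    def test_jittered_rigid_motion_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            lm1 = random_triangle(rng)
            r = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved = lm1.points @ r.T + t + rng.uniform(-0.5, 0.5, (3, 3))
            true_perm = tuple(rng.permutation(3))
            lm2 = LandmarkSet(moved[list(true_perm)])
            # independent exhaustive oracle over the 6 permutations
            d1 = lm1.distance_matrix()
            best, best_cost = None, np.inf
            for p in sorted(itertools.permutations(range(3))):
                cost = 0.0
                for i in range(3):
                    for j in range(i + 1, 3):
                        dij = np.linalg.norm(lm2.points[p[i]] - lm2.points[p[j]])
                        cost += (d1[i, j] - dij) ** 2
                if cost < best_cost:
                    best, best_cost = p, cost
            perm, _ = match_landmarks(lm1, lm2)
            assert perm == best
            np.testing.assert_allclose(lm2.permuted(perm).points[list(true_perm)], moved[list(true_perm)])

    def test_large_mismatch_warns_but_returns(self, rng):
        lm1 = random_triangle(rng)
        lm2 = LandmarkSet(lm1.points * 1.5)  # >5 mm pairwise mismatch
        with pytest.warns(CongruenceWarning):
            perm, res = match_landmarks(lm1, lm2)
        assert res > 5.0

    def test_collinear_rejected(self):
        line = LandmarkSet(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        tri = LandmarkSet(np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float))
        with pytest.raises(DegenerateLandmarksError):
            match_landmarks(tri, line)


class TestSolveTransform:
    def test_identity(self, rng):
        lm = random_triangle(rng)
        t = solve_transform(lm, lm)
        np.testing.assert_allclose(t.linear_part, np.eye(3), atol=1e-9)
        p = rng.uniform(-50, 50, (5, 3))
        np.testing.assert_allclose(t.apply(p), p, atol=1e-9)

    def test_pure_translation(self, rng):
        lm1 = random_triangle(rng)
        shift = np.array([7.0, -3.0, 12.0])
        lm2 = LandmarkSet(lm1.points + shift)
        t = solve_transform(lm1, lm2)
        p = rng.uniform(-50, 50, (10, 3))
        np.testing.assert_allclose(t.apply(p), p - shift, atol=1e-9)

    def test_agrees_with_kabsch_on_congruent_triples(self, rng):
        for _ in range(25):
            lm1 = random_triangle(rng)
            r = Rotation.random(rng=rng).as_matrix()
            tvec = rng.uniform(-30, 30, 3)
            lm2 = LandmarkSet(lm1.points @ r.T + tvec)
            t = solve_transform(lm1, lm2)
            # oracle maps segment-two points back onto segment one
            r_o, t_o = kabsch(lm2.points, lm1.points)
            pts = rng.uniform(-100, 100, (20, 3))
            np.testing.assert_allclose(t.apply(pts), pts @ r_o.T + t_o, atol=1e-9)
            np.testing.assert_allclose(
                t.linear_part @ t.linear_part.T, np.eye(3), atol=1e-9
            )
            assert np.linalg.det(t.linear_part) == pytest.approx(1.0, abs=1e-9)

    def test_maps_landmarks_exactly_when_congruent(self, rng):
        lm1 = random_triangle(rng)
        r = Rotation.random(rng=rng).as_matrix()
        lm2 = LandmarkSet(lm1.points @ r.T + np.array([1.0, 2.0, 3.0]))
        t = solve_transform(lm1, lm2)
        np.testing.assert_allclose(t.apply(lm2.points), lm1.points, atol=1e-9)
        np.testing.assert_allclose(t.apply(t.anchor_source), t.anchor_target, atol=1e-12)

    def test_inverse_consistency(self, rng):
        lm1 = random_triangle(rng)
        r = Rotation.random(rng=rng).as_matrix()
        lm2 = LandmarkSet(lm1.points @ r.T + np.array([5.0, 0.0, -4.0]))
        fwd = solve_transform(lm1, lm2)
        rev = solve_transform(lm2, lm1)
        pts = rng.uniform(-80, 80, (10, 3))
        np.testing.assert_allclose(rev.apply(fwd.apply(pts)), pts, atol=1e-9)

    def test_pick_order_invariance(self, rng):
        lm1 = random_triangle(rng)
        r = Rotation.random(rng=rng).as_matrix()
        lm2 = LandmarkSet(lm1.points @ r.T + np.array([2.0, -1.0, 3.0]))
        t_ref = solve_transform(lm1, lm2)
        pts = rng.uniform(-50, 50, (5, 3))
        for perm in itertools.permutations(range(3)):
            t = solve_transform(lm1.permuted(perm), lm2.permuted(perm))
            np.testing.assert_allclose(t.apply(pts), t_ref.apply(pts), atol=1e-9)

    def test_collinear_raises(self):
        line = LandmarkSet(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        tri = LandmarkSet(np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float))
        with pytest.raises(DegenerateLandmarksError):
            solve_transform(line, tri)


class TestApplyTransform:
    def test_anchor_maps_to_anchor(self):
        t = StitchTransform(np.eye(3), np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        np.testing.assert_allclose(apply_transform(t, [1.0, 2, 3]), [4.0, 5, 6])

    def test_identity(self, rng):
        t = StitchTransform.identity()
        p = rng.uniform(-10, 10, (4, 3))
        np.testing.assert_allclose(apply_transform(t, p), p)

    def test_matches_explicit_matrix_arithmetic(self, rng):
        linear = Rotation.random(rng=rng).as_matrix()
        b2, b1 = rng.uniform(-20, 20, 3), rng.uniform(-20, 20, 3)
        t = StitchTransform(linear, b2, b1)
        p = rng.uniform(-50, 50, 3)
        np.testing.assert_allclose(
            apply_transform(t, p), b1 + linear @ (p - b2), atol=1e-12
        )

    def test_parameter_recovery_from_exact_landmarks(self, rng):
        """Known rigid motion is recovered to 0.1 deg / 0.1 mm from exact picks."""
        lm1 = random_triangle(rng)
        r = Rotation.from_euler("xyz", [3.0, -2.0, 5.0], degrees=True).as_matrix()
        tvec = np.array([4.0, -1.0, 8.0])
        # segment-two anatomy moved by (r, tvec): true map back is (r.T, -r.T t)
        lm2 = LandmarkSet(lm1.points @ r.T + tvec)
        t = solve_transform(lm1, lm2)
        rot_err = Rotation.from_matrix(t.linear_part @ r).magnitude()
        assert np.degrees(rot_err) < 0.1
        _, offset = t.as_affine()
        np.testing.assert_allclose(offset, -r.T @ tvec, atol=0.1)
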