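"""Three-landmark rigid alignment between two body-segment acquisitions.

Each leg carries three fiducial landmarks (radio-opaque BBs) visible in the
overlap band of both acquisitions.  Writing the landmark triples of the two
segments as A, B, C (segment one) and A', B', C' (segment two), rigid motion
of the leg means every dot product and cross product among the edge vectors
is preserved, which yields three linear equations for the segment-one
position X of any segment-two point Y:

    M2 . (Y - B')  =  M1 . (X - B)

where Mi stacks the rows (A-B), (C-B) and (A-B)x(C-B) of the respective
segment.  The unique solution

    X = B + M1^-1 . M2 . (Y - B')

exists whenever the three landmarks are not collinear (det M1 != 0).  For
exactly congruent triangles M1^-1.M2 is a proper rotation, so the mapping is
rigid; small congruence residuals (soft-tissue deformation between the two
scans) distort it mildly and are reported, never fatal.

All geometry is carried out in patient-space millimetres, so one transform
serves both the CT and the PET grid of a segment regardless of their voxel
sizes or fields of view.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LandmarkSet",
    "StitchTransform",
    "DegenerateLandmarksError",
    "CongruenceWarning",
    "check_nondegenerate",
    "match_landmarks",
    "solve_transform",
    "apply_transform",
    "DEGENERACY_TOL",
    "CONGRUENCE_WARN_MM",
]

#: Normalized-determinant threshold below which a landmark triple is treated
#: as collinear (the exact-zero condition, padded for floating point and for
#: nearly collinear picks that would make the solve ill-conditioned).
DEGENERACY_TOL = 1e-6

#: Pairwise-distance mismatch (mm) above which a non-fatal congruence warning
#: is emitted; stitching proceeds regardless.
CONGRUENCE_WARN_MM = 5.0

LABELS = ("a", "b", "c")


class DegenerateLandmarksError(ValueError):
    """Landmarks are duplicated or collinear: the transform is not unique."""


class CongruenceWarning(UserWarning):
    """The two landmark triangles differ by more than the rigid-motion
    tolerance (likely soft-tissue deformation between the segments)."""


@dataclass(frozen=True)
class LandmarkSet:
    """Three labelled fiducial positions for one leg in one segment.

    Parameters
    ----------
    points : (3, 3) array
        Rows are the landmarks labelled ``a``, ``b``, ``c``; columns are
        patient-space x, y, z in millimetres.
    side : {"left", "right", ""}
    segment : {"upper", "lower", ""}
    """

    points: np.ndarray
    side: str = ""
    segment: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (3, 3):
            raise ValueError(f"expected three 3D points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        d = self.distance_matrix()
        off = d[np.triu_indices(3, k=1)]
        if np.any(off <= 0.0):
            raise DegenerateLandmarksError(
                "duplicate landmark pick: this landmark has already been "
                "chosen, please make another choice"
            )

    @property
    def a(self) -> np.ndarray:
        return self.points[0]

    @property
    def b(self) -> np.ndarray:
        return self.points[1]

    @property
    def c(self) -> np.ndarray:
        return self.points[2]

    def distance_matrix(self) -> np.ndarray:
        """Symmetric 3x3 matrix of pairwise landmark distances (mm)."""
        diff = self.points[:, None, :] - self.points[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def permuted(self, perm) -> "LandmarkSet":
        """Return a copy with points reordered so new row i is old row perm[i]."""
        return replace(self, points=self.points[list(perm)])


@dataclass(frozen=True)
class StitchTransform:
    """The solved rigid mapping from segment-two to segment-one coordinates.

    Applies as ``X = anchor_target + linear_part . (Y - anchor_source)``
    where the anchors are the B landmark of each segment.  For exactly
    congruent landmark triangles ``linear_part`` is a proper rotation.
    """

    linear_part: np.ndarray
    anchor_source: np.ndarray  # B of segment two, mm
    anchor_target: np.ndarray  # B of segment one, mm
    congruence_residual: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear_part", np.asarray(self.linear_part, float))
        object.__setattr__(self, "anchor_source", np.asarray(self.anchor_source, float))
        object.__setattr__(self, "anchor_target", np.asarray(self.anchor_target, float))

    @classmethod
    def identity(cls) -> "StitchTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Map one point (3,) or many points (..., 3) from segment two into
        segment-one/stitched coordinates."""
        p = np.asarray(points, dtype=float)
        return (p - self.anchor_source) @ self.linear_part.T + self.anchor_target

    def inverse(self) -> "StitchTransform":
        return StitchTransform(
            np.linalg.inv(self.linear_part),
            anchor_source=self.anchor_target,
            anchor_target=self.anchor_source,
            congruence_residual=self.congruence_residual,
        )

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (L, o) such that X = L.Y + o."""
        return self.linear_part, self.anchor_target - self.linear_part @ self.anchor_source

    def rotation_angle_deg(self) -> float:
        """Rotation angle (degrees) of the nearest proper rotation.

        For congruent landmark triangles the linear part is itself a
        rotation; with a nonzero congruence residual it deviates slightly
        from orthogonality, so the angle is read off the polar factor.
        """
        u, _, vt = np.linalg.svd(self.linear_part)
        r = u @ np.diag([1.0, 1.0, float(np.sign(np.linalg.det(u @ vt)))]) @ vt
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _edge_matrix(points: np.ndarray, anchor: int, others: tuple[int, int]) -> np.ndarray:
    """Rows (A-B), (C-B), (A-B)x(C-B) for the given vertex roles."""
    u = points[others[0]] - points[anchor]
    v = points[others[1]] - points[anchor]
    return np.array([u, v, np.cross(u, v)])


def check_nondegenerate(lm: LandmarkSet) -> float:
    """Scaled determinant of the landmark edge matrix.

    Returns |det M| / L^3 where L is the RMS side length of the landmark
    triangle, a dimensionless non-collinearity measure that is zero exactly
    when the three points lie on a line.  Values below
    :data:`DEGENERACY_TOL` should be treated as degenerate.
    """
    d = lm.distance_matrix()
    sides = d[np.triu_indices(3, k=1)]
    if np.any(sides <= 0.0):  # unreachable through the constructor, kept as a guard
        raise DegenerateLandmarksError("duplicate landmark pick")
    m = _edge_matrix(lm.points, anchor=1, others=(0, 2))
    rms = float(np.sqrt(np.mean(sides**2)))
    return float(abs(np.linalg.det(m)) / rms**3)


def match_landmarks(
    lm1: LandmarkSet, lm2: LandmarkSet, warn_threshold: float = CONGRUENCE_WARN_MM
) -> tuple[tuple[int, int, int], float]:
    """Find the correspondence between two arbitrarily ordered landmark triples.

    The pick order of the BBs is arbitrary, so all six permutations of
    ``lm2`` are scored by the sum of squared differences between the
    corresponding pairwise distances and the minimizer is returned, with
    lexicographic tie-breaking.

    Returns
    -------
    perm : tuple of int
        ``lm2.permuted(perm)`` is in correspondence with ``lm1``.
    residual : float
        Maximum absolute pairwise-distance mismatch (mm) for the winner
        (the congruence residual; zero under perfectly rigid motion).
    """
    for lm in (lm1, lm2):
        if check_nondegenerate(lm) < DEGENERACY_TOL:
            raise DegenerateLandmarksError(
                "collinear landmarks: the transform would not be unique"
            )
    d1 = lm1.distance_matrix()
    d2 = lm2.distance_matrix()
    iu = np.triu_indices(3, k=1)
    best_perm: tuple[int, int, int] | None = None
    best_cost = np.inf
    for perm in sorted(itertools.permutations(range(3))):
        p = list(perm)
        diff = (d1 - d2[np.ix_(p, p)])[iu]
        cost = float(np.sum(diff**2))
        if cost < best_cost:
            best_cost = cost
            best_perm = perm
    p = list(best_perm)
    residual = float(np.max(np.abs((d1 - d2[np.ix_(p, p)])[iu])))
    if residual > warn_threshold:
        warnings.warn(
            f"landmark triangles differ by {residual:.2f} mm in pairwise "
            "distances; possible soft-tissue deformation between segments",
            CongruenceWarning,
            stacklevel=2,
        )
    return best_perm, residual


def _anchor_index(lm: LandmarkSet) -> int:
    """Vertex used as the transform anchor B: the point minimizing the sum of
    distances to the other two (ties: lowest index), so the result does not
    depend on pick order."""
    sums = lm.distance_matrix().sum(axis=1)
    return int(np.argmin(sums))


def solve_transform(lm1: LandmarkSet, lm2: LandmarkSet) -> StitchTransform:
    """Solve the three-equation system for the segment-two -> segment-one map.

    ``lm2`` must already be permuted into correspondence with ``lm1``
    (see :func:`match_landmarks`).  The anchor vertex B is chosen from
    ``lm1`` by the minimum-distance-sum rule and the same vertex role is
    used in ``lm2``, so the transform is invariant to the order in which
    the landmarks were picked.
    """
    for lm in (lm1, lm2):
        if check_nondegenerate(lm) < DEGENERACY_TOL:
            raise DegenerateLandmarksError(
                "collinear landmarks: the transform would not be unique"
            )
    ib = _anchor_index(lm1)
    others = tuple(i for i in range(3) if i != ib)
    m1 = _edge_matrix(lm1.points, ib, others)
    m2 = _edge_matrix(lm2.points, ib, others)
    try:
        linear = np.linalg.solve(m1, m2)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateLandmarksError("singular landmark matrix") from exc
    d1 = lm1.distance_matrix()
    d2 = lm2.distance_matrix()
    residual = float(np.max(np.abs(d1 - d2)[np.triu_indices(3, k=1)]))
    return StitchTransform(
        linear_part=linear,
        anchor_source=lm2.points[ib],
        anchor_target=lm1.points[ib],
        congruence_residual=residual,
    )


def apply_transform(t: StitchTransform, p) -> np.ndarray:
    """Map point(s) ``p`` (mm) from segment-two into stitched coordinates."""
    return t.apply(p)
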