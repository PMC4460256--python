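"""Morphological acupoints: distance-functional minimization along a surface
curve between two control points.

For each target the unknown position X on the target head is chosen so that
its distances to the two target-side control points best reproduce the
distances of the standard-source target R to the standard-source controls
P and Q:

    L(X) = (|X - P'| - |R - P|)^2 + (|X - Q'| - |R - Q|)^2

L vanishes when source and target coincide, so running the solver with the
standard model as its own target recovers the standard positions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .catalog import Catalog, MorphRule, load_catalog
from .landmarks import Landmark, LandmarkSet
from .surface import SurfaceMesh


class CurveError(RuntimeError):
    pass


@dataclass
class CurvePath:
    """Ordered polyline of surface vertices from control A to control B."""

    points: np.ndarray           # (N, 3)
    vertex_indices: np.ndarray | None = None  # indices into the source mesh

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise CurveError("curve needs at least two vertices")
        if self.vertex_indices is not None:
            self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)

    @property
    def arc_length(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_waypoints(cls, waypoints, points_per_segment: int = 1) -> "CurvePath":
        """Densified polyline through the given waypoints; the waypoints
        themselves are kept as exact vertices."""
        waypoints = np.asarray(waypoints, dtype=float)
        pieces = [waypoints[:1]]
        for a, b in zip(waypoints[:-1], waypoints[1:]):
            ts = np.linspace(0.0, 1.0, points_per_segment + 1)[1:]
            pieces.append(a[None, :] + ts[:, None] * (b - a)[None, :])
        return cls(np.concatenate(pieces, axis=0))


@dataclass(frozen=True)
class MorphSolution:
    target: str
    position: tuple[float, float, float]
    L_value: float
    side: str
    curve_index: int = -1

    def __post_init__(self) -> None:
        if self.L_value < 0:
            raise ValueError("L must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.position)


def candidate_curve(
    mesh: SurfaceMesh,
    p_prime,
    q_prime,
    center,
    plane_tol: float,
    *,
    max_widen: int = 4,
) -> CurvePath:
    """Chain of mesh vertices near the plane through the two controls and
    ``center``, ordered along the shorter arc from ``p_prime`` to ``q_prime``.

    Vertices are parametrized by their angle about ``center`` within the
    section plane; the nearest mesh vertices to the two controls become the
    curve endpoints.
    """
    p_prime = np.asarray(p_prime, dtype=float)
    q_prime = np.asarray(q_prime, dtype=float)
    center = np.asarray(center, dtype=float)
    u = p_prime - center
    v = q_prime - center
    if np.linalg.norm(p_prime - q_prime) < 1e-12:
        raise CurveError("control points coincide")
    normal = np.cross(u, v)
    if np.linalg.norm(normal) < 1e-12 * np.linalg.norm(u) * np.linalg.norm(v):
        raise CurveError("section plane is degenerate (controls collinear with center)")
    normal = normal / np.linalg.norm(normal)

    tree = cKDTree(mesh.vertices)
    _d_p, idx_p = tree.query(p_prime)
    _d_q, idx_q = tree.query(q_prime)

    e1 = u / np.linalg.norm(u)
    w = v - (v @ e1) * e1
    e2 = w / np.linalg.norm(w)
    span = float(np.arctan2(v @ e2, v @ e1))  # in (0, pi): shorter arc

    rel = mesh.vertices - center
    dist = np.abs(rel @ normal)
    phi = np.arctan2(rel @ e2, rel @ e1)
    # clamp to the angular range spanned by the endpoint vertices so the
    # nearest vertices to the controls open and close the chain
    lo, hi = sorted((phi[idx_p], phi[idx_q]))
    lo, hi = max(lo, -1e-9), min(hi, span + 1e-9)

    for step in range(max_widen + 1):
        tol = plane_tol * (2.0 ** step)
        sel = (dist <= tol) & (phi >= lo) & (phi <= hi)
        sel[idx_p] = sel[idx_q] = True
        indices = np.flatnonzero(sel)
        if len(indices) >= 2:
            order = np.argsort(phi[indices])
            indices = indices[order]
            if phi[idx_p] > phi[idx_q]:  # orient the chain from A to B
                indices = indices[::-1]
            return CurvePath(mesh.vertices[indices], indices)
    raise CurveError("no connected arc between the control points")


def distance_functional(x, p_prime, q_prime, p, q, r) -> float | np.ndarray:
    """Squared mismatch between target-side and source-side control
    distances; zero iff X reproduces the source geometry exactly."""
    x = np.asarray(x, dtype=float)
    d_p = np.linalg.norm(np.atleast_2d(x) - np.asarray(p_prime), axis=1)
    d_q = np.linalg.norm(np.atleast_2d(x) - np.asarray(q_prime), axis=1)
    s_p = np.linalg.norm(np.asarray(r, dtype=float) - np.asarray(p, dtype=float))
    s_q = np.linalg.norm(np.asarray(r, dtype=float) - np.asarray(q, dtype=float))
    L = (d_p - s_p) ** 2 + (d_q - s_q) ** 2
    return float(L[0]) if x.ndim == 1 else L


def minimize_on_curve(curve: CurvePath, p_prime, q_prime, p, q, r) -> tuple[int, float]:
    """Exhaustive minimization of the functional over curve vertices; ties go
    to the smaller arc-length coordinate."""
    L = distance_functional(curve.points, p_prime, q_prime, p, q, r)
    idx = int(np.argmin(L))  # argmin returns the first (smallest arc length)
    return idx, float(L[idx])


def solve_on_curve(
    rule: MorphRule, curve: CurvePath, p_prime, q_prime, side: str
) -> list[MorphSolution]:
    """Solve every target of ``rule`` on an already-built curve."""
    solutions = []
    p = rule.standard_point(rule.control_a, side)
    q = rule.standard_point(rule.control_b, side)
    for target in rule.targets:
        r = rule.standard_point(target, side)
        idx, value = minimize_on_curve(curve, p_prime, q_prime, p, q, r)
        solutions.append(
            MorphSolution(target, tuple(curve.points[idx]), value, side, idx)
        )
    return solutions


def solve_morph_rule(
    rule: MorphRule,
    mesh: SurfaceMesh,
    target_controls: LandmarkSet,
    side: str,
    *,
    center=None,
    plane_tol: float = 4.0 / 512.0,
) -> list[MorphSolution]:
    """Build the candidate curve between the rule's target-side controls and
    minimize the functional for each target on it."""
    try:
        p_prime = target_controls.point(rule.control_a, side)
        q_prime = target_controls.point(rule.control_b, side)
    except KeyError as exc:
        raise CurveError(f"missing control point: {exc}") from exc
    center = (
        np.asarray(center, dtype=float)
        if center is not None
        else mesh.vertices.mean(axis=0)
    )
    curve = candidate_curve(mesh, p_prime, q_prime, center, plane_tol)
    return solve_on_curve(rule, curve, p_prime, q_prime, side)


def compute_all_morphological(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    catalog: Catalog | None = None,
    *,
    center=None,
    plane_tol: float = 4.0 / 512.0,
    collect_curves: dict | None = None,
) -> LandmarkSet:
    """All 7 morphological names on both sides (14 instances).

    ``landmarks`` must contain the anatomical controls and the upstream
    proportional point ST8.  ``collect_curves`` (optional dict) receives each
    rule's curve keyed by ``(control_a, control_b, side)``.
    """
    catalog = catalog or load_catalog()
    out = LandmarkSet()
    for rule in catalog.morph_rules:
        for side in ("left", "right"):
            for ctrl in (rule.control_a, rule.control_b):
                if (ctrl, side) not in landmarks:
                    raise CurveError(f"missing control point ({ctrl}, {side})")
            p_prime = landmarks.point(rule.control_a, side)
            q_prime = landmarks.point(rule.control_b, side)
            ctr = (
                np.asarray(center, dtype=float)
                if center is not None
                else mesh.vertices.mean(axis=0)
            )
            curve = candidate_curve(mesh, p_prime, q_prime, ctr, plane_tol)
            if collect_curves is not None:
                collect_curves[(rule.control_a, rule.control_b, side)] = curve
            for sol in solve_on_curve(rule, curve, p_prime, q_prime, side):
                out.add(
                    Landmark(
                        sol.target, side, sol.position,
                        frame=mesh.frame_tag, provenance="computed",
                        category="morphological",
                    )
                )
    return out
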