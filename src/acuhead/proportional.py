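"""Proportional acupoints: angle-ratio and coordinate-constraint solvers.

All angles share one vertex, the midpoint of the two TE20 points (``te20cp``).
``theta0`` is the reference angle subtended there by Yintang and GV17; ratio
rules place points where the angle to the GV17 ray (sagittal rules) or to the
GV24 ray (transverse rules) is a prescribed fraction of ``theta0``.  Skin
vertices satisfying a rule within a small interval are averaged and the mean
snapped to the nearest mesh vertex, so every output lies on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .catalog import Catalog, ProportionalRule, load_catalog
from .frames import (
    DEFAULT_ALPHA,
    Plane,
    coronal_plane,
    sagittal_plane,
    transverse_plane,
)
from .landmarks import Landmark, LandmarkSet
from .surface import SurfaceMesh


class RuleSolveError(RuntimeError):
    """Raised when a rule's surface selection stays empty after widening."""


@dataclass(frozen=True)
class AngleFrame:
    """Vertex point and reference rays for the angle machinery."""

    te20cp: tuple[float, float, float]
    theta0: float
    yintang: tuple[float, float, float]
    gv17: tuple[float, float, float]

    def __post_init__(self) -> None:
        # exactly antipodal reference rays (theta0 == pi) are representable,
        # but degenerate for sagittal interpolation
        if not 0.0 < self.theta0 <= np.pi:
            raise ValueError(f"theta0 must lie in (0, pi]; got {self.theta0}")

    @property
    def vertex(self) -> np.ndarray:
        return np.asarray(self.te20cp)

    def ray(self, point) -> np.ndarray:
        d = np.asarray(point, dtype=float) - self.vertex
        length = np.linalg.norm(d)
        if length == 0:
            raise ValueError("zero-length ray from te20cp")
        return d / length


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances for the surface selection bands.

    ``voxel_pitch`` is the model-frame size of one voxel (alpha * spacing);
    plane/coordinate bands default to half of it.  Empty selections widen all
    tolerances geometrically, up to ``widen_steps`` times.
    """

    voxel_pitch: float = DEFAULT_ALPHA
    ratio_tol_deg: float = 0.25
    plane_tol: float | None = None
    coord_tol: float | None = None
    widen_factor: float = 2.0
    widen_steps: int = 4

    @property
    def plane_band(self) -> float:
        return self.plane_tol if self.plane_tol is not None else 0.5 * self.voxel_pitch

    @property
    def coord_band(self) -> float:
        return self.coord_tol if self.coord_tol is not None else 0.75 * self.voxel_pitch


def build_angle_frame(landmarks: LandmarkSet) -> AngleFrame:
    """Midpoint of the TE20 pair plus the Yintang/GV17 reference angle."""
    te20cp = 0.5 * (landmarks.point("TE20", "left") + landmarks.point("TE20", "right"))
    yintang = landmarks.point("Yintang")
    gv17 = landmarks.point("GV17")
    for name, p in (("Yintang", yintang), ("GV17", gv17)):
        if np.linalg.norm(p - te20cp) == 0:
            raise ValueError(f"{name} coincides with te20cp; ray undefined")
    u = (yintang - te20cp) / np.linalg.norm(yintang - te20cp)
    v = (gv17 - te20cp) / np.linalg.norm(gv17 - te20cp)
    theta0 = float(np.arccos(np.clip(u @ v, -1.0, 1.0)))
    return AngleFrame(tuple(te20cp), theta0, tuple(yintang), tuple(gv17))


def _angles_to_ray(points: np.ndarray, vertex: np.ndarray, ray: np.ndarray) -> np.ndarray:
    d = np.atleast_2d(points) - vertex
    norms = np.linalg.norm(d, axis=1)
    if (norms == 0).any():
        raise ValueError("point coincides with te20cp; angle undefined")
    cosang = np.clip((d / norms[:, None]) @ ray, -1.0, 1.0)
    return np.arccos(cosang)


def theta1(p, frame: AngleFrame, gv17=None) -> float | np.ndarray:
    """Angle at te20cp between the ray to ``p`` and the ray to GV17."""
    gv17 = frame.gv17 if gv17 is None else gv17
    out = _angles_to_ray(np.asarray(p, dtype=float), frame.vertex, frame.ray(gv17))
    return float(out[0]) if np.ndim(p) == 1 else out


def theta2(p, frame: AngleFrame, gv24) -> float | np.ndarray:
    """Angle at te20cp between the ray to ``p`` and the ray to GV24 (which
    must already have been computed)."""
    if gv24 is None:
        raise ValueError("theta2 requires GV24, which has not been computed yet")
    out = _angles_to_ray(np.asarray(p, dtype=float), frame.vertex, frame.ray(gv24))
    return float(out[0]) if np.ndim(p) == 1 else out


def _slerp(u: np.ndarray, v: np.ndarray, angle: float, total: float) -> np.ndarray:
    """Rotate unit vector ``u`` toward ``v`` (separated by ``total``) by
    ``angle`` within their common plane."""
    if total < 1e-12:
        return u
    s = np.sin(total)
    return (np.sin(total - angle) * u + np.sin(angle) * v) / s


def _snap(mesh: SurfaceMesh, point: np.ndarray, tree: cKDTree | None = None):
    tree = tree or cKDTree(mesh.vertices)
    _dist, idx = tree.query(point)
    return mesh.vertices[int(idx)], int(idx)


def _widened(config: SolverConfig, step: int) -> float:
    return config.widen_factor ** step


def solve_ratio_point(
    mesh: SurfaceMesh,
    frame: AngleFrame,
    rule: ProportionalRule,
    plane: Plane,
    config: SolverConfig = SolverConfig(),
    *,
    gv24=None,
    side_plane: Plane | None = None,
    side_sign: float = 0.0,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Mean of skin vertices in the rule's angle/plane band, snapped to the
    nearest mesh vertex.

    Sagittal rules measure the angle from the GV17 ray and are restricted to
    the cranial branch (near the ray interpolated from GV17 toward Yintang);
    transverse rules measure from the GV24 ray within the transverse band and
    are restricted to one side of the sagittal plane via ``side_plane`` and
    ``side_sign``.
    """
    verts = mesh.vertices
    theta_target = rule.ratio * frame.theta0
    if rule.rule_kind == "sagittal_ratio":
        ref_ray = frame.ray(frame.gv17)
        branch_ray = _slerp(
            ref_ray, frame.ray(frame.yintang), theta_target, frame.theta0
        )
    elif rule.rule_kind == "transverse_ratio":
        if gv24 is None:
            raise ValueError(f"{rule.target}: transverse rule requires GV24")
        ref_ray = frame.ray(gv24)
        branch_ray = None
    else:
        raise ValueError(f"{rule.target} is not a ratio rule")

    angles = _angles_to_ray(verts, frame.vertex, ref_ray)
    plane_dist = np.abs(plane.signed_distance(verts))
    if branch_ray is not None:
        branch_angles = _angles_to_ray(verts, frame.vertex, branch_ray)
    if side_plane is not None and side_sign != 0.0:
        side_ok = side_plane.signed_distance(verts) * side_sign > 0
    else:
        side_ok = np.ones(len(verts), dtype=bool)

    base_tol = np.deg2rad(config.ratio_tol_deg)
    for step in range(config.widen_steps + 1):
        w = _widened(config, step)
        sel = (
            (np.abs(angles - theta_target) <= base_tol * w)
            & (plane_dist <= config.plane_band * w)
            & side_ok
        )
        if branch_ray is not None:
            sel &= branch_angles <= theta_target + base_tol * w
        if sel.any():
            mean = verts[sel].mean(axis=0)
            snapped, _ = _snap(mesh, mean, tree)
            return snapped
    raise RuleSolveError(
        f"rule {rule.target}: empty selection after {config.widen_steps} widenings"
    )


def solve_coordinate_point(
    mesh: SurfaceMesh,
    rule: ProportionalRule,
    resolve,
    config: SolverConfig = SolverConfig(),
    *,
    anterior_sign: float = 1.0,
    superior_sign: float = 1.0,
    center=None,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Mean of skin vertices satisfying every coordinate constraint within a
    band, on the hemisphere the rule prescribes; ``resolve(name)`` supplies
    referenced point coordinates (same side as the target for bilateral ones).
    """
    verts = mesh.vertices
    center = np.asarray(
        center if center is not None else verts.mean(axis=0), dtype=float
    )
    if rule.rule_kind == "midpoint":
        pts = [resolve(name) for name in rule.midpoint_of]
        snapped, _ = _snap(mesh, np.mean(pts, axis=0), tree)
        return snapped
    if rule.rule_kind != "coordinate":
        raise ValueError(f"{rule.target} is not a coordinate rule")

    targets = [
        ("xyz".index(c.axis), c.evaluate(resolve)) for c in rule.constraints
    ]
    if rule.hemisphere == "anterior":
        hemi = (verts[:, 1] - center[1]) * anterior_sign > 0
    elif rule.hemisphere == "posterior":
        hemi = (verts[:, 1] - center[1]) * anterior_sign < 0
    elif rule.hemisphere == "superior":
        hemi = (verts[:, 2] - center[2]) * superior_sign > 0
    else:
        hemi = np.ones(len(verts), dtype=bool)

    for step in range(config.widen_steps + 1):
        band = config.coord_band * _widened(config, step)
        sel = hemi.copy()
        for axis, value in targets:
            sel &= np.abs(verts[:, axis] - value) <= band
        if sel.any():
            mean = verts[sel].mean(axis=0)
            snapped, _ = _snap(mesh, mean, tree)
            return snapped
    raise RuleSolveError(
        f"rule {rule.target}: empty selection after {config.widen_steps} widenings"
    )


def _dependency_order(rules: list[ProportionalRule]) -> list[ProportionalRule]:
    """Topological order so every rule runs after the rule targets it uses;
    transverse rules implicitly depend on GV24 (their reference ray)."""
    targets = {r.target for r in rules}
    deps = {}
    for rule in rules:
        d = {name for name in rule.referenced if name in targets}
        if rule.rule_kind == "transverse_ratio":
            d.add("GV24")
        d.discard(rule.target)
        deps[rule.target] = d
    ordered: list[ProportionalRule] = []
    done: set[str] = set()
    pending = list(rules)
    while pending:
        progress = [r for r in pending if deps[r.target] <= done]
        if not progress:
            chain = sorted(r.target for r in pending)
            raise RuleSolveError(f"dependency cycle or missing input among {chain}")
        for rule in progress:
            ordered.append(rule)
            done.add(rule.target)
        pending = [r for r in pending if r.target not in done]
    return ordered


def compute_all_proportional(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    catalog: Catalog | None = None,
    config: SolverConfig = SolverConfig(),
    *,
    include_aux: bool = False,
) -> LandmarkSet:
    """All 24 proportional points (bilateral ones on both sides) in rule
    dependency order; mesh and landmarks must share one coordinate frame."""
    catalog = catalog or load_catalog()
    frame = build_angle_frame(landmarks)
    yintang = landmarks.point("Yintang")
    top = landmarks.point("TOP")
    gv17 = landmarks.point("GV17")
    sag = sagittal_plane(yintang, top, gv17)
    cor = coronal_plane(
        landmarks.point("TE20", "left"), landmarks.point("TE20", "right"), top
    )
    side_signs = {
        side: float(np.sign(sag.signed_distance(landmarks.point("TE20", side))))
        for side in ("left", "right")
    }
    center = mesh.vertices.mean(axis=0)
    anterior_sign = float(np.sign(yintang[1] - gv17[1])) or 1.0
    superior_sign = float(np.sign(top[2] - frame.vertex[2])) or 1.0
    tree = cKDTree(mesh.vertices)

    computed: dict[tuple[str, str], np.ndarray] = {}

    def resolver(side: str):
        def resolve(name: str) -> np.ndarray:
            for key in ((name, side), (name, "midline")):
                if key in computed:
                    return computed[key]
            return landmarks.point(name, side)
        return resolve

    for rule in _dependency_order(list(catalog.proportional_rules)):
        if rule.target in catalog.points:
            sides = catalog.record(rule.target).sides
        else:  # internal intermediate (AUX) rides the sagittal midline
            sides = ("midline",)
        for side in sides:
            if rule.rule_kind == "sagittal_ratio":
                pos = solve_ratio_point(
                    mesh, frame, rule, sag, config, tree=tree
                )
            elif rule.rule_kind == "transverse_ratio":
                gv24 = computed[("GV24", "midline")]
                trans = transverse_plane(sag, cor, gv24)
                pos = solve_ratio_point(
                    mesh, frame, rule, trans, config,
                    gv24=gv24, side_plane=sag, side_sign=side_signs[side],
                    tree=tree,
                )
            else:
                pos = solve_coordinate_point(
                    mesh, rule, resolver(side), config,
                    anterior_sign=anterior_sign, superior_sign=superior_sign,
                    center=center, tree=tree,
                )
            computed[(rule.target, side)] = pos

    out = LandmarkSet()
    for (name, side), pos in computed.items():
        if name not in catalog.points and not include_aux:
            continue
        category = (
            catalog.record(name).category if name in catalog.points else "auxiliary"
        )
        out.add(
            Landmark(
                name, side, tuple(pos),
                frame=mesh.frame_tag, provenance="computed", category=category,
            )
        )
    return out
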