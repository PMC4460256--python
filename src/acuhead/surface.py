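"""Triangulated surface reconstruction from binary volumes and mesh I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage import measure

from .phantom import BinaryVolume


@dataclass
class SurfaceMesh:
    """Triangle mesh with per-vertex normals.

    ``frame_tag`` is ``stack`` for meshes straight out of reconstruction
    (voxel units scaled by spacing) and ``model`` after the centred/scaled
    transform has been applied.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    frame_tag: str = "stack"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(
                self.vertex_normals, dtype=float
            ).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        n = np.cross(a, b)
        lengths = np.linalg.norm(n, axis=1)
        lengths[lengths == 0] = 1.0
        return n / lengths[:, None]

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def transformed(self, func, frame_tag: str) -> "SurfaceMesh":
        mesh = SurfaceMesh(
            np.asarray(func(self.vertices)),
            self.faces.copy(),
            None,
            frame_tag,
        )
        return smooth_normals(mesh)


def _largest_component(verts: np.ndarray, faces: np.ndarray):
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    n = len(verts)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp <= 1:
        keep_faces = faces
        keep_mask = np.ones(n, dtype=bool)
    else:
        sizes = np.bincount(labels)
        keep = sizes.argmax()
        keep_mask = labels == keep
        keep_faces = faces[keep_mask[faces[:, 0]]]
    # also drop vertices not referenced by any kept face
    used = np.zeros(n, dtype=bool)
    used[keep_faces.ravel()] = True
    keep_mask &= used
    remap = -np.ones(n, dtype=np.int64)
    remap[keep_mask] = np.arange(keep_mask.sum())
    return verts[keep_mask], remap[keep_faces]


def marching_cubes(
    bin_vol: BinaryVolume,
    iso: float = 0.5,
    *,
    keep_largest: bool = True,
) -> SurfaceMesh:
    """Triangulate the isosurface of a binary mask at level ``iso``.

    Vertex coordinates are in the stack frame, voxel indices scaled by the
    volume spacing.  Debris components are dropped by default; degenerate
    (zero-area) triangles are removed.
    """
    mask = bin_vol.mask
    if not mask.any() or mask.all():
        raise ValueError("no isosurface: mask is empty or full")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _normals, _values = measure.marching_cubes(
        padded, level=iso, spacing=tuple(bin_vol.spacing_mm)
    )
    verts = verts - np.asarray(bin_vol.spacing_mm)  # undo the 1-voxel pad
    if keep_largest:
        verts, faces = _largest_component(verts, faces)
    mesh = SurfaceMesh(verts, faces)
    areas = mesh.face_areas()
    if (areas == 0).any():
        mesh = SurfaceMesh(verts, faces[areas > 0])
    return smooth_normals(mesh)


def smooth_normals(mesh: SurfaceMesh) -> SurfaceMesh:
    """Per-vertex normals as the renormalized unweighted average of incident
    face normals; geometry is left untouched."""
    fn = mesh.face_normals()
    acc = np.zeros((mesh.n_vertices, 3))
    counts = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(acc, mesh.faces[:, col], fn)
        np.add.at(counts, mesh.faces[:, col], 1)
    isolated = np.flatnonzero(counts == 0)
    if isolated.size:
        raise ValueError(
            f"vertices with no incident face: {isolated[:10].tolist()}"
        )
    avg = acc / counts[:, None]
    lengths = np.linalg.norm(avg, axis=1)
    lengths[lengths == 0] = 1.0
    mesh.vertex_normals = avg / lengths[:, None]
    return mesh


# ---------------------------------------------------------------------- I/O

_FMT = "{:.6g}"


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply(mesh, path)
    elif path.suffix.lower() == ".obj":
        _write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    if path.suffix.lower() == ".obj":
        return _read_obj(path)
    raise ValueError(f"unsupported mesh format {path.suffix!r}")


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment frame {mesh.frame_tag}",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(" ".join(_FMT.format(c) for c in v))
    for f in mesh.faces:
        lines.append("3 " + " ".join(str(i) for i in f))
    path.write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> SurfaceMesh:
    lines = path.read_text().splitlines()
    n_vert = n_face = None
    frame = "stack"
    header_end = None
    for idx, line in enumerate(lines):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "element" and tokens[1] == "vertex":
            n_vert = int(tokens[2])
        elif tokens[0] == "element" and tokens[1] == "face":
            n_face = int(tokens[2])
        elif tokens[0] == "comment" and len(tokens) >= 3 and tokens[1] == "frame":
            frame = tokens[2]
        elif tokens[0] == "end_header":
            header_end = idx
            break
    if header_end is None or n_vert is None or n_face is None:
        raise ValueError(f"{path}: malformed PLY header")
    verts, faces = [], []
    for offset in range(n_vert):
        lineno = header_end + 1 + offset
        try:
            verts.append([float(t) for t in lines[lineno].split()[:3]])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno + 1}: bad vertex line") from exc
    for offset in range(n_face):
        lineno = header_end + 1 + n_vert + offset
        try:
            tokens = lines[lineno].split()
            count = int(tokens[0])
            if count != 3:
                raise ValueError("only triangle faces supported")
            faces.append([int(t) for t in tokens[1:4]])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno + 1}: bad face line") from exc
    return smooth_normals(SurfaceMesh(np.array(verts), np.array(faces), None, frame))


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    lines = [f"# frame {mesh.frame_tag}"]
    for v in mesh.vertices:
        lines.append("v " + " ".join(_FMT.format(c) for c in v))
    for f in mesh.faces:
        lines.append("f " + " ".join(str(i + 1) for i in f))  # OBJ is 1-based
    path.write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> SurfaceMesh:
    verts, faces = [], []
    frame = "stack"
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            if tokens[0] == "#" and len(tokens) >= 3 and tokens[1] == "frame":
                frame = tokens[2]
            elif tokens[0] == "v":
                verts.append([float(t) for t in tokens[1:4]])
            elif tokens[0] == "f":
                faces.append([int(t.split("/")[0]) - 1 for t in tokens[1:4]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: bad OBJ line") from exc
    if not verts:
        raise ValueError(f"{path}: no vertices found")
    return smooth_normals(SurfaceMesh(np.array(verts), np.array(faces), None, frame))
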