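"""Triangle-mesh data model, file I/O and geometric primitives.

All coordinates are in millimetres.  :class:`TriangleMesh` is the carrier used
by every other module: a plain vertices/faces pair with optional per-vertex
category labels (e.g. ``"articular"``).  File I/O (STL/PLY/OBJ, with vertex
welding) is delegated to :mod:`trimesh`; the point-to-surface distance query,
plane clipping and mirroring used throughout the shape analysis are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _tm
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "Plane",
    "read_surface",
    "write_surface",
    "point_to_mesh_distance",
    "points_to_mesh_distance",
    "closest_points",
    "clip_by_plane",
    "mirror_to_left",
    "reflection_matrix",
]

_WELD_TOL = 1e-6  # mm; STL stores a facet soup, shared vertices are welded


class MeshError(ValueError):
    """Raised for invalid meshes or mesh operations that cannot proceed."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array
        Vertex-index triples; all indices must be in range.  Degenerate
        (zero-area) faces are dropped on construction.
    vertex_labels : (V,) array of str, optional
        Per-vertex category tags, e.g. ``"articular"`` marking the
        trochlea+capitellum region.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        if self.faces is None:
            self.faces = np.zeros((0, 3), dtype=np.int64)  # point set without topology
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshError(f"faces must be (F, 3), got {self.faces.shape}")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")
        if self.faces.size:
            # drop zero-area faces (repeated indices or collinear vertices)
            tri = self.vertices[self.faces]
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            area2 = np.linalg.norm(cross, axis=1)
            keep = area2 > 1e-14
            if not keep.all():
                self.faces = self.faces[keep]
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels)
            if len(self.vertex_labels) != len(self.vertices):
                raise MeshError("vertex_labels length must match vertex count")

    # -- basic quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (mm^3).

        Positive for a closed mesh with outward-oriented faces.
        """
        tri = self.triangles
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)

    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    # -- conversions -------------------------------------------------------
    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: _tm.Trimesh, vertex_labels=None) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), vertex_labels)

    # -- transforms --------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "TriangleMesh":
        """Apply ``v -> R v + t`` to every vertex (labels preserved)."""
        rotation = np.asarray(rotation, dtype=float)
        v = self.vertices @ rotation.T + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy(), _copy_labels(self.vertex_labels))

    def submesh_from_vertex_mask(self, mask: np.ndarray) -> "TriangleMesh":
        """Faces whose three vertices are all selected, vertices re-indexed."""
        mask = np.asarray(mask, dtype=bool)
        face_mask = mask[self.faces].all(axis=1)
        return self.submesh_from_face_mask(face_mask)

    def submesh_from_face_mask(self, face_mask: np.ndarray) -> "TriangleMesh":
        faces = self.faces[np.asarray(face_mask, dtype=bool)]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        labels = self.vertex_labels[used] if self.vertex_labels is not None else None
        return TriangleMesh(self.vertices[used], remap[faces], labels)

    # -- cached spatial structures ----------------------------------------
    def _vertex_tree(self) -> cKDTree:
        tree = self._cache.get("vertex_tree")
        if tree is None:
            tree = cKDTree(self.vertices)
            self._cache["vertex_tree"] = tree
        return tree

    def _vertex_face_incidence(self):
        inc = self._cache.get("vfi")
        if inc is None:
            order = np.argsort(self.faces.ravel(), kind="stable")
            fidx = np.repeat(np.arange(self.n_faces), 3)[order]
            vids = self.faces.ravel()[order]
            starts = np.searchsorted(vids, np.arange(self.n_vertices))
            ends = np.searchsorted(vids, np.arange(self.n_vertices), side="right")
            inc = (fidx, starts, ends)
            self._cache["vfi"] = inc
        return inc

    def _max_edge(self) -> float:
        me = self._cache.get("max_edge")
        if me is None:
            tri = self.triangles
            e = np.concatenate(
                [
                    np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
                    np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
                    np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
                ]
            )
            me = float(e.max()) if e.size else 0.0
            self._cache["max_edge"] = me
        return me


def _copy_labels(labels):
    return None if labels is None else labels.copy()


@dataclass
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if n < 1e-12:
            raise MeshError("plane normal must be nonzero")
        self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = {"stl", "ply", "obj"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshError(f"unsupported mesh format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return fmt


def read_surface(path, format: str | None = None) -> TriangleMesh:
    """Read a triangle surface mesh (STL binary/ASCII, PLY, OBJ).

    Duplicated vertices (STL facet soup) are welded at a 1e-6 mm tolerance;
    face orientation is preserved.  Raises :class:`MeshError` for missing,
    malformed or empty files.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.is_file():
        raise MeshError(f"mesh file not found: {path}")
    try:
        loaded = _tm.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise MeshError(f"failed to parse {path} as {fmt.upper()}: {exc}") from exc
    if loaded is None or not hasattr(loaded, "vertices") or len(loaded.vertices) == 0:
        raise MeshError(f"{path}: empty mesh")
    # weld duplicated vertices at fixed tolerance, preserving winding
    loaded.merge_vertices(digits_vertex=int(-np.log10(_WELD_TOL)))
    if len(loaded.faces) == 0:
        raise MeshError(f"{path}: mesh has no valid faces")
    return TriangleMesh.from_trimesh(loaded)


def write_surface(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh re-readable by :func:`read_surface` (binary STL default)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshError("refusing to write an empty mesh")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# point-to-mesh distance
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each paired query point.

    Vectorized barycentric-region algorithm; ``points`` is (N, 3) and
    ``triangles`` is (N, 3, 3); returns the (N, 3) closest points (which may
    lie in a triangle's interior, on an edge, or at a vertex).
    """
    p = np.asarray(points, dtype=float)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    t = np.divide(d1[m], denom, out=np.zeros_like(denom), where=denom != 0)
    out[m] = a[m] + t[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    t = np.divide(d2[m], denom, out=np.zeros_like(denom), where=denom != 0)
    out[m] = a[m] + t[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    t = np.divide(d4[m] - d3[m], denom, out=np.zeros_like(denom), where=denom != 0)
    out[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    v = np.divide(vb[m], denom, out=np.zeros_like(denom), where=denom != 0)
    w = np.divide(vc[m], denom, out=np.zeros_like(denom), where=denom != 0)
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


def closest_points(points: np.ndarray, mesh: TriangleMesh):
    """Exact closest surface points of ``mesh`` for an array of query points.

    Returns ``(surface_points (N,3), distances (N,), face_indices (N,))``.
    Candidate triangles are culled with a vertex k-d tree: the nearest vertex
    gives an upper bound d, and any triangle containing a closer point must
    have a vertex within d + longest-edge, so the result is exact.
    """
    if mesh.n_faces == 0:
        raise MeshError("cannot compute distances to an empty mesh")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = mesh._vertex_tree()
    d_ub, _ = tree.query(points)
    radius = d_ub + mesh._max_edge() + 1e-9
    cand_vertices = tree.query_ball_point(points, radius)
    fidx, starts, ends = mesh._vertex_face_incidence()

    # expand (point, candidate-vertex) pairs to (point, incident-face) pairs
    # fully vectorized, then deduplicate faces per point
    v_counts = np.fromiter((len(v) for v in cand_vertices), dtype=np.int64, count=len(points))
    flat_v = np.fromiter(
        (v for vs in cand_vertices for v in vs), dtype=np.int64, count=int(v_counts.sum())
    )
    point_of_v = np.repeat(np.arange(len(points)), v_counts)
    f_counts = ends[flat_v] - starts[flat_v]
    # ranges trick: concatenated arange(starts[v], ends[v]) per flat_v entry
    offsets = np.repeat(np.cumsum(f_counts) - f_counts, f_counts)
    pos_in_run = np.arange(int(f_counts.sum())) - offsets
    face_slots = np.repeat(starts[flat_v], f_counts) + pos_in_run
    pf = fidx[face_slots]
    pp = np.repeat(point_of_v, f_counts)
    keys = np.unique(pp * np.int64(mesh.n_faces) + pf)
    pp, pf = keys // mesh.n_faces, keys % mesh.n_faces

    cp = closest_point_on_triangles(points[pp], mesh.triangles[pf])
    d = np.linalg.norm(cp - points[pp], axis=1)

    best = np.full(len(points), np.inf)
    np.minimum.at(best, pp, d)
    # recover argmin pairs (first matching occurrence per point)
    is_best = d <= best[pp] + 1e-15
    first = np.full(len(points), -1, dtype=np.int64)
    idx = np.nonzero(is_best)[0][::-1]
    first[pp[idx]] = idx
    return cp[first], np.linalg.norm(cp[first] - points, axis=1), pf[first]


def points_to_mesh_distance(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Unsigned Euclidean point-to-mesh distances for an array of points (mm)."""
    return closest_points(points, mesh)[1]


def point_to_mesh_distance(point, mesh: TriangleMesh) -> float:
    """Unsigned minimum Euclidean distance from one point to the surface (mm)."""
    return float(points_to_mesh_distance(np.asarray(point, dtype=float)[None, :], mesh)[0])


# ---------------------------------------------------------------------------
# clipping and mirroring
# ---------------------------------------------------------------------------


def clip_by_plane(mesh: TriangleMesh, plane: Plane, keep_side: int = 1) -> TriangleMesh:
    """Keep the sub-mesh on one side of a plane, splitting crossing triangles.

    ``keep_side=+1`` keeps the half-space the normal points into, ``-1`` the
    other.  Cut-boundary vertices lie on the plane to within 1e-6 mm.  Labels
    are propagated to cut vertices from the nearest original vertex.
    """
    if keep_side not in (1, -1):
        raise MeshError("keep_side must be +1 or -1")
    normal = plane.normal * keep_side
    sliced = _tm.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=normal, plane_origin=plane.point
    )
    if sliced is None or len(sliced.faces) == 0:
        raise MeshError("plane removes entire mesh")
    labels = None
    if mesh.vertex_labels is not None:
        _, nearest = mesh._vertex_tree().query(np.asarray(sliced.vertices))
        labels = mesh.vertex_labels[nearest]
    return TriangleMesh(np.asarray(sliced.vertices), np.asarray(sliced.faces), labels)


def reflection_matrix(normal: np.ndarray) -> np.ndarray:
    """Householder reflection ``I - 2 n n^T`` across a plane with unit normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return np.eye(3) - 2.0 * np.outer(n, n)


def mirror_to_left(mesh: TriangleMesh, plane: Plane | None = None) -> TriangleMesh:
    """Reflect a mesh across a plane, flipping winding to preserve orientation.

    Used to map right-sided bones to left-sided ones before pooling a cohort.
    Default plane: the y-z plane through the mesh centroid.
    """
    if plane is None:
        plane = Plane(mesh.centroid, np.array([1.0, 0.0, 0.0]))
    refl = reflection_matrix(plane.normal)
    v = (mesh.vertices - plane.point) @ refl.T + plane.point
    faces = mesh.faces[:, [0, 2, 1]]  # reflection reverses orientation
    return TriangleMesh(v, faces, _copy_labels(mesh.vertex_labels))
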