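"""Template-to-target mesh correspondence.

The shape model requires every bone to be expressed on one shared topology.
This module establishes that correspondence the standard way: rigid
registration (landmark Procrustes when landmarks are available, iterative
closest point otherwise), then a stiffness-scheduled non-rigid ICP that morphs
the template onto each target with a per-vertex locally-affine deformation
regularized by a first-order stiffness term.  Decreasing the stiffness over a
schedule lets the template first track gross shape, then fine detail, while
correspondence rejection (distance and normal-compatibility gates) keeps thin
structures such as the olecranon-fossa rim from snapping across the fossa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import MeshError, TriangleMesh, closest_points

__all__ = [
    "RigidTransform",
    "CorrespondenceSet",
    "ICPConfig",
    "MorphConfig",
    "procrustes_rigid",
    "icp_refine",
    "nonrigid_morph",
    "build_correspondence_set",
    "correspondence_from_population",
]


class RegistrationError(RuntimeError):
    """Raised when a registration step cannot be completed."""


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation contains a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, float)) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)


@dataclass
class CorrespondenceSet:
    """n shapes x (V*3) matrix of corresponded vertex coordinates.

    Every row shares the template topology (``template_faces``); ``residuals``
    are the per-shape mean surface distances of the morphed template to its
    target (mm).
    """

    template_faces: np.ndarray
    shapes: np.ndarray
    sample_ids: list
    residuals: np.ndarray
    vertex_labels: np.ndarray | None = None
    landmark_vertex_indices: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.template_faces = np.asarray(self.template_faces, dtype=np.int64)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.shapes.ndim != 2:
            raise ValueError("shapes must be a 2-D (n, V*3) matrix")
        if self.shapes.shape[1] % 3 != 0:
            raise ValueError("row length must be a multiple of 3")
        if len(self.sample_ids) != len(self.shapes) or len(self.residuals) != len(self.shapes):
            raise ValueError("sample_ids/residuals must match the number of shapes")
        if (self.residuals < 0).any():
            raise ValueError("residuals must be nonnegative")

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1] // 3

    def shape_mesh(self, i: int) -> TriangleMesh:
        return TriangleMesh(self.shapes[i].reshape(-1, 3), self.template_faces, self.vertex_labels)

    # plain-text serialization (matrix + faces + manifest)
    def save(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "shapes.tsv", self.shapes, fmt="%.9g", delimiter="\t")
        np.savetxt(outdir / "faces.tsv", self.template_faces, fmt="%d", delimiter="\t")
        manifest = {
            "sample_ids": [str(s) for s in self.sample_ids],
            "residuals": [float(r) for r in self.residuals],
            "excluded": self.excluded,
            "landmark_vertex_indices": {k: int(v) for k, v in self.landmark_vertex_indices.items()},
        }
        if self.vertex_labels is not None:
            manifest["vertex_labels"] = [str(x) for x in self.vertex_labels]
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh)

    @classmethod
    def load(cls, indir) -> "CorrespondenceSet":
        import json
        from pathlib import Path

        indir = Path(indir)
        shapes = np.loadtxt(indir / "shapes.tsv", delimiter="\t", ndmin=2)
        faces = np.loadtxt(indir / "faces.tsv", delimiter="\t", dtype=np.int64, ndmin=2)
        with open(indir / "manifest.json") as fh:
            manifest = json.load(fh)
        labels = manifest.get("vertex_labels")
        return cls(
            faces,
            shapes,
            manifest["sample_ids"],
            np.array(manifest["residuals"]),
            np.array(labels) if labels is not None else None,
            {k: int(v) for k, v in manifest.get("landmark_vertex_indices", {}).items()},
            manifest.get("excluded", []),
        )


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def procrustes_rigid(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform (Kabsch; reflections excluded).

    Minimizes ``sum ||R s_i + t - t_i||^2`` over proper rotations R and
    translations t.  Requires at least three non-collinear point pairs.
    """
    s = np.asarray(source_points, dtype=float)
    t = np.asarray(target_points, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3 or len(s) < 3:
        raise RegistrationError("need matching (k>=3, 3) point arrays")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    for pts, name in ((s0, "source"), (t0, "target")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise RegistrationError(f"{name} points are collinear/degenerate")
    H = s0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


@dataclass
class ICPConfig:
    max_iter: int = 50
    tol_mm: float = 1e-6
    max_pair_dist_mm: float = 25.0


def icp_refine(
    source: TriangleMesh, target: TriangleMesh, init: RigidTransform | None = None, config: ICPConfig | None = None
) -> RigidTransform:
    """Rigid iterative-closest-point refinement of ``init``.

    Pairs source vertices with their closest points on the target surface
    (rejecting pairs farther than ``max_pair_dist_mm``) and re-solves the
    rigid Procrustes problem each iteration; the mean closest-point residual
    is monotone non-increasing.  ``max_iter=0`` returns ``init`` unchanged.
    """
    if source.n_faces == 0 or target.n_faces == 0:
        raise MeshError("ICP requires nonempty meshes")
    init = init or RigidTransform.identity()
    config = config or ICPConfig()
    transform = init
    prev = np.inf
    for _ in range(config.max_iter):
        moved = transform.apply(source.vertices)
        cp, d, _ = closest_points(moved, target)
        keep = d <= config.max_pair_dist_mm
        if keep.sum() < 3:
            raise RegistrationError("no valid point pairs under max_pair_dist_mm")
        step = procrustes_rigid(source.vertices[keep], cp[keep])
        resid = float(d[keep].mean())
        if resid > prev - config.tol_mm:
            break
        transform, prev = step, resid
    return transform


# ---------------------------------------------------------------------------
# non-rigid morph (stiffness-scheduled locally-affine non-rigid ICP)
# ---------------------------------------------------------------------------


@dataclass
class MorphConfig:
    stiffness_schedule: tuple = (50.0, 20.0, 5.0, 2.0)
    inner_iters: int = 10
    tol: float = 1e-3  # mean per-vertex motion (mm) that ends a stiffness level
    max_dist_mm: float = 10.0
    normal_compat_deg: float = 60.0
    gamma: float = 1.0  # weighting of the affine (vs translational) stiffness
    landmark_weight: float = 10.0
    init_anchor_weight: float = 0.005  # weak stay-put prior of the landmark init
    # fraction of the tangential data constraint released per iteration: the
    # data term then pulls mainly along the target normal, so the stiffness
    # term (not the arbitrary tangential position of the closest point) decides
    # where vertices sit on the surface — this is what keeps correspondence
    # from sliding when the target is a smoothly deformed copy of the template
    tangential_release: float = 0.9


class MorphDivergence(RuntimeError):
    """Non-rigid morph residual increased across a full stiffness level."""


def _template_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def nonrigid_morph(
    template: TriangleMesh,
    target: TriangleMesh,
    landmark_pairs: tuple | None = None,
    config: MorphConfig | None = None,
    init_landmark_pairs: tuple | None = None,
):
    """Morph the (rigidly pre-aligned) template onto the target surface.

    Each template vertex carries an affine 4x3 transform; the energy is the
    weighted sum of squared closest-point distances plus a stiffness term
    penalizing transform differences across template edges, solved as a sparse
    linear least-squares problem per iteration.  The output mesh has exactly
    the template's topology.  ``landmark_pairs`` is ``(vertex_indices,
    target_points)`` enforcing soft landmark constraints.

    ``init_landmark_pairs`` selects the landmarks used for the high-stiffness
    initialization (default: all of ``landmark_pairs``).  Landmarks that move
    with the gross deformation belong here; landmarks on locally variable
    features (e.g. the epicondylar prominences) are better left to the data
    phase, because a small landmark set fits their local displacement with a
    spurious global gradient.

    Returns ``(morphed_mesh, mean_surface_residual_mm)``.
    """
    config = config or MorphConfig()
    V = template.n_vertices
    if V < 4 or target.n_faces == 0:
        raise MeshError("morph requires a template with >=4 vertices and a nonempty target")

    edges = _template_edges(template.faces)
    E = len(edges)
    # stiffness matrix M kron G : rows 4E, cols 4V
    g = np.array([1.0, 1.0, 1.0, config.gamma])
    rows = np.repeat(np.arange(4 * E), 2)
    cols = np.empty(8 * E, dtype=np.int64)
    vals = np.empty(8 * E)
    for j in range(4):
        cols[2 * j :: 8] = 4 * edges[:, 0] + j
        cols[2 * j + 1 :: 8] = 4 * edges[:, 1] + j
        vals[2 * j :: 8] = g[j]
        vals[2 * j + 1 :: 8] = -g[j]
    MG = sp.csr_matrix((vals, (rows, cols)), shape=(4 * E, 4 * V))
    K = (MG.T @ MG).tocsc()

    lm_term = None
    if landmark_pairs is not None:
        lm_idx, lm_targets = landmark_pairs
        lm_idx = np.asarray(lm_idx, dtype=np.int64)
        lm_targets = np.asarray(lm_targets, dtype=float)
        DL = _data_matrix(template.vertices, lm_idx, V)
        lm_term = (DL, lm_targets)

    X = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (V, 1))
    target_face_normals = target.face_normals()
    tmpl_tm = template.to_trimesh()
    vert_faces = [np.asarray(f, dtype=np.int64) for f in tmpl_tm.vertex_faces]

    def current_positions(X):
        Xb = X.reshape(V, 4, 3)
        return np.einsum("vi,vij->vj", np.column_stack([template.vertices, np.ones(V)]), Xb)

    def vertex_normals_of(positions):
        tri = positions[template.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(fn, axis=1, keepdims=True)
        fn = fn / np.maximum(nrm, 1e-12)
        vn = np.zeros((V, 3))
        np.add.at(vn, template.faces[:, 0], fn)
        np.add.at(vn, template.faces[:, 1], fn)
        np.add.at(vn, template.faces[:, 2], fn)
        return vn / np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-12)

    cos_gate = np.cos(np.radians(config.normal_compat_deg))
    D_full = _data_matrix(template.vertices, np.arange(V), V)

    if lm_term is not None:
        # landmark-only initialization: at high stiffness the minimizer is the
        # smoothest (for consistent landmarks: globally affine) field through
        # the landmark constraints, which registers the gross deformation
        # before surface closest points are trusted.  Weak stay-put anchors on
        # every vertex bound the deformation gradients the (small, often
        # nearly coplanar) landmark set cannot observe.
        if init_landmark_pairs is not None:
            ii = np.asarray(init_landmark_pairs[0], dtype=np.int64)
            DLi = _data_matrix(template.vertices, ii, V)
            ULi = np.asarray(init_landmark_pairs[1], dtype=float)
        else:
            DLi, ULi = lm_term
        alpha0 = 10.0 * max(config.stiffness_schedule)
        b2 = config.landmark_weight**2
        wa2 = config.init_anchor_weight**2
        Da = _data_matrix(template.vertices, np.arange(V), V)
        A0 = ((alpha0**2) * K + b2 * (DLi.T @ DLi) + wa2 * (Da.T @ Da)).tocsc()
        X = splu(A0).solve(b2 * (DLi.T @ ULi) + wa2 * (Da.T @ template.vertices))

    prev_level_resid = None
    resid = np.inf
    for alpha in config.stiffness_schedule:
        for _ in range(max(config.inner_iters, 1)):
            pos = current_positions(X)
            cp, d, fidx = closest_points(pos, target)
            w = (d <= config.max_dist_mm).astype(float)
            vn = vertex_normals_of(pos)
            compat = np.einsum("ij,ij->i", vn, target_face_normals[fidx]) >= cos_gate
            w *= compat
            if w.sum() < 4:
                raise RegistrationError("morph: no valid correspondences under the gates")
            # release most of the tangential pull: target point = closest point
            # plus a fraction of the in-plane offset of the current position
            tn = target_face_normals[fidx]
            normal_off = np.einsum("ij,ij->i", pos - cp, tn)[:, None] * tn
            u = cp + config.tangential_release * (pos - cp - normal_off)
            W = sp.diags(w)
            A = (alpha**2) * K + (D_full.T @ W @ D_full).tocsc()
            B = D_full.T @ (w[:, None] * u)
            if lm_term is not None:
                DL, UL = lm_term
                b2 = config.landmark_weight**2
                A = A + b2 * (DL.T @ DL).tocsc()
                B = B + b2 * (DL.T @ UL)
            X_new = splu(A.tocsc()).solve(B)
            moved = current_positions(X_new) - pos
            X = X_new
            # position-based convergence: mean vertex motion per iteration
            if float(np.linalg.norm(moved, axis=1).mean()) < config.tol:
                break
        pos = current_positions(X)
        _, d, _ = closest_points(pos, target)
        resid = float(d.mean())
        if prev_level_resid is not None and resid > prev_level_resid + max(1e-6, 0.05 * prev_level_resid):
            raise MorphDivergence(
                f"residual increased across stiffness level {alpha}: "
                f"{prev_level_resid:.6f} -> {resid:.6f} mm"
            )
        prev_level_resid = resid

    morphed = TriangleMesh(current_positions(X), template.faces.copy(), template.vertex_labels)
    return morphed, resid


def _data_matrix(vertices: np.ndarray, idx: np.ndarray, V: int) -> sp.csr_matrix:
    k = len(idx)
    rows = np.repeat(np.arange(k), 4)
    cols = (4 * idx[:, None] + np.arange(4)[None, :]).ravel()
    vals = np.column_stack([vertices[idx], np.ones(k)]).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(k, 4 * V))


# ---------------------------------------------------------------------------
# full correspondence builder
# ---------------------------------------------------------------------------


def build_correspondence_set(
    template: TriangleMesh,
    targets: list,
    template_landmarks: np.ndarray | None = None,
    target_landmarks: list | None = None,
    sample_ids: list | None = None,
    icp_config: ICPConfig | None = None,
    morph_config: MorphConfig | None = None,
    landmark_vertex_indices: dict | None = None,
    strict: bool = True,
    init_landmark_rows=None,
) -> CorrespondenceSet:
    """Rigid-align then morph the template onto every target.

    When landmarks are given (``template_landmarks`` (k,3) and a per-target
    list of matching (k,3) arrays) the rigid stage is landmark Procrustes,
    otherwise centroid-initialized ICP.  ``init_landmark_rows`` selects which
    landmark rows seed the morph initialization (see
    :func:`nonrigid_morph`); default all.  Rows are expressed in template
    space (each target's rigid pose removed).  In strict mode any per-target
    failure aborts; in lenient mode failing targets are recorded in
    ``excluded``.
    """
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    sample_ids = list(sample_ids) if sample_ids is not None else [f"shape_{i:03d}" for i in range(len(targets))]
    use_lms = template_landmarks is not None and target_landmarks is not None
    lm_vidx = None
    lm_voffset = None
    if use_lms:
        template_landmarks = np.asarray(template_landmarks, float)
        from scipy.spatial import cKDTree

        lm_vidx = cKDTree(template.vertices).query(template_landmarks)[1]
        # the constrained template VERTEX sits up to an edge length away from
        # the landmark point; carry that offset onto the target side so the
        # landmark constraints stay mutually consistent (first-order exact
        # for smooth deformations)
        lm_voffset = template.vertices[lm_vidx] - template_landmarks

    rows, residuals, kept_ids, excluded = [], [], [], []
    for i, tgt in enumerate(targets):
        try:
            if use_lms:
                rigid = procrustes_rigid(template_landmarks, np.asarray(target_landmarks[i], float))
            else:
                init = RigidTransform(np.eye(3), tgt.centroid - template.centroid)
                rigid = icp_refine(template, tgt, init, icp_config)
            aligned = template.transformed(rigid.rotation, rigid.translation)
            pairs = None
            init_pairs = None
            if use_lms:
                # the vertex-to-landmark offsets must shrink/grow with the
                # bone, so scale them by the landmark-estimated size ratio
                tl = np.asarray(target_landmarks[i], float)
                src0 = template_landmarks - template_landmarks.mean(axis=0)
                tgt0 = tl - tl.mean(axis=0)
                scale_est = float(np.sqrt((tgt0**2).sum() / (src0**2).sum()))
                lm_targets = tl + scale_est * (lm_voffset @ rigid.rotation.T)
                pairs = (lm_vidx, lm_targets)
                if init_landmark_rows is not None:
                    rows_sel = np.asarray(init_landmark_rows, dtype=np.int64)
                    init_pairs = (lm_vidx[rows_sel], lm_targets[rows_sel])
            morphed, resid = nonrigid_morph(
                aligned, tgt, landmark_pairs=pairs, config=morph_config, init_landmark_pairs=init_pairs
            )
            back = rigid.inverse()
            rows.append(back.apply(morphed.vertices).ravel())
            residuals.append(resid)
            kept_ids.append(sample_ids[i])
        except Exception as exc:  # noqa: BLE001 - surfaced below
            if strict:
                raise RegistrationError(f"correspondence failed for {sample_ids[i]}: {exc}") from exc
            excluded.append({"sample_id": sample_ids[i], "error": str(exc)})
    if not rows:
        raise RegistrationError("all targets failed correspondence")
    return CorrespondenceSet(
        template_faces=template.faces.copy(),
        shapes=np.vstack(rows),
        sample_ids=kept_ids,
        residuals=np.array(residuals),
        vertex_labels=template.vertex_labels,
        landmark_vertex_indices=dict(landmark_vertex_indices or {}),
        excluded=excluded,
    )


def correspondence_from_population(bundles: list, template) -> CorrespondenceSet:
    """Ground-truth correspondence of a phantom population.

    Phantom vertices are displaced template vertices, so the left-sided vertex
    arrays already share the template topology; this bypasses registration and
    is the exact-correspondence oracle for model fitting and quality metrics.
    """
    shapes = np.vstack([b.left_vertices.ravel() for b in bundles])
    return CorrespondenceSet(
        template_faces=template.mesh.faces.copy(),
        shapes=shapes,
        sample_ids=[f"phantom_{i:03d}" for i in range(len(bundles))],
        residuals=np.zeros(len(bundles)),
        vertex_labels=template.mesh.vertex_labels,
        landmark_vertex_indices=dict(template.landmark_vertex_indices),
    )
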