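"""PCA statistical shape model (SSM).

A :class:`StatisticalShapeModel` is built from corresponded shapes (an
``(n, V*3)`` matrix in which every row is one bone on the shared template
topology); ``fit()`` returns a :class:`ShapeModelResults` carrying the mean
shape, the orthonormal modes of variation (principal components), their
variances, and methods to synthesize mode instances (mean +- k SD), project
new shapes to mode scores, and summarize the model.

No size normalization is applied before the PCA: shapes are only rigidly
aligned, so the first mode captures overall size — the dominant variation in
long-bone cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import CorrespondenceSet
from .mesh import TriangleMesh

__all__ = ["StatisticalShapeModel", "ShapeModelResults", "ModeInstance"]


class StatisticalShapeModel:
    """Model object: corresponded training shapes awaiting a PCA fit.

    Parameters
    ----------
    shapes : (n, V*3) array or CorrespondenceSet
        One row per training shape; rows must be rigidly aligned and in
        one-to-one vertex correspondence.
    faces : (F, 3) int array, optional
        Shared template topology (taken from the correspondence set when one
        is given).
    """

    def __init__(self, shapes, faces=None, sample_ids=None, vertex_labels=None, landmark_vertex_indices=None):
        if isinstance(shapes, CorrespondenceSet):
            cs = shapes
            self.shapes = cs.shapes
            self.faces = cs.template_faces
            self.sample_ids = list(cs.sample_ids)
            self.vertex_labels = cs.vertex_labels
            self.landmark_vertex_indices = dict(cs.landmark_vertex_indices)
        else:
            self.shapes = np.asarray(shapes, dtype=float)
            self.faces = np.asarray(faces, dtype=np.int64) if faces is not None else None
            self.sample_ids = list(sample_ids) if sample_ids is not None else list(range(len(self.shapes)))
            self.vertex_labels = vertex_labels
            self.landmark_vertex_indices = dict(landmark_vertex_indices or {})
        if self.shapes.ndim != 2 or len(self.shapes) < 2:
            raise ValueError("need an (n >= 2, V*3) shape matrix")
        if self.shapes.shape[1] % 3 != 0:
            raise ValueError("row length must be a multiple of 3")

    @classmethod
    def from_correspondence(cls, cs: CorrespondenceSet) -> "StatisticalShapeModel":
        return cls(cs)

    def fit(self, variance_floor: float = 1e-12) -> "ShapeModelResults":
        """Fit the PCA via the thin SVD of the centered data matrix.

        Eigenvalues are those of the sample covariance (divisor n-1); modes
        with variance below ``variance_floor`` times the leading variance are
        truncated.  Mode signs are fixed so each mode's largest-magnitude
        entry is positive (PCA signs are otherwise arbitrary).
        """
        X = self.shapes
        n = len(X)
        mean = X.mean(axis=0)
        centered = X - mean
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        variances = s**2 / (n - 1)
        m = min(n - 1, len(variances))
        variances = variances[:m]
        modes = Vt[:m].T
        if variances[0] > 0:
            keep = variances >= variance_floor * variances[0]
            variances, modes = variances[keep], modes[:, keep]
        # deterministic sign convention
        flip = modes[np.abs(modes).argmax(axis=0), np.arange(modes.shape[1])] < 0
        modes[:, flip] *= -1.0
        return ShapeModelResults(
            model=self,
            mean=mean,
            modes=modes,
            variances=variances,
            faces=self.faces,
            n_training=n,
            vertex_labels=self.vertex_labels,
            landmark_vertex_indices=self.landmark_vertex_indices,
        )


@dataclass
class ModeInstance:
    """A synthesized shape: mean + c * sqrt(lambda_k) * mode_k."""

    mode_index: int  # 1-based, as in "PC1"
    sd_multiplier: float
    mesh: TriangleMesh

    @property
    def label(self) -> str:
        sign = "+" if self.sd_multiplier >= 0 else "-"
        return f"PC{self.mode_index} {sign} {abs(self.sd_multiplier):g}SD"


@dataclass
class ShapeModelResults:
    """Fitted SSM: mean shape, orthonormal modes and per-mode variances."""

    model: StatisticalShapeModel
    mean: np.ndarray
    modes: np.ndarray  # (V*3, m), orthonormal columns
    variances: np.ndarray  # (m,), mm^2, descending
    faces: np.ndarray | None
    n_training: int
    vertex_labels: np.ndarray | None = None
    landmark_vertex_indices: dict | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.mean) // 3

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.mean.reshape(-1, 3), self.faces, self.vertex_labels)

    def variance_fractions(self) -> np.ndarray:
        """Per-mode fraction of total variance, in percent (sums to 100)."""
        total = self.variances.sum()
        if total <= 0:
            raise ValueError("model has zero total variance")
        return 100.0 * self.variances / total

    def n_significant_modes(self, threshold_percent: float = 3.0) -> int:
        """Number of leading modes each explaining at least the threshold."""
        frac = self.variance_fractions()
        sig = np.nonzero(frac >= threshold_percent)[0]
        return int(sig[-1] + 1) if len(sig) else 1

    def synthesize(self, k: int, c: float) -> ModeInstance:
        """Instance of mode ``k`` (1-based) at ``c`` standard deviations."""
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode index {k} out of range 1..{self.n_modes}")
        x = self.mean + c * np.sqrt(self.variances[k - 1]) * self.modes[:, k - 1]
        return ModeInstance(k, float(c), TriangleMesh(x.reshape(-1, 3), self.faces, self.vertex_labels))

    def project(self, shape: np.ndarray) -> np.ndarray:
        """Mode scores ``b_k = phi_k^T (x - mean)`` of a corresponded shape."""
        shape = np.asarray(shape, dtype=float).ravel()
        if len(shape) != len(self.mean):
            raise ValueError("shape length does not match the model")
        return self.modes.T @ (shape - self.mean)

    def reconstruct(self, scores: np.ndarray, n_modes: int | None = None) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        m = self.n_modes if n_modes is None else int(n_modes)
        return self.mean + self.modes[:, :m] @ scores[:m]

    def summary(self) -> str:
        frac = self.variance_fractions()
        cum = np.cumsum(frac)
        lines = [
            "Statistical shape model (PCA)",
            "=" * 46,
            f"training shapes : {self.n_training}",
            f"vertices        : {self.n_vertices}",
            f"modes retained  : {self.n_modes}",
            f"total variance  : {self.variances.sum():.4f} mm^2",
            "-" * 46,
            f"{'mode':>4} {'variance':>12} {'percent':>9} {'cumul %':>9}",
        ]
        for k in range(self.n_modes):
            lines.append(f"{k + 1:>4} {self.variances[k]:>12.4f} {frac[k]:>9.2f} {cum[k]:>9.2f}")
        return "\n".join(lines)

    # -- serialization (plain text) ---------------------------------------
    def save(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "mean.tsv", self.mean[None, :], fmt="%.9g", delimiter="\t")
        np.savetxt(outdir / "modes.tsv", self.modes, fmt="%.9g", delimiter="\t")
        np.savetxt(outdir / "variances.tsv", self.variances[None, :], fmt="%.9g", delimiter="\t")
        if self.faces is not None:
            np.savetxt(outdir / "faces.tsv", self.faces, fmt="%d", delimiter="\t")
        meta = {"n_training": self.n_training}
        if self.vertex_labels is not None:
            meta["vertex_labels"] = [str(x) for x in self.vertex_labels]
        if self.landmark_vertex_indices:
            meta["landmark_vertex_indices"] = {k: int(v) for k, v in self.landmark_vertex_indices.items()}
        with open(outdir / "model.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, indir) -> "ShapeModelResults":
        import json
        from pathlib import Path

        indir = Path(indir)
        mean = np.loadtxt(indir / "mean.tsv", delimiter="\t").ravel()
        modes = np.loadtxt(indir / "modes.tsv", delimiter="\t", ndmin=2)
        variances = np.loadtxt(indir / "variances.tsv", delimiter="\t").ravel()
        faces = None
        if (indir / "faces.tsv").exists():
            faces = np.loadtxt(indir / "faces.tsv", delimiter="\t", dtype=np.int64, ndmin=2)
        with open(indir / "model.json") as fh:
            meta = json.load(fh)
        labels = meta.get("vertex_labels")
        dummy = StatisticalShapeModel(np.vstack([mean, mean]), faces)
        return cls(
            model=dummy,
            mean=mean,
            modes=modes,
            variances=variances,
            faces=faces,
            n_training=int(meta["n_training"]),
            vertex_labels=np.array(labels) if labels is not None else None,
            landmark_vertex_indices={k: int(v) for k, v in meta.get("landmark_vertex_indices", {}).items()},
        )

    def export_mode_meshes(self, outdir, k_max: int | None = None, c: float = 3.0) -> list:
        """Write ``pc{k}_{+|-}{c}sd.stl`` meshes for the leading modes."""
        from pathlib import Path

        from .mesh import write_surface

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for k in range(1, (k_max or self.n_modes) + 1):
            for sign in (+1, -1):
                inst = self.synthesize(k, sign * c)
                p = outdir / f"pc{k}_{'+' if sign > 0 else '-'}{c:g}sd.stl"
                write_surface(inst.mesh, p)
                paths.append(p)
        write_surface(self.mean_mesh(), outdir / "mean.stl")
        return paths
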