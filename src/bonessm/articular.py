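"""Articular surface difference analysis.

To isolate *shape* change of the articulation (trochlea + capitellum) from
pose, the articular patch of each synthesized mode instance is rigidly
registered onto the mean-model patch using five anatomical landmarks —
rigid only, no scaling, so a pure size mode still shows up as a residual
surface difference.  The unsigned Euclidean point-to-mesh distance is then
taken from every mean-patch vertex to the registered instance surface and
summarized as range / median / mean / SD / RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import ARTICULAR_LANDMARK_NAMES
from .correspondence import procrustes_rigid
from .mesh import MeshError, TriangleMesh, points_to_mesh_distance
from .model import ShapeModelResults

__all__ = [
    "DistanceSummary",
    "extract_articular",
    "register_articular",
    "distance_summary",
    "mode_difference_report",
]


@dataclass
class DistanceSummary:
    """Summary of one-directional point-to-mesh distances (all mm)."""

    d_min: float
    d_max: float
    median: float
    mean: float
    sd: float
    rms: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_min <= self.median <= self.d_max:
            raise ValueError("distance summary ordering violated")
        if self.rms < self.mean - 1e-12:
            raise ValueError("RMS must be >= mean (power-mean inequality)")

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceSummary":
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise ValueError("no distances to summarize")
        sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        return cls(
            d_min=float(d.min()),
            d_max=float(d.max()),
            median=float(np.median(d)),
            mean=float(d.mean()),
            sd=sd,
            rms=float(np.sqrt(np.mean(d**2))),
            n_points=int(len(d)),
        )

    def as_row(self) -> dict:
        """One report row in the standard Range/Median/Mean/SD/RMS layout."""
        return {
            "Range (mm)": f"0 - {self.d_max:.2f}" if self.d_min < 5e-3 else f"{self.d_min:.2f} - {self.d_max:.2f}",
            "Median (mm)": round(self.median, 2),
            "Mean (mm)": round(self.mean, 2),
            "Std Deviation (mm)": round(self.sd, 2),
            "RMS (mm)": round(self.rms, 2),
        }


def extract_articular(mesh: TriangleMesh, label: str = "articular") -> TriangleMesh:
    """Sub-mesh of the labeled articular region (faces fully inside the label)."""
    if mesh.vertex_labels is None:
        raise MeshError("mesh carries no vertex labels")
    vmask = mesh.vertex_labels == label
    if not vmask.any():
        raise MeshError(f"no vertices labeled {label!r}")
    patch = mesh.submesh_from_vertex_mask(vmask)
    if patch.n_faces == 0:
        raise MeshError(f"label {label!r} contains no complete faces")
    return patch


def register_articular(
    moving_patch: TriangleMesh, moving_landmarks: np.ndarray, fixed_landmarks: np.ndarray
) -> TriangleMesh:
    """Rigidly register a patch onto a reference via its five landmarks.

    Only position and orientation are removed — scaling is deliberately kept,
    so size differences remain visible in the distance summary.
    """
    transform = procrustes_rigid(np.asarray(moving_landmarks, float), np.asarray(fixed_landmarks, float))
    return moving_patch.transformed(transform.rotation, transform.translation)


def distance_summary(source_patch: TriangleMesh, target_patch: TriangleMesh) -> DistanceSummary:
    """One-directional unsigned distances from source vertices to the target surface."""
    if source_patch.n_vertices == 0 or target_patch.n_faces == 0:
        raise MeshError("distance summary requires nonempty patches")
    d = points_to_mesh_distance(source_patch.vertices, target_patch)
    return DistanceSummary.from_distances(d)


def per_vertex_distances(source_patch: TriangleMesh, target_patch: TriangleMesh) -> np.ndarray:
    """The raw per-vertex distance field (for heat-map style export)."""
    return points_to_mesh_distance(source_patch.vertices, target_patch)


def mode_difference_report(results: ShapeModelResults, k_max: int | None = None, c: float = 3.0):
    """Distance summaries of mean-vs-(+-c SD) articular surfaces per mode.

    The five registration landmarks are tracked through the correspondence as
    template vertex indices, so they move consistently with every synthesized
    instance.  Returns a pandas DataFrame with one row per (mode, sign) in the
    order PC1+, PC1-, PC2+, ...
    """
    import pandas as pd

    if results.vertex_labels is None:
        raise MeshError("model template carries no articular labels")
    lm_idx = results.landmark_vertex_indices or {}
    missing = [n for n in ARTICULAR_LANDMARK_NAMES if n not in lm_idx]
    if missing:
        raise MeshError(f"template is missing articular registration landmarks: {missing}")
    idx = np.array([lm_idx[n] for n in ARTICULAR_LANDMARK_NAMES], dtype=np.int64)

    k_max = k_max or results.n_modes
    mean_mesh = results.mean_mesh()
    mean_patch = extract_articular(mean_mesh)
    fixed_lms = mean_mesh.vertices[idx]

    rows = []
    labels = []
    for k in range(1, k_max + 1):
        for sign in (+1.0, -1.0):
            inst = results.synthesize(k, sign * c)
            moving_lms = inst.mesh.vertices[idx]
            patch = extract_articular(inst.mesh)
            registered = register_articular(patch, moving_lms, fixed_lms)
            summary = distance_summary(mean_patch, registered)
            rows.append(summary.as_row())
            labels.append(f"PC{k} {'+' if sign > 0 else '-'} {c:g}SD")
    return pd.DataFrame(rows, index=pd.Index(labels, name="model"))
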