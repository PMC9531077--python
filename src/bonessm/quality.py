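"""Shape-model quality metrics: compactness, generalization, specificity, ICC.

Compactness is the cumulative variance fraction against the number of modes;
generalization is the leave-one-out reconstruction error of unseen shapes
(mm, mean per-vertex distance); specificity draws random plausible instances
from the model and reports their average distance to the most similar
training shape.  Because every shape shares the template topology, both error
metrics use the vertex-to-vertex correspondence distance.

The intraclass correlation coefficient ICC(2,1) (two-way random effects,
absolute agreement, single measurement) quantifies rater reliability of
manual steps such as landmark selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .model import ShapeModelResults, StatisticalShapeModel

__all__ = [
    "QualityCurves",
    "compactness",
    "generalization",
    "specificity",
    "icc_absolute_agreement",
]


@dataclass
class QualityCurves:
    """The three SSM quality curves, tabulated against the mode count."""

    compactness_modes: np.ndarray
    compactness: np.ndarray  # cumulative variance fraction (0..1]
    generalization_modes: np.ndarray
    generalization: np.ndarray  # mm
    specificity_modes: np.ndarray
    specificity: np.ndarray  # mm
    settings: dict

    def to_frame(self):
        import pandas as pd

        rows = []
        for kind, ms, vs in (
            ("compactness", self.compactness_modes, self.compactness),
            ("generalization", self.generalization_modes, self.generalization),
            ("specificity", self.specificity_modes, self.specificity),
        ):
            for m, v in zip(ms, vs):
                rows.append({"metric": kind, "n_modes": int(m), "value": float(v)})
        return pd.DataFrame(rows)

    def plot(self, path=None):
        """Three-panel quality figure (compactness / specificity / generalization)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].plot(self.compactness_modes, 100 * self.compactness, "o-")
        axes[0].set_ylabel("cumulative variance (%)")
        axes[0].set_title("Compactness")
        axes[1].plot(self.specificity_modes, self.specificity, "o-")
        axes[1].set_ylabel("distance (mm)")
        axes[1].set_title("Specificity")
        axes[2].plot(self.generalization_modes, self.generalization, "o-")
        axes[2].set_ylabel("error (mm)")
        axes[2].set_title("Generalization")
        for ax in axes:
            ax.set_xlabel("number of modes")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def compactness(results: ShapeModelResults, m_max: int | None = None) -> np.ndarray:
    """Cumulative variance fraction C(m') for m' = 1..m_max (ends at 1)."""
    frac = results.variances / results.variances.sum()
    cum = np.cumsum(frac)
    return cum[: (m_max or len(cum))]


def _mean_vertex_distance(a: np.ndarray, b: np.ndarray) -> float:
    diff = (a - b).reshape(-1, 3)
    return float(np.linalg.norm(diff, axis=1).mean())


def generalization(shapes, m_values=None) -> tuple:
    """Leave-one-out reconstruction error per mode count.

    For each fold the model is refitted on the remaining shapes, the held-out
    shape is projected onto the first m' modes and reconstructed, and the
    error is the mean per-vertex distance.  Returns ``(m_values, mean errors
    over folds)``; ``m'=0`` reconstructs with the fold mean alone.
    """
    from .correspondence import CorrespondenceSet

    if isinstance(shapes, CorrespondenceSet):
        shapes = shapes.shapes
    X = np.asarray(shapes, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out generalization needs at least 3 shapes")
    m_max = n - 2  # a fold of n-1 shapes has at most n-2 modes
    if m_values is None:
        m_values = np.arange(0, m_max + 1)
    m_values = np.asarray(m_values, dtype=int)
    if (m_values > m_max).any():
        raise ValueError(f"m' cannot exceed {m_max} for {n} shapes")

    errors = np.zeros((n, len(m_values)))
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        res = StatisticalShapeModel(rest).fit()
        b = res.project(X[i])
        for j, m in enumerate(m_values):
            rec = res.reconstruct(b, int(m))
            errors[i, j] = _mean_vertex_distance(X[i], rec)
    return m_values, errors.mean(axis=0)


def specificity(
    results: ShapeModelResults,
    training,
    M: int = 1000,
    seed: int = 0,
    m_values=None,
) -> tuple:
    """Mean distance of M model-sampled instances to their nearest training shape.

    Scores are drawn per mode from a normal with the mode's variance,
    truncated at +-3 SD (the plausible-shape range); the same draws feed every
    m' (leading columns), so the curve is internally consistent and
    deterministic under ``seed``.
    """
    from .correspondence import CorrespondenceSet

    if M < 1:
        raise ValueError("M must be >= 1")
    if isinstance(training, CorrespondenceSet):
        training = training.shapes
    T = np.asarray(training, dtype=float)
    m = results.n_modes
    if m_values is None:
        m_values = np.arange(1, m + 1)
    m_values = np.asarray(m_values, dtype=int)
    rng = np.random.default_rng(seed)
    z = truncnorm.rvs(-3.0, 3.0, size=(M, m), random_state=rng)
    scores = z * np.sqrt(results.variances)[None, :]

    V = results.n_vertices
    out = np.zeros(len(m_values))
    for j, mp in enumerate(m_values):
        samples = results.mean[None, :] + scores[:, :mp] @ results.modes[:, :mp].T
        dmin = np.full(M, np.inf)
        chunk = max(1, int(2e7 // (T.size or 1)))
        for s0 in range(0, M, chunk):
            block = samples[s0 : s0 + chunk]  # (c, 3V)
            diff = block[:, None, :].reshape(len(block), 1, V, 3) - T.reshape(1, len(T), V, 3)
            d = np.linalg.norm(diff, axis=3).mean(axis=2)  # (c, n) mean vertex distance
            dmin[s0 : s0 + chunk] = d.min(axis=1)
        out[j] = dmin.mean()
    return m_values, out


def quality_curves(
    results: ShapeModelResults,
    training,
    M: int = 1000,
    seed: int = 0,
    m_values=None,
) -> QualityCurves:
    """Convenience wrapper computing all three curves on one model."""
    comp = compactness(results)
    gm, gv = generalization(training, m_values=m_values)
    sm, sv = specificity(results, training, M=M, seed=seed, m_values=None if m_values is None else m_values[m_values >= 1])
    return QualityCurves(
        compactness_modes=np.arange(1, len(comp) + 1),
        compactness=comp,
        generalization_modes=gm,
        generalization=gv,
        specificity_modes=sm,
        specificity=sv,
        settings={"M_samples": M, "seed": seed},
    )


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is a (targets x raters) matrix with no missing cells.  Computed
    from the two-way ANOVA mean squares; a constant matrix has no defined ICC.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - gm) ** 2).sum()
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        raise ValueError("ICC undefined: ratings matrix has no variance")
    return float((msr - mse) / denom)
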