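"""Principal component ordination of tangent shape coordinates.

Covariance (not correlation) PCA — tangent coordinates share units — with
a-posteriori projection of query specimens that were excluded from the fit.
Axis signs follow a deterministic convention: each axis is oriented so that
its largest-magnitude loading is positive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateShapeError, DimensionError

__all__ = ["PcaModel", "pca_fit", "pca_project"]


@dataclass
class PcaModel:
    """Fitted PCA: mean, orthonormal axes (rows), eigenvalues and their
    fractions of the *total* variance (so dropped near-null axes make the
    retained fractions sum to slightly less than 1)."""

    mean: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    @property
    def r(self) -> int:
        return self.axes.shape[0]


def pca_fit(tangent_coords: np.ndarray, drop_tol: float = 1e-12) -> PcaModel:
    """Eigen-decompose the covariance of rows about their mean.

    Axes with eigenvalue below ``drop_tol`` times the largest are dropped.
    """
    x = np.asarray(tangent_coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DimensionError("pca_fit needs an (n >= 2, p) matrix")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    total = float(eigvals.sum())
    if total <= 0:
        raise DegenerateShapeError("zero total variance: PCA undefined")
    keep = eigvals >= drop_tol * eigvals[0]
    axes = vt[keep]
    eigvals = eigvals[keep]
    # Deterministic sign: largest-magnitude loading positive.
    for i, axis in enumerate(axes):
        j = int(np.argmax(np.abs(axis)))
        if axis[j] < 0:
            axes[i] = -axis
    return PcaModel(
        mean=mean,
        axes=axes,
        eigenvalues=eigvals,
        variance_fractions=eigvals / total,
    )


def pca_project(model: PcaModel, tangent_coords: np.ndarray) -> np.ndarray:
    """Scores of (possibly new) specimens in the fitted PCA space."""
    x = np.atleast_2d(np.asarray(tangent_coords, dtype=float))
    if x.shape[1] != model.mean.shape[0]:
        raise DimensionError(
            f"coordinate dimension {x.shape[1]} does not match model "
            f"({model.mean.shape[0]})"
        )
    return (x - model.mean) @ model.axes.T
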