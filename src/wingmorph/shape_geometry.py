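"""Procrustes superimposition, tangent projection and shape distances.

The module implements the classical generalized least-squares (GLS)
superimposition for 2D landmark configurations: every configuration is
centered, scaled to unit centroid size and rotated (proper rotations only —
reflections are never fitted) onto an iteratively re-estimated consensus.
Aligned shapes live on the unit sphere of Kendall's shape space (pre-shapes
optimally rotated to the consensus); statistics are carried out after an
orthogonal projection onto the Euclidean space tangent to that sphere at the
consensus. The adequacy of the linear approximation is certified by
regressing tangent-space Euclidean distances on pairwise Procrustes
distances, the standard tps-SMALL-style diagnostic.

2D rotations are handled in the complex-number representation: a landmark
configuration is a complex k-vector, a proper rotation is multiplication by a
unit complex scalar, and the optimal rotation of ``z`` onto ``c`` is
``z * w/|w|`` with ``w = Σ conj(z) c``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import DegenerateShapeError, DimensionError, WingmorphError
from .io_landmarks import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "AlignedShapes",
    "AdequacyReport",
    "centroid_size",
    "mirror",
    "optimal_rotation",
    "opa_align",
    "gpa",
    "tangent_project",
    "procrustes_distance_matrix",
    "tangent_adequacy",
]


@dataclass
class AlignedShapes:
    """Superimposed (optionally tangent-projected) landmark coordinates.

    ``aligned`` holds one specimen per row, coordinates interleaved as
    ``x1, y1, ..., xk, yk``. ``consensus`` is the mean shape, centered at the
    origin with unit centroid size. ``centroid_sizes`` are the pre-scaling
    sizes of the raw configurations.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ids: list[str]
    is_tangent: bool = False
    iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1] // 2

    def shapes(self) -> np.ndarray:
        """Aligned coordinates as an (n, k, 2) array."""
        return self.aligned.reshape(self.n, self.k, 2)

    def consensus_shape(self) -> np.ndarray:
        return self.consensus.reshape(self.k, 2)


@dataclass
class AdequacyReport:
    """Tangent-space adequacy diagnostic.

    ``slope`` is the no-intercept least-squares slope of tangent Euclidean
    distances on Procrustes distances; ``correlation`` their Pearson
    coefficient; both near 1 certify that the tangent plane is an adequate
    linear stand-in for the curved shape space at the observed variation.
    """

    slope: float
    correlation: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "correlation": self.correlation,
            "n_pairs": self.n_pairs,
        }


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _coords_of(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    arr = np.asarray(config, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DimensionError(f"expected (k, 2) coordinates, got {arr.shape}")
    return arr


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances to the centroid."""
    coords = _coords_of(config)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size < 1e-300:
        raise DegenerateShapeError("all landmarks coincide: no size or shape")
    return size


def mirror(coords: np.ndarray) -> np.ndarray:
    """Mirror a configuration about the y-axis (for right wings)."""
    out = _coords_of(coords).copy()
    out[:, 0] = -out[:, 0]
    return out


def _center_unit(coords: np.ndarray) -> tuple[np.ndarray, float]:
    coords = _coords_of(coords)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size < 1e-300:
        raise DegenerateShapeError("all landmarks coincide: no size or shape")
    return centered / size, size


def _to_complex(coords: np.ndarray) -> np.ndarray:
    return coords[..., 0] + 1j * coords[..., 1]


def _to_real(z: np.ndarray) -> np.ndarray:
    return np.stack([z.real, z.imag], axis=-1)


def _rotation_angle(z_from: np.ndarray, z_to: np.ndarray) -> float:
    w = np.sum(np.conj(z_from) * z_to)
    if abs(w) < 1e-300:
        return 0.0
    return float(np.angle(w))


def optimal_rotation(moving, target) -> np.ndarray:
    """Proper 2x2 rotation matrix R minimizing ||moving @ R.T - target||.

    Both configurations are taken as given (no centering or scaling);
    reflections are never returned (det R = +1 always).
    """
    a = _coords_of(moving)
    b = _coords_of(target)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    theta = _rotation_angle(_to_complex(a), _to_complex(b))
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def opa_align(target, reference) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of one shape onto another.

    Both configurations are centered and scaled to unit centroid size; the
    target is then rotated (proper rotation) to minimize the summed squared
    distance to the reference. Returns the aligned (k, 2) target and the
    partial Procrustes distance between the two unit-size shapes.
    """
    t = _coords_of(target)
    r = _coords_of(reference)
    if t.shape != r.shape:
        raise DimensionError(f"landmark mismatch: {t.shape} vs {r.shape}")
    tu, _ = _center_unit(t)
    ru, _ = _center_unit(r)
    zt, zr = _to_complex(tu), _to_complex(ru)
    theta = _rotation_angle(zt, zr)
    aligned = _to_real(zt * np.exp(1j * theta))
    dist = float(np.sqrt(np.sum((aligned - ru) ** 2)))
    return aligned, dist


# ---------------------------------------------------------------------------
# Generalized (GLS) superimposition
# ---------------------------------------------------------------------------


def _canonical_orientation(z: np.ndarray, consensus: np.ndarray):
    """Rotate the whole solution into a deterministic orientation.

    The consensus principal axis is aligned with x; of the two such rotations
    the one placing the landmark farthest from the centroid at positive x is
    chosen. Makes GPA output invariant to per-specimen nuisance rotations.
    """
    c = _to_real(consensus)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    phi = np.arctan2(axis[1], axis[0])
    rot = np.exp(-1j * phi)
    c_rot = consensus * rot
    far = int(np.argmax(np.abs(c_rot)))
    if c_rot[far].real < 0:
        rot = -rot
    return z * rot, consensus * rot


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ids: list[str] | None = None,
) -> AlignedShapes:
    """Generalized least-squares Procrustes superimposition.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated onto a consensus that is re-estimated as the rescaled
    arithmetic mean, until the Procrustes distance between successive
    consensuses drops below ``tol``. Non-convergence at ``max_iter`` returns
    a result with ``converged=False`` and a warning, never a silent pass.
    """
    if isinstance(dataset, LandmarkDataset):
        coords = dataset.coords_array()
        ids = dataset.ids
    else:
        coords = np.asarray(dataset, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise DimensionError(f"expected (n, k, 2) array, got {coords.shape}")
        if ids is None:
            ids = [str(i) for i in range(coords.shape[0])]
    n = coords.shape[0]
    if n < 2:
        raise WingmorphError("GPA requires at least 2 configurations")

    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes < 1e-300):
        bad = [ids[i] for i in np.nonzero(sizes < 1e-300)[0]]
        raise DegenerateShapeError(f"degenerate configurations: {bad}")
    z = _to_complex(centered / sizes[:, None, None])

    consensus = z[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w = z @ np.conj(consensus)
        mag = np.abs(w)
        unit = np.where(mag > 1e-300, w / np.where(mag > 0, mag, 1.0), 1.0)
        z = z * np.conj(unit)[:, None]
        new_c = z.mean(axis=0)
        norm = np.abs(np.vdot(new_c, new_c)) ** 0.5
        if norm < 1e-300:
            raise DegenerateShapeError("consensus collapsed to zero")
        new_c = new_c / norm
        # Consensus step as a direct vector norm after optimal rotation;
        # sqrt(2 - 2|<c,c'>|) hits a floating-point floor near sqrt(eps).
        w_c = np.vdot(consensus, new_c)
        phase = w_c / abs(w_c) if abs(w_c) > 0 else 1.0
        step = float(np.linalg.norm(new_c - consensus * phase))
        consensus = new_c
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus step {step:.3e})",
            stacklevel=2,
        )

    z, consensus = _canonical_orientation(z, consensus)
    return AlignedShapes(
        aligned=_to_real(z).reshape(n, -1),
        consensus=_to_real(consensus).reshape(-1),
        centroid_sizes=sizes,
        ids=list(ids),
        is_tangent=False,
        iterations=iterations,
        converged=converged,
    )


def align_to_consensus(aligned: AlignedShapes, coords: np.ndarray) -> np.ndarray:
    """OPA-align extra configurations onto an existing consensus.

    Returns the centered, unit-size, optimally rotated coordinates as rows of
    an (m, 2k) matrix in the orientation of ``aligned``. Used when query
    specimens are kept out of the consensus estimation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    ref = aligned.consensus_shape()
    rows = []
    for c in coords:
        if c.shape != ref.shape:
            raise DimensionError(f"landmark mismatch: {c.shape} vs {ref.shape}")
        row, _ = opa_align(c, ref)
        # opa_align centers/scales the reference too; ref is already unit size
        rows.append(row.reshape(-1))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Tangent space
# ---------------------------------------------------------------------------


def tangent_project(aligned: AlignedShapes) -> AlignedShapes:
    """Orthogonal projection onto the tangent plane at the consensus.

    Each aligned row ``x`` (a 2k-vector on the unit sphere) is mapped to
    ``x - (x·c - 1) c`` where ``c`` is the consensus, i.e. projected onto the
    hyperplane tangent to the sphere at ``c``.
    """
    if aligned.is_tangent:
        raise WingmorphError("shapes are already tangent-projected")
    c = aligned.consensus
    x = aligned.aligned
    proj = x - np.outer(x @ c - 1.0, c)
    return replace(aligned, aligned=proj, is_tangent=True)


def procrustes_distance_matrix(aligned: AlignedShapes) -> np.ndarray:
    """Pairwise partial Procrustes distances between aligned shapes.

    Each pair is re-superimposed optimally (rotation only; both shapes are
    already unit-size), so entries do not depend on the consensus orientation.
    """
    if aligned.is_tangent:
        raise WingmorphError(
            "Procrustes distances are defined on pre-tangent aligned shapes"
        )
    z = _to_complex(aligned.shapes())
    gram = np.abs(np.conj(z) @ z.T)
    d2 = np.clip(2.0 - 2.0 * gram, 0.0, None)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def tangent_adequacy(
    aligned_raw: AlignedShapes, aligned_tangent: AlignedShapes
) -> AdequacyReport:
    """Regress tangent Euclidean distances on Procrustes distances.

    Reports the no-intercept least-squares slope and the Pearson correlation
    over all n(n-1)/2 specimen pairs; both are expected to be close to 1 when
    shape variation is small relative to the curvature of shape space.
    """
    if aligned_raw.is_tangent or not aligned_tangent.is_tangent:
        raise WingmorphError(
            "pass (raw aligned, tangent-projected) shapes in that order"
        )
    if aligned_raw.ids != aligned_tangent.ids:
        raise WingmorphError("the two inputs hold different specimens")
    dmat = procrustes_distance_matrix(aligned_raw)
    iu = np.triu_indices(dmat.shape[0], k=1)
    dp = dmat[iu]
    de = pdist(aligned_tangent.aligned)
    if np.all(dp == 0):
        raise DegenerateShapeError(
            "all pairwise distances are zero: adequacy undefined"
        )
    slope = float(np.sum(dp * de) / np.sum(dp * dp))
    correlation = float(np.corrcoef(dp, de)[0, 1])
    return AdequacyReport(slope=slope, correlation=correlation, n_pairs=len(dp))
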