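"""Linear discriminant analysis of shape coordinates, with leave-one-out
cross-validated hit ratios and Mahalanobis/posterior-probability assignment.

The fit proceeds in two stages. Tangent coordinates are first reduced onto
the PCA basis spanning all of the non-null total variance (superimposition
leaves the data rank-deficient: translation, scale and rotation each remove a
dimension). The generalized symmetric eigenproblem of the between-group
versus pooled within-group covariance is then solved on the reduced scores;
the eigenvectors are scaled so that the pooled within-group covariance of the
discriminant scores is the identity. In that whitened score space the
Euclidean distance from a specimen to a group centroid *is* the Mahalanobis
distance, and Gaussian posterior probabilities follow directly from the
squared distances and the group priors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.special

from .exceptions import DimensionError, WingmorphError

__all__ = [
    "DiscriminantModel",
    "GroupDistances",
    "CrossValidationReport",
    "lda_fit",
    "lda_scores",
    "group_distances",
    "loocv",
]

_RANK_TOL = 1e-10  # relative eigenvalue threshold for the PCA reduction


@dataclass
class DiscriminantModel:
    """Fitted LDA in whitened discriminant-score space.

    ``reducer_basis`` (p x 2k) maps centered tangent coordinates to the
    non-null-variance PCA scores; ``projection`` (d x p) maps those to the
    d <= g-1 discriminant axes, scaled so the pooled within-group covariance
    of training scores is the identity.
    """

    group_labels: list[str]
    projection: np.ndarray
    group_centroids: np.ndarray
    priors: np.ndarray
    reducer_mean: np.ndarray
    reducer_basis: np.ndarray
    eigenvalues: np.ndarray

    @property
    def g(self) -> int:
        return len(self.group_labels)

    @property
    def d(self) -> int:
        return self.projection.shape[0]

    def transform(self, coords: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(coords, dtype=float))
        if x.shape[1] != self.reducer_mean.shape[0]:
            raise DimensionError(
                f"coordinate dimension {x.shape[1]} does not match model "
                f"({self.reducer_mean.shape[0]})"
            )
        return (x - self.reducer_mean) @ self.reducer_basis.T @ self.projection.T


@dataclass
class GroupDistances:
    """Mahalanobis distances and posterior probabilities to every group."""

    group_labels: list[str]
    md: np.ndarray
    pp: np.ndarray
    best: str

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "md": dict(zip(self.group_labels, self.md.tolist())),
            "pp": dict(zip(self.group_labels, self.pp.tolist())),
        }


@dataclass
class CrossValidationReport:
    """Leave-one-out cross-validation summary for one grouping level.

    ``confusion`` rows are original groups, columns predicted groups.
    ``per_group_hr`` is in percent (NaN for groups with no counted folds);
    ``excluded`` lists (specimen_id, reason) for folds that cannot be run,
    i.e. members of singleton groups.
    """

    group_labels: list[str]
    confusion: np.ndarray
    per_group_hr: np.ndarray
    global_hr: float
    excluded: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "group_labels": self.group_labels,
            "confusion": self.confusion.tolist(),
            "per_group_hr": self.per_group_hr.tolist(),
            "global_hr": self.global_hr,
            "excluded": list(self.excluded),
        }


def _resolve_priors(priors, labels_sorted, counts) -> np.ndarray:
    if isinstance(priors, str):
        if priors == "proportional":
            p = counts / counts.sum()
        elif priors == "equal":
            p = np.full(len(labels_sorted), 1.0 / len(labels_sorted))
        else:
            raise WingmorphError(
                f"priors must be 'proportional', 'equal' or a vector, "
                f"got {priors!r}"
            )
    else:
        p = np.asarray(priors, dtype=float)
        if p.shape != (len(labels_sorted),) or np.any(p < 0):
            raise WingmorphError("explicit priors: nonnegative vector, one per group")
        p = p / p.sum()
    return p


def lda_fit(
    tangent_coords: np.ndarray,
    labels,
    priors="proportional",
) -> DiscriminantModel:
    """Fit the linear discriminant model.

    The pooled within-group covariance uses the n - g denominator. Groups
    with a single member are allowed (they contribute a centroid but no
    within-group scatter) and produce a warning. A singular pooled
    within-group covariance after the PCA reduction is an error asking for
    rank inspection rather than a silent ridge fix.
    """
    x = np.asarray(tangent_coords, dtype=float)
    y = np.asarray(labels, dtype=object)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise DimensionError("coords must be (n, p) matching len(labels)")
    group_labels, y_idx = np.unique(y, return_inverse=True)
    g = len(group_labels)
    n = x.shape[0]
    if g < 2:
        raise WingmorphError("need at least 2 groups")
    if n <= g:
        raise WingmorphError("need more specimens than groups for within-group scatter")
    counts = np.bincount(y_idx, minlength=g).astype(float)
    if np.any(counts == 1):
        singletons = [str(group_labels[i]) for i in np.nonzero(counts == 1)[0]]
        warnings.warn(
            f"singleton groups contribute no within-group scatter: {singletons}",
            stacklevel=2,
        )

    # Stage 1: PCA reduction to the non-null total-variance subspace.
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    keep = ev >= _RANK_TOL * ev[0]
    basis = vt[keep]
    t = xc @ basis.T
    p = basis.shape[0]

    # Stage 2: between vs pooled within-group covariance on reduced scores.
    means = np.zeros((g, p))
    np.add.at(means, y_idx, t)
    means /= counts[:, None]
    resid = t - means[y_idx]
    sw = resid.T @ resid / (n - g)
    grand = t.mean(axis=0)
    dev = means - grand
    sb = (dev * counts[:, None]).T @ dev / (n - g)

    w_eig = np.linalg.eigvalsh(sw)
    if w_eig[0] < _RANK_TOL * max(w_eig[-1], 1e-300):
        raise WingmorphError(
            "pooled within-group covariance is singular after the PCA "
            "reduction; inspect group sizes and data rank"
        )
    evals, evecs = scipy.linalg.eigh(sb, sw)
    d = min(g - 1, p)
    order = np.argsort(evals)[::-1][:d]
    w = evecs[:, order]  # (p, d); w.T @ sw @ w = I by eigh normalization
    # Deterministic sign: largest-magnitude coefficient positive.
    for j in range(w.shape[1]):
        i = int(np.argmax(np.abs(w[:, j])))
        if w[i, j] < 0:
            w[:, j] = -w[:, j]

    return DiscriminantModel(
        group_labels=[str(gl) for gl in group_labels],
        projection=w.T,
        group_centroids=means @ w,
        priors=_resolve_priors(priors, group_labels, counts),
        reducer_mean=mean,
        reducer_basis=basis,
        eigenvalues=np.maximum(evals[order], 0.0),
    )


def lda_scores(model: DiscriminantModel, tangent_coords: np.ndarray) -> np.ndarray:
    """Discriminant scores of (possibly new) specimens."""
    return model.transform(tangent_coords)


def group_distances(model: DiscriminantModel, score: np.ndarray) -> GroupDistances:
    """Mahalanobis distance and posterior probability against every group.

    Scores live in the whitened space, so the Euclidean distance to a group
    centroid is the Mahalanobis distance. Posteriors are computed in the log
    domain (log prior - md^2/2, normalized by log-sum-exp), so enormous
    distances underflow gracefully instead of erroring. Exact posterior ties
    are broken lexicographically on the group label.
    """
    score = np.asarray(score, dtype=float).reshape(-1)
    if score.shape[0] != model.d:
        raise DimensionError(
            f"score has dimension {score.shape[0]}, model has {model.d}"
        )
    md = np.linalg.norm(model.group_centroids - score, axis=1)
    logw = np.log(np.where(model.priors > 0, model.priors, 1e-300)) - 0.5 * md**2
    logw -= scipy.special.logsumexp(logw)
    pp = np.exp(logw)
    # argmax returns the first maximum; labels are sorted, so ties resolve
    # lexicographically.
    best = model.group_labels[int(np.argmax(pp))]
    return GroupDistances(
        group_labels=list(model.group_labels), md=md, pp=pp, best=best
    )


def loocv(
    tangent_coords: np.ndarray,
    labels,
    priors="proportional",
    ids: list[str] | None = None,
) -> CrossValidationReport:
    """Leave-one-out cross-validated assignment by maximum posterior.

    Each specimen is held out, the model refitted on the remainder (priors
    policy recomputed), and the held-out specimen assigned by maximum
    posterior probability. Members of singleton groups are recorded under
    ``excluded`` — their group would vanish from the training fold.
    Superimposition is *not* redone per fold; the cross-validation question
    is about the discriminant rule, not the registration.
    """
    x = np.asarray(tangent_coords, dtype=float)
    y = np.asarray(labels, dtype=object)
    group_labels, y_idx = np.unique(y, return_inverse=True)
    g = len(group_labels)
    counts = np.bincount(y_idx, minlength=g)
    label_pos = {str(gl): i for i, gl in enumerate(group_labels)}
    if ids is None:
        ids = [str(i) for i in range(x.shape[0])]

    confusion = np.zeros((g, g), dtype=int)
    excluded: list[tuple[str, str]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton warnings repeat per fold
        for i in range(x.shape[0]):
            if counts[y_idx[i]] == 1:
                excluded.append(
                    (ids[i], f"only member of group {group_labels[y_idx[i]]!r}")
                )
                continue
            mask = np.ones(x.shape[0], dtype=bool)
            mask[i] = False
            try:
                model = lda_fit(x[mask], y[mask], priors=priors)
            except WingmorphError as exc:
                raise WingmorphError(f"LOOCV fold {i} failed: {exc}") from exc
            gd = group_distances(model, lda_scores(model, x[i])[0])
            pred = gd.best
            if pred in label_pos:
                confusion[y_idx[i], label_pos[pred]] += 1

    counted = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = 100.0 * np.diag(confusion) / counted
    per_group = np.where(counted > 0, per_group, np.nan)
    total = counted.sum()
    global_hr = 100.0 * np.trace(confusion) / total if total else float("nan")
    return CrossValidationReport(
        group_labels=[str(gl) for gl in group_labels],
        confusion=confusion,
        per_group_hr=per_group,
        global_hr=float(global_hr),
        excluded=excluded,
    )
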