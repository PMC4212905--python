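"""End-to-end taxonomic assignment of unknown wing configurations.

The pipeline superimposes reference and unknown specimens *jointly* (GLS
superimposition is sampling dependent, so scoring unknowns against a
reference aligned without them would compare coordinates from two different
registrations), tangent-projects everything, then runs one independent
linear discriminant analysis per requested taxonomic level on the reference
rows only. Each unknown is projected a posteriori into every level's
discriminant space and reported with its Mahalanobis distance and posterior
probability against every candidate group. Levels are independent analyses,
not a decision tree; a convenience checker flags reports whose per-level
winners are taxonomically incompatible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discriminant import (
    CrossValidationReport,
    group_distances,
    lda_fit,
    lda_scores,
    loocv,
)
from .exceptions import DimensionError, WingmorphError
from .io_landmarks import LandmarkDataset, labels_for_level
from .shape_geometry import (
    AdequacyReport,
    AlignedShapes,
    align_to_consensus,
    gpa,
    tangent_adequacy,
    tangent_project,
)

__all__ = [
    "LevelAssignment",
    "AssignmentReport",
    "ValidationResult",
    "assign_unknowns",
    "validate_reference",
]


@dataclass
class LevelAssignment:
    """One unknown's distances at one taxonomic level."""

    level: str
    group_labels: list[str]
    md: np.ndarray
    pp: np.ndarray
    best: str

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "best": self.best,
            "md": dict(zip(self.group_labels, self.md.tolist())),
            "pp": dict(zip(self.group_labels, self.pp.tolist())),
        }


@dataclass
class AssignmentReport:
    """Per-level assignment of one unknown specimen, coarse to fine."""

    specimen_id: str
    per_level: list[LevelAssignment]
    notes: dict = field(default_factory=dict)

    def best_by_level(self) -> dict[str, str]:
        return {la.level: la.best for la in self.per_level}

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "per_level": [la.to_dict() for la in self.per_level],
            "notes": dict(self.notes),
        }


@dataclass
class ValidationResult:
    """Reference-set diagnostics: tangent adequacy plus per-level LOOCV."""

    adequacy: AdequacyReport
    per_level: dict[str, CrossValidationReport]

    def to_dict(self) -> dict:
        return {
            "adequacy": self.adequacy.to_dict(),
            "per_level": {lv: r.to_dict() for lv, r in self.per_level.items()},
        }


def _lineage_consistent(
    reference: LandmarkDataset, winners: dict[str, str], levels: list[str]
) -> bool:
    """True when each finer winner nests inside the coarser winner.

    Uses the co-occurrence of labels on reference specimens as the taxonomy.
    """
    order = [lv for lv in reference.level_names if lv in levels]
    for coarse, fine in zip(order, order[1:]):
        coarse_of_fine = set()
        fine_labels = labels_for_level(reference, fine)
        coarse_labels = labels_for_level(reference, coarse)
        for cl, fl in zip(coarse_labels, fine_labels):
            if fl == winners[fine]:
                coarse_of_fine.add(cl)
        if winners[coarse] not in coarse_of_fine:
            return False
    return True


def assign_unknowns(
    reference: LandmarkDataset,
    unknowns: LandmarkDataset,
    levels: list[str] | None = None,
    priors="proportional",
    include_unknowns_in_consensus: bool = True,
) -> list[AssignmentReport]:
    """Assign unknown specimens at each requested taxonomic level.

    One joint superimposition of reference plus unknowns; per level, the LDA
    is fitted on the reference rows only and the unknowns are scored a
    posteriori. Set ``include_unknowns_in_consensus=False`` to estimate the
    consensus from the reference alone and OPA-align the unknowns onto it
    (sensitivity analysis); the policy used is recorded in the report notes.
    """
    if levels is None:
        levels = [lv for lv in reference.level_names if lv != "species"]
    if len(unknowns) == 0:
        return []
    if reference.k != unknowns.k:
        raise DimensionError(
            f"reference has k={reference.k}, unknowns k={unknowns.k}"
        )
    n_ref = len(reference)

    if include_unknowns_in_consensus:
        joint = reference.concat(unknowns)
        aligned = gpa(joint)
        tangent = tangent_project(aligned)
        ref_rows = tangent.aligned[:n_ref]
        unk_rows = tangent.aligned[n_ref:]
        policy = "joint"
    else:
        aligned = gpa(reference)
        unk_aligned = align_to_consensus(aligned, unknowns.coords_array())
        c = aligned.consensus
        tangent = tangent_project(aligned)
        ref_rows = tangent.aligned
        unk_rows = unk_aligned - np.outer(unk_aligned @ c - 1.0, c)
        policy = "reference_only"

    reports = [
        AssignmentReport(
            specimen_id=cfg.specimen_id,
            per_level=[],
            notes={"consensus": policy, "priors": str(priors)},
        )
        for cfg in unknowns
    ]
    for level in levels:
        labels = labels_for_level(reference, level)
        model = lda_fit(ref_rows, labels, priors=priors)
        scores = lda_scores(model, unk_rows)
        for rep, score in zip(reports, scores):
            gd = group_distances(model, score)
            rep.per_level.append(
                LevelAssignment(
                    level=level,
                    group_labels=gd.group_labels,
                    md=gd.md,
                    pp=gd.pp,
                    best=gd.best,
                )
            )
    for rep in reports:
        winners = rep.best_by_level()
        rep.notes["lineage_consistent"] = _lineage_consistent(
            reference, winners, list(winners)
        )
    return reports


def validate_reference(
    reference: LandmarkDataset,
    levels: list[str] | None = None,
    priors="proportional",
) -> ValidationResult:
    """Reference-set diagnostics run on the reference alone.

    Superimposes and tangent-projects the reference (no unknowns — adding
    unlabeled specimens would shift the consensus), computes the tangent
    adequacy regression, and a leave-one-out cross-validation at each level.
    """
    if levels is None:
        levels = [lv for lv in reference.level_names if lv != "species"]
    if any(cfg.is_unknown for cfg in reference):
        raise WingmorphError("validation reference must not contain unknowns")
    aligned = gpa(reference)
    tangent = tangent_project(aligned)
    adequacy = tangent_adequacy(aligned, tangent)
    per_level = {}
    for level in levels:
        labels = labels_for_level(reference, level)
        per_level[level] = loocv(
            tangent.aligned, labels, priors=priors, ids=reference.ids
        )
    return ValidationResult(adequacy=adequacy, per_level=per_level)
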