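"""Hierarchically structured synthetic wing-landmark datasets.

The generator emulates the statistical structure of a multi-family wing
morphometrics reference collection: a nested taxonomy (suprafamily, family,
subfamily, tribe, species), between-group shape effects that shrink going
down the hierarchy, individual/digitization landmark noise, and arbitrary
similarity-transform nuisance (rotation, scale, translation) per specimen.
Ground truth — every specimen's lineage and every group's true mean shape —
is returned alongside, so recovery of known structure can be scored at every
pipeline stage.

Group effects are drawn as i.i.d. Gaussian landmark displacements and
orthogonalized against translation and scaling of the template, so the
specified standard deviations are interpretable as *shape* displacements (in
units of centroid size), commensurate with the pipeline's tangent space.
Randomness is derived by stable hashing of the taxon path, so adding a taxon
never perturbs another taxon's draws.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateShapeError, WingmorphError
from .io_landmarks import DEFAULT_LEVELS, LandmarkConfiguration, LandmarkDataset

__all__ = [
    "WING_TEMPLATE",
    "DEFAULT_EFFECT_SD",
    "Taxonomy",
    "Nuisance",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "make_unknowns",
]

#: 18 landmarks sketching the vein intersections of an elongate bee-like
#: forewing (arbitrary units; fixture, not a digitized specimen).
WING_TEMPLATE = np.array(
    [
        [0.0, 1.8],
        [1.8, 2.6],
        [2.6, 1.9],
        [3.4, 2.9],
        [4.6, 3.0],
        [5.9, 3.1],
        [7.6, 2.8],
        [3.9, 2.2],
        [5.0, 2.4],
        [6.1, 2.5],
        [4.3, 1.6],
        [5.5, 1.8],
        [6.6, 2.0],
        [2.9, 1.1],
        [4.8, 0.9],
        [6.3, 1.2],
        [1.9, 0.5],
        [3.6, 0.2],
    ]
)

#: Per-level shape-effect standard deviations (units of centroid size),
#: decreasing down the hierarchy.
DEFAULT_EFFECT_SD = {
    "suprafamily": 0.009,
    "family": 0.0036,
    "subfamily": 0.0031,
    "tribe": 0.0027,
    "species": 0.0015,
}


@dataclass
class Taxonomy:
    """Counts per nesting level; the default sizes the dataset like a broad
    multi-family reference collection (~640 specimens, 40 tribes, 16
    specimens per tribe, capped at 20 per tribe)."""

    suprafamilies: int = 2
    families_per_suprafamily: int = 5
    subfamilies_per_family: int = 2
    tribes_per_subfamily: int = 2
    species_per_tribe: int = 4
    specimens_per_species: int = 4
    max_specimens_per_tribe: int = 20

    def __post_init__(self) -> None:
        for name in (
            "suprafamilies",
            "families_per_suprafamily",
            "subfamilies_per_family",
            "tribes_per_subfamily",
            "species_per_tribe",
            "specimens_per_species",
        ):
            if getattr(self, name) < 1:
                raise WingmorphError(f"taxonomy count {name} must be >= 1")
        per_tribe = self.species_per_tribe * self.specimens_per_species
        if per_tribe > self.max_specimens_per_tribe:
            raise WingmorphError(
                f"{per_tribe} specimens per tribe exceeds the cap of "
                f"{self.max_specimens_per_tribe}"
            )

    @property
    def n_specimens(self) -> int:
        return (
            self.suprafamilies
            * self.families_per_suprafamily
            * self.subfamilies_per_family
            * self.tribes_per_subfamily
            * self.species_per_tribe
            * self.specimens_per_species
        )


@dataclass
class Nuisance:
    """Similarity-transform nuisance ranges applied per specimen."""

    rotation_range: tuple[float, float] = (0.0, 2.0 * math.pi)
    log_scale_sd: float = 0.3
    translation_range: tuple[float, float] = (-5.0, 5.0)

    @classmethod
    def none(cls) -> "Nuisance":
        return cls((0.0, 0.0), 0.0, (0.0, 0.0))


@dataclass
class SyntheticSpec:
    """Full parameterization of the hierarchical wing simulator."""

    template: np.ndarray = field(default_factory=lambda: WING_TEMPLATE.copy())
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    effect_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SD)
    )
    noise_sd: float = 0.004
    nuisance: Nuisance = field(default_factory=Nuisance)
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.noise_sd < 0 or any(v < 0 for v in self.effect_sd.values()):
            raise WingmorphError("standard deviations must be nonnegative")


@dataclass
class GroundTruth:
    """True labels, group mean shapes and realized effect vectors."""

    labels: dict[str, dict[str, str]]
    mean_shapes: dict[str, dict[str, np.ndarray]]
    effects: dict[str, np.ndarray]
    unknown_lineages: dict[str, dict[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RNG plumbing: stable per-path sub-streams
# ---------------------------------------------------------------------------


def _rng(seed: int, *path: str) -> np.random.Generator:
    digest = hashlib.blake2b(
        ("/".join([str(seed), *path])).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


def _unit_template(template: np.ndarray) -> np.ndarray:
    centered = template - template.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size < 1e-300:
        raise DegenerateShapeError("degenerate template")
    return centered / size


def _shape_effect(rng: np.random.Generator, sd: float, t0: np.ndarray) -> np.ndarray:
    """i.i.d. landmark displacements orthogonalized against translation and
    scaling of the unit template ``t0``."""
    v = rng.normal(0.0, sd, t0.shape)
    v -= v.mean(axis=0)
    v -= float(np.sum(v * t0)) * t0  # t0 has unit norm
    return v


def _apply_nuisance(
    coords: np.ndarray, nuisance: Nuisance, rng: np.random.Generator
) -> np.ndarray:
    theta = rng.uniform(*nuisance.rotation_range)
    log_s = rng.normal(0.0, nuisance.log_scale_sd) if nuisance.log_scale_sd else 0.0
    shift = rng.uniform(*nuisance.translation_range, size=2)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return coords @ rot.T * math.exp(log_s) + shift


def generate(spec: SyntheticSpec) -> tuple[LandmarkDataset, GroundTruth]:
    """Simulate a labeled reference dataset; deterministic given the seed."""
    t0 = _unit_template(spec.template)
    tax = spec.taxonomy
    sd = {lv: spec.effect_sd.get(lv, 0.0) for lv in DEFAULT_LEVELS}

    configs: list[LandmarkConfiguration] = []
    truth = GroundTruth(labels={}, mean_shapes={lv: {} for lv in DEFAULT_LEVELS}, effects={})

    def descend(level_idx: int, path: list[str], mean: np.ndarray) -> None:
        level = DEFAULT_LEVELS[level_idx]
        counts = {
            "suprafamily": tax.suprafamilies,
            "family": tax.families_per_suprafamily,
            "subfamily": tax.subfamilies_per_family,
            "tribe": tax.tribes_per_subfamily,
            "species": tax.species_per_tribe,
        }
        short = {"suprafamily": "SF", "family": "F", "subfamily": "S",
                 "tribe": "T", "species": "sp"}[level]
        for i in range(1, counts[level] + 1):
            name = f"{path[-1]}.{short}{i}" if path else f"SF{i}"
            lineage = path + [name]
            eff = _shape_effect(_rng(spec.seed, "effect", name), sd[level], t0)
            gmean = mean + eff
            truth.effects[name] = eff
            truth.mean_shapes[level][name] = gmean
            if level == "species":
                _emit_specimens(name, lineage, gmean)
            else:
                descend(level_idx + 1, lineage, gmean)

    def _emit_specimens(species: str, lineage: list[str], gmean: np.ndarray) -> None:
        for j in range(1, tax.specimens_per_species + 1):
            sid = f"{species}.{j:02d}"
            noise = _rng(spec.seed, "noise", sid).normal(0.0, spec.noise_sd, t0.shape)
            coords = _apply_nuisance(
                gmean + noise, spec.nuisance, _rng(spec.seed, "nuisance", sid)
            )
            labels = dict(zip(DEFAULT_LEVELS, lineage))
            configs.append(
                LandmarkConfiguration(specimen_id=sid, coords=coords, labels=labels)
            )
            truth.labels[sid] = labels

    descend(0, [], t0)
    return LandmarkDataset(configs, DEFAULT_LEVELS), truth


def make_unknowns(
    spec: SyntheticSpec,
    truth: GroundTruth,
    n_unknowns: int = 4,
    from_level: str = "tribe",
    holdout: bool = True,
    seed: int = 0,
) -> LandmarkDataset:
    """Draw unknown-flagged query specimens from known lineages.

    With ``holdout`` (default), each unknown comes from a *fresh* species
    effect inside the chosen group — a species the reference has never seen —
    drawn with the same noise model; otherwise it is drawn from one of the
    existing species means. True lineages are recorded in
    ``truth.unknown_lineages`` for recovery scoring.
    """
    if from_level not in truth.mean_shapes or not truth.mean_shapes[from_level]:
        raise WingmorphError(f"no groups generated at level {from_level!r}")
    if holdout and from_level == "tribe" and spec.taxonomy.species_per_tribe < 2:
        raise WingmorphError(
            "holdout species requested but each tribe has a single species"
        )
    t0 = _unit_template(spec.template)
    groups = sorted(truth.mean_shapes[from_level])
    rng = _rng(seed, "unknown-pick")
    chosen = [
        groups[i]
        for i in rng.choice(
            len(groups), size=n_unknowns, replace=n_unknowns > len(groups)
        )
    ]
    level_idx = DEFAULT_LEVELS.index(from_level)
    configs = []
    for u, gname in enumerate(chosen, start=1):
        base = truth.mean_shapes[from_level][gname]
        if holdout:
            finer = DEFAULT_LEVELS[min(level_idx + 1, len(DEFAULT_LEVELS) - 1)]
            eff = _shape_effect(
                _rng(seed, "unknown-effect", gname, str(u)),
                spec.effect_sd.get(finer, 0.0),
                t0,
            )
            base = base + eff
        else:
            members = sorted(
                name
                for name in truth.mean_shapes["species"]
                if name.startswith(gname + ".")
            )
            if members:
                pick = _rng(seed, "unknown-member", gname, str(u))
                base = truth.mean_shapes["species"][
                    members[int(pick.integers(len(members)))]
                ]
        sid = f"unknown{u}"
        noise = _rng(seed, "unknown-noise", sid).normal(0.0, spec.noise_sd, t0.shape)
        coords = _apply_nuisance(
            base + noise, spec.nuisance, _rng(seed, "unknown-nuisance", sid)
        )
        configs.append(
            LandmarkConfiguration(specimen_id=sid, coords=coords, is_unknown=True)
        )
        parts = gname.split(".")
        truth.unknown_lineages[sid] = {
            DEFAULT_LEVELS[i]: ".".join(parts[: i + 1])
            for i in range(level_idx + 1)
        }
    return LandmarkDataset(configs, DEFAULT_LEVELS)
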