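"""Reading and writing 2D landmark datasets.

Two on-disk dialects are supported: the TPS text format of the tps software
family (``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=`` records) and a delimited
table with one specimen per row and coordinate columns ``x1,y1,...,xk,yk``.
Every specimen carries an identifier, an optional subset of nested taxonomy
labels (suprafamily, family, subfamily, tribe, species) and an ``is_unknown``
flag marking query specimens (e.g. fossils) that take part in superimposition
but never in model fitting.

Coordinates are stored exactly as digitized, y-up Cartesian; the ``SCALE``
factor of a TPS record is recorded but never applied implicitly (generalized
Procrustes superimposition removes scale anyway, and silent rescaling would
change centroid sizes).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DimensionError, LandmarkParseError, WingmorphError

#: Canonical taxonomy level names, coarsest to finest.
DEFAULT_LEVELS: tuple[str, ...] = (
    "suprafamily",
    "family",
    "subfamily",
    "tribe",
    "species",
)


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks plus its identity and labels.

    Parameters
    ----------
    specimen_id : str
        Unique, non-empty specimen identifier.
    coords : (k, 2) ndarray
        Landmark coordinates in digitizing units, k >= 3.
    scale : float
        Physical units per coordinate unit as recorded in the source file
        (1.0 when absent). Never applied implicitly.
    labels : dict
        Mapping from level name to taxon label; any subset of levels.
    is_unknown : bool
        True for query specimens (fossils) without a priori labels.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float = 1.0
    labels: dict[str, str] = field(default_factory=dict)
    is_unknown: bool = False

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise WingmorphError("specimen_id must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DimensionError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise DimensionError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks"
            )
        if not np.all(np.isfinite(self.coords)):
            raise WingmorphError(
                f"specimen {self.specimen_id!r}: non-finite coordinate"
            )
        if not (self.scale > 0):
            raise WingmorphError(
                f"specimen {self.specimen_id!r}: scale must be positive"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """An ordered collection of configurations sharing a landmark count."""

    configurations: list[LandmarkConfiguration]
    level_names: tuple[str, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        self.configurations = list(self.configurations)
        self.level_names = tuple(self.level_names)
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise DimensionError(
                f"inconsistent landmark counts across dataset: {sorted(ks)}"
            )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise WingmorphError(f"duplicate specimen ids: {dupes}")

    @property
    def k(self) -> int:
        if not self.configurations:
            raise WingmorphError("empty dataset has no landmark count")
        return self.configurations[0].k

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def concat(self, other: "LandmarkDataset") -> "LandmarkDataset":
        """Concatenate two datasets (same k, disjoint ids, same levels)."""
        return LandmarkDataset(
            self.configurations + list(other.configurations), self.level_names
        )

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset(
            [self.configurations[i] for i in indices], self.level_names
        )


def labels_for_level(
    dataset: LandmarkDataset, level: str, fallback: bool = True
) -> np.ndarray:
    """Grouping labels of the non-query specimens at a taxonomic level.

    A specimen missing a fine-level label inherits its nearest coarser label
    when ``fallback`` is true (the rule used for groups, like subfamilies
    without defined tribes, that serve as their own finer-level group).
    Raises for labelled-reference specimens with no usable label, naming them.
    """
    if level not in dataset.level_names:
        raise WingmorphError(
            f"unknown level {level!r}; dataset levels are {dataset.level_names}"
        )
    order = list(dataset.level_names)
    idx = order.index(level)
    out: list[str] = []
    missing: list[str] = []
    for cfg in dataset:
        if cfg.is_unknown:
            continue
        label = cfg.labels.get(level)
        if label is None and fallback:
            for coarser in reversed(order[:idx]):
                label = cfg.labels.get(coarser)
                if label is not None:
                    break
        if label is None:
            missing.append(cfg.specimen_id)
        else:
            out.append(label)
    if missing:
        raise WingmorphError(
            f"specimens without a usable label at level {level!r}: {missing}"
        )
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^\s*([A-Za-z_]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS landmark file.

    Accepts ``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=`` keys (case-insensitive).
    ``CURVES``/``POINTS`` outline blocks are skipped with a warning — only
    fixed landmarks are analysed. Specimen ids default to IMAGE, then ID,
    then the running record index.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    records: list[dict] = []
    current: dict | None = None
    skip_curve_points = 0
    record_no = 0

    def finalize(rec: dict | None) -> None:
        if rec is None:
            return
        if len(rec["coords"]) != rec["lm"]:
            raise LandmarkParseError(
                f"record {rec['index']}: LM={rec['lm']} but "
                f"{len(rec['coords'])} coordinate lines found"
            )
        records.append(rec)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _TPS_KEY.match(line)
        if m:
            key = m.group(1).upper()
            value = m.group(2)
            if key == "LM":
                finalize(current)
                record_no += 1
                try:
                    lm = int(value)
                except ValueError:
                    raise LandmarkParseError(
                        f"line {lineno}: invalid LM count {value!r}"
                    ) from None
                current = {
                    "index": record_no,
                    "lm": lm,
                    "coords": [],
                    "id": None,
                    "image": None,
                    "scale": 1.0,
                }
                skip_curve_points = 0
            elif current is None:
                raise LandmarkParseError(
                    f"line {lineno}: {key}= before any LM= record"
                )
            elif key == "ID":
                current["id"] = value
            elif key == "IMAGE":
                current["image"] = value
            elif key == "SCALE":
                try:
                    current["scale"] = float(value)
                except ValueError:
                    raise LandmarkParseError(
                        f"line {lineno}: invalid SCALE {value!r}"
                    ) from None
            elif key in ("CURVES", "POINTS"):
                if key == "CURVES":
                    warnings.warn(
                        f"record {current['index']}: ignoring CURVES outline "
                        "block (landmark analysis only)",
                        stacklevel=2,
                    )
                skip_curve_points = int(value) if key == "POINTS" else 0
            else:
                # Unknown key: tolerated, ignored.
                pass
            continue
        # Coordinate (or curve-point) line.
        if current is None:
            raise LandmarkParseError(
                f"line {lineno}: coordinates before any LM= record"
            )
        if skip_curve_points > 0:
            skip_curve_points -= 1
            continue
        parts = line.split()
        if len(parts) != 2:
            raise LandmarkParseError(
                f"line {lineno}: expected 'x y', got {line!r}"
            )
        try:
            xy = (float(parts[0]), float(parts[1]))
        except ValueError:
            raise LandmarkParseError(
                f"line {lineno}: non-numeric coordinate {line!r}"
            ) from None
        if len(current["coords"]) >= current["lm"]:
            raise LandmarkParseError(
                f"record {current['index']}: more than LM={current['lm']} "
                f"coordinate lines (line {lineno})"
            )
        current["coords"].append(xy)
    finalize(current)

    configs = []
    for rec in records:
        sid = rec["image"] or rec["id"] or str(rec["index"])
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coords=np.asarray(rec["coords"], dtype=float),
                scale=rec["scale"],
            )
        )
    return LandmarkDataset(configs)


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------


def _coordinate_columns(k: int) -> list[str]:
    cols: list[str] = []
    for i in range(1, k + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def read_table(
    path: str | Path,
    id_column: str = "specimen_id",
    label_columns: Mapping[str, str] | None = None,
    level_names: Sequence[str] = DEFAULT_LEVELS,
) -> LandmarkDataset:
    """Read a delimited (CSV) landmark table, one specimen per row.

    Coordinate columns follow the ``x1,y1,...,xk,yk`` convention. Label
    columns default to any of ``level_names`` present in the header;
    ``label_columns`` maps level name -> column name to override. Row order
    is preserved and rows are never deduplicated.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    coord_cols = [c for c in df.columns if re.fullmatch(r"[xy]\d+", c)]
    if len(coord_cols) % 2 != 0:
        raise DimensionError(
            f"odd number of coordinate columns ({len(coord_cols)})"
        )
    k = len(coord_cols) // 2
    if k == 0:
        raise DimensionError("no coordinate columns (x1, y1, ...) found")
    ordered = _coordinate_columns(k)
    missing_cols = [c for c in ordered if c not in df.columns]
    if missing_cols:
        raise DimensionError(f"missing coordinate columns: {missing_cols}")

    if label_columns is None:
        label_columns = {lv: lv for lv in level_names if lv in df.columns}

    configs = []
    for row_no, row in df.iterrows():
        xy = row[ordered]
        if xy.isna().any():
            bad = xy.index[xy.isna()][0]
            raise WingmorphError(
                f"row {row_no}: missing coordinate in column {bad!r}"
            )
        coords = xy.to_numpy(dtype=float).reshape(k, 2)
        labels = {}
        for level, col in label_columns.items():
            val = row.get(col)
            if pd.notna(val) and str(val) != "":
                labels[level] = str(val)
        sid = str(row[id_column]) if id_column in df.columns else str(row_no)
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coords=coords,
                scale=float(row["scale"]) if "scale" in df.columns else 1.0,
                labels=labels,
                is_unknown=bool(row["is_unknown"])
                if "is_unknown" in df.columns
                else False,
            )
        )
    return LandmarkDataset(configs, tuple(level_names))


def write_table(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as a CSV table re-readable by :func:`read_table`.

    Coordinates survive the round trip bit-exactly (shortest-repr floats).
    """
    if not dataset.configurations:
        raise WingmorphError("refusing to write an empty dataset")
    k = dataset.k
    rows = []
    for cfg in dataset:
        row: dict[str, object] = {
            "specimen_id": cfg.specimen_id,
            "is_unknown": cfg.is_unknown,
            "scale": cfg.scale,
        }
        for level in dataset.level_names:
            if level in cfg.labels:
                row[level] = cfg.labels[level]
        for i in range(k):
            row[f"x{i + 1}"] = cfg.coords[i, 0]
            row[f"y{i + 1}"] = cfg.coords[i, 1]
        rows.append(row)
    label_cols = [
        lv for lv in dataset.level_names if any(lv in c.labels for c in dataset)
    ]
    columns = ["specimen_id", "is_unknown", "scale", *label_cols]
    columns += _coordinate_columns(k)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
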