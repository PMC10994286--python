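"""Visual-field containers and dataset I/O.

A visual field is a vector of differential light sensitivity thresholds in
decibels (dB), one per test location of a :class:`~sorsvf.grid.GridSpec`.
Datasets hold many fields column-wise together with an eye identifier per
field, so that cross-validation can split by eye (repeated visits of one
eye never straddle a train/test boundary).

Two CSV dialects are supported:

``wide``
    one row per field; columns ``eye_id``, optional ``laterality`` and
    ``md``, and one threshold column per location named ``db_<x>_<y>``
    (coordinates in the eye's own convention).

``long``
    one row per (field, location); columns ``eye_id``, optional ``visit``
    and ``laterality``, plus ``x``, ``y``, ``db``.

Left-eye (OS) fields are mirrored into right-eye (OD) convention on load
(x -> -x); all in-memory data is OD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, build_24_2_grid

logger = logging.getLogger(__name__)

DB_MIN = 0.0
DB_MAX = 40.0


class FieldFormatError(ValueError):
    """A dataset file is missing required columns or malformed."""


class FieldRecordError(ValueError):
    """A single field record is invalid (wrong locations, out of range)."""


@dataclass
class VisualField:
    """One field: 54 dB thresholds in grid order, OD convention."""

    values: np.ndarray
    eye_id: str = ""
    laterality: str = "OD"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (54,):
            raise FieldRecordError(
                f"field {self.eye_id!r}: expected 54 values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FieldRecordError(f"field {self.eye_id!r}: non-finite thresholds")


def mirror_values(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Reflect a field left-right (x -> -x) on the grid.

    Used to map OS fields into OD convention.  Applying it twice is the
    identity.  The 24-2 grid is not left-right symmetric (nasal extension),
    so mirroring maps location (x, y) to (-x, y) where that location
    exists and leaves the unmatched nasal-extension/temporal-edge pair in
    place.
    """
    out = np.array(values, dtype=float)
    done = set()
    for i, (x, y) in enumerate(grid.locations):
        if i in done:
            continue
        try:
            j = grid.index_of(-x, y)
        except KeyError:
            continue
        out[i], out[j] = values[j], values[i]
        done.update((i, j))
    return out


@dataclass
class FieldDataset:
    """A 54 x N matrix of thresholds with per-field eye identifiers."""

    X: np.ndarray
    eye_ids: list[str]
    grid: GridSpec = field(default_factory=build_24_2_grid)
    md: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.grid.n_locations:
            raise FieldFormatError(
                f"X must be {self.grid.n_locations} x N, got {self.X.shape}"
            )
        if self.X.shape[1] != len(self.eye_ids):
            raise FieldFormatError("eye_ids length must equal the number of fields")

    @property
    def n_fields(self) -> int:
        return self.X.shape[1]

    @property
    def n_eyes(self) -> int:
        return len(set(self.eye_ids))

    def field(self, j: int) -> VisualField:
        return VisualField(self.X[:, j].copy(), eye_id=self.eye_ids[j])

    def subset(self, cols) -> "FieldDataset":
        cols = np.asarray(cols)
        return FieldDataset(
            X=self.X[:, cols],
            eye_ids=[self.eye_ids[j] for j in cols],
            grid=self.grid,
            md=None if self.md is None else self.md[cols],
        )


def _clip_logged(values: np.ndarray, label: str) -> np.ndarray:
    clipped = np.clip(values, DB_MIN, DB_MAX)
    n = int(np.sum(clipped != values))
    if n:
        logger.info("%s: clipped %d threshold(s) into [%g, %g] dB", label, n, DB_MIN, DB_MAX)
    return clipped


def _wide_columns(grid: GridSpec) -> list[str]:
    return [f"db_{x}_{y}" for x, y in grid.locations]


def load_dataset(path, dialect: str = "wide", grid: GridSpec | None = None) -> FieldDataset:
    """Read a CSV of visual fields, mirroring OS fields to OD convention.

    Parameters
    ----------
    path : str or path-like
    dialect : {"wide", "long"}
    """
    grid = grid or build_24_2_grid()
    if dialect == "wide":
        return _load_wide(path, grid)
    if dialect == "long":
        return _load_long(path, grid)
    raise ValueError(f"unknown dialect {dialect!r}")


def _finish_field(vals: np.ndarray, laterality: str, label: str, grid: GridSpec) -> np.ndarray:
    if laterality == "OS":
        vals = mirror_values(vals, grid)
        logger.debug("%s: mirrored OS field into OD convention", label)
    return _clip_logged(vals, label)


def _load_wide(path, grid: GridSpec) -> FieldDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _wide_columns(grid)
    missing = [c for c in cols if c not in df.columns]
    if "eye_id" not in df.columns or missing:
        raise FieldFormatError(
            f"wide CSV must have 'eye_id' and 54 db_<x>_<y> columns; missing: "
            f"{['eye_id'] * ('eye_id' not in df.columns) + missing[:5]}"
        )
    columns, ids = [], []
    for _, row in df.iterrows():
        lat = str(row.get("laterality", "OD"))
        vals = row[cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise FieldRecordError(f"eye {row['eye_id']}: missing/non-finite thresholds")
        columns.append(_finish_field(vals, lat, f"eye {row['eye_id']}", grid))
        ids.append(str(row["eye_id"]))
    md = df["md"].to_numpy(dtype=float) if "md" in df.columns else None
    return FieldDataset(np.column_stack(columns), ids, grid=grid, md=md)


def _load_long(path, grid: GridSpec) -> FieldDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"eye_id", "x", "y", "db"}
    if not required.issubset(df.columns):
        raise FieldFormatError(f"long CSV must have columns {sorted(required)}")
    keys = ["eye_id"] + (["visit"] if "visit" in df.columns else [])
    columns, ids = [], []
    for key, g in df.groupby(keys, sort=True):
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        got = {(int(r.x), int(r.y)): float(r.db) for r in g.itertuples()}
        want = set(grid.locations)
        if set(got) != want:
            missing = sorted(want - set(got))
            extra = sorted(set(got) - want)
            raise FieldRecordError(
                f"record {label}: expected 54 grid locations; "
                f"missing {missing[:4]}, unexpected {extra[:4]}"
            )
        vals = np.array([got[p] for p in grid.locations])
        lat = str(g["laterality"].iloc[0]) if "laterality" in g.columns else "OD"
        columns.append(_finish_field(vals, lat, f"record {label}", grid))
        ids.append(str(key[0] if isinstance(key, tuple) else key))
    return FieldDataset(np.column_stack(columns), ids, grid=grid)


def write_dataset(dataset: FieldDataset, path, dialect: str = "wide") -> None:
    """Write a dataset to CSV (OD convention; round-trips with load_dataset)."""
    if dialect != "wide":
        raise ValueError("only the wide dialect is written")
    cols = _wide_columns(dataset.grid)
    df = pd.DataFrame(dataset.X.T, columns=cols)
    df.insert(0, "eye_id", dataset.eye_ids)
    df.insert(1, "laterality", "OD")
    if dataset.md is not None:
        df["md"] = dataset.md
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
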