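"""Core geometric types and file I/O for contour shape analysis.

Coordinate convention: right-handed x-y plane (no image-row flipping).
Contours are cyclic point sequences: index ``m`` is identified with index 0,
so the closing point is never stored twice.

File formats (all plain text):

* contour CSV — one ``x,y`` pair per row, ``.`` decimal separator, an
  optional single header line (auto-detected by a non-numeric first row);
* dataset JSON — a list of shapes with ``id`` + ``points`` so one file can
  hold a whole dataset, with optional per-shape ``group``;
* design CSV — one row per shape with ``shape_id``, ``group`` and optional
  continuous covariate columns;
* results JSON — per-point statistic values, threshold, p value,
  supra-threshold indices and reproducibility metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contour",
    "LandmarkSet",
    "ShapeSample",
    "DesignTable",
    "InferenceResult",
    "ContourIOError",
    "ValidationError",
    "read_contour",
    "write_contour",
    "read_dataset",
    "write_dataset",
    "read_design",
    "write_results",
    "read_results",
]

PACKAGE_VERSION = "0.1.0"


class ContourIOError(ValueError):
    """Malformed input file (bad row, missing column, ...)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates a domain invariant."""


def _as_points(points, label: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"{label}: points must be an (n, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError(f"{label}: points contain non-finite values")
    return pts


@dataclass(frozen=True)
class Contour:
    """Closed 2D outline: an ordered cyclic sequence of >= 4 vertices.

    The closing edge from the last point back to the first is implicit.
    Consecutive duplicate points (zero-length segments) are forbidden,
    including the wrap-around pair.
    """

    points: np.ndarray
    shape_id: str = ""
    closed: bool = True

    def __post_init__(self):
        pts = _as_points(self.points, f"Contour {self.shape_id!r}")
        object.__setattr__(self, "points", pts)
        if len(pts) < 4:
            raise ValidationError(
                f"Contour {self.shape_id!r}: needs at least 4 points, got {len(pts)}"
            )
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        if np.any(seg == 0.0):
            i = int(np.argmin(seg))
            raise ValidationError(
                f"Contour {self.shape_id!r}: zero-length segment at index {i}"
            )

    @property
    def m(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def perimeter(self) -> float:
        return float(np.linalg.norm(np.roll(self.points, -1, axis=0) - self.points, axis=1).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def with_points(self, points: np.ndarray) -> "Contour":
        return Contour(points=points, shape_id=self.shape_id, closed=self.closed)


@dataclass(frozen=True)
class LandmarkSet:
    """A set of L >= 3 manually identified homologous points for one shape."""

    points: np.ndarray
    shape_id: str = ""

    def __post_init__(self):
        pts = _as_points(self.points, f"LandmarkSet {self.shape_id!r}")
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValidationError(
                f"LandmarkSet {self.shape_id!r}: needs at least 3 landmarks, got {len(pts)}"
            )

    @property
    def m(self) -> int:
        return len(self.points)


@dataclass
class ShapeSample:
    """A set of corresponded shapes (equal point count) with group labels.

    ``shapes`` may hold :class:`Contour` or :class:`LandmarkSet` objects;
    ``group`` gives one categorical label per shape and ``covariates`` maps
    covariate names to per-shape real values (e.g. size).
    """

    shapes: list
    group: list
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.shapes) != len(self.group):
            raise ValidationError(
                f"sample: {len(self.shapes)} shapes but {len(self.group)} group labels"
            )
        counts = {s.m for s in self.shapes}
        if len(counts) > 1:
            raise ValidationError(f"sample: unequal point counts across shapes: {sorted(counts)}")
        self.group = list(self.group)
        for name, vals in self.covariates.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (len(self.shapes),):
                raise ValidationError(f"covariate {name!r}: wrong length")
            self.covariates[name] = vals

    def __len__(self) -> int:
        return len(self.shapes)

    @property
    def m(self) -> int:
        return self.shapes[0].m

    def coords(self) -> np.ndarray:
        """Stack point coordinates into an (n_shapes, m, 2) array."""
        return np.stack([s.points for s in self.shapes])

    def group_levels(self) -> list:
        seen = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen

    def group_indices(self) -> dict:
        return {lev: [i for i, g in enumerate(self.group) if g == lev] for lev in self.group_levels()}

    def require_two_groups(self):
        levels = self.group_levels()
        if len(levels) != 2:
            raise ValidationError(f"two-sample analysis needs exactly 2 groups, got {levels}")
        return levels

    def with_coords(self, coords: np.ndarray) -> "ShapeSample":
        shapes = [s.with_points(c) if isinstance(s, Contour) else LandmarkSet(c, s.shape_id)
                  for s, c in zip(self.shapes, coords)]
        return ShapeSample(shapes=shapes, group=list(self.group),
                           covariates={k: v.copy() for k, v in self.covariates.items()})


@dataclass
class DesignTable:
    """One row per shape: shape_id, group, optional continuous covariates."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        for col in ("shape_id", "group"):
            if col not in df.columns:
                raise ValidationError(f"design table: missing required column {col!r}")
        if df["shape_id"].duplicated().any():
            dup = df.loc[df["shape_id"].duplicated(), "shape_id"].iloc[0]
            raise ValidationError(f"design table: duplicate shape_id {dup!r}")
        self.table = df.reset_index(drop=True)

    @property
    def covariate_names(self) -> list:
        return [c for c in self.table.columns if c not in ("shape_id", "group")]

    def group_for(self, shape_id: str):
        row = self.table.loc[self.table["shape_id"] == shape_id]
        if row.empty:
            raise ValidationError(f"design table: no row for shape_id {shape_id!r}")
        return row["group"].iloc[0]


@dataclass
class InferenceResult:
    """Outcome of a maximum-statistic test over a contour or landmark field."""

    statistic: np.ndarray          # per-point T2 values
    t2max: float
    threshold: float
    p: float
    alpha: float
    method: str                    # "parametric" | "nonparametric"
    fwhm: float | None = None      # parametric only
    n_perm: int | None = None      # nonparametric only
    supra_indices: tuple = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.supra_indices = tuple(int(i) for i in self.supra_indices)

    @property
    def reject(self) -> bool:
        return self.t2max > self.threshold

    def to_dict(self) -> dict:
        out = {
            "statistic": [float(v) for v in self.statistic],
            "t2max": float(self.t2max),
            "threshold": float(self.threshold),
            "p": float(self.p),
            "alpha": float(self.alpha),
            "method": self.method,
            "fwhm": None if self.fwhm is None else float(self.fwhm),
            "n_perm": None if self.n_perm is None else int(self.n_perm),
            "supra_indices": list(self.supra_indices),
            "metadata": dict(self.metadata),
            "software_version": PACKAGE_VERSION,
        }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "InferenceResult":
        return cls(
            statistic=np.asarray(d["statistic"], dtype=float),
            t2max=d["t2max"],
            threshold=d["threshold"],
            p=d["p"],
            alpha=d["alpha"],
            method=d["method"],
            fwhm=d.get("fwhm"),
            n_perm=d.get("n_perm"),
            supra_indices=tuple(d.get("supra_indices", ())),
            metadata=dict(d.get("metadata", {})),
        )


# ----------------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------------

def _parse_xy_line(line: str, lineno: int, path) -> tuple:
    parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip() != ""]
    if len(parts) != 2:
        raise ContourIOError(f"{path}: line {lineno}: expected two values, got {len(parts)}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as e:
        raise ContourIOError(f"{path}: line {lineno}: could not parse {line.strip()!r}") from e


def read_contour(path, shape_id: str | None = None) -> Contour:
    """Read one contour from a CSV of x,y rows (optional single header line).

    Points are returned in file order; ordering along the outline is an
    explicit downstream operation, never done by the reader.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() != ""]
    start = 0
    if lines:
        try:
            _parse_xy_line(lines[0], 1, path)
        except ContourIOError:
            start = 1  # header line
    for k, line in enumerate(lines[start:], start=start + 1):
        rows.append(_parse_xy_line(line, k, path))
    if len(rows) < 4:
        raise ValidationError(f"{path}: a contour needs at least 4 points, got {len(rows)}")
    return Contour(points=np.asarray(rows, dtype=float),
                   shape_id=shape_id if shape_id is not None else path.stem)


def write_contour(contour: Contour, path) -> None:
    """Write one contour as x,y rows at full double precision."""
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in contour.points:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def write_dataset(shapes: Iterable[Contour], path, group: Sequence | None = None) -> None:
    shapes = list(shapes)
    recs = []
    for i, s in enumerate(shapes):
        rec = {"id": s.shape_id, "points": [[float(x), float(y)] for x, y in s.points]}
        if group is not None:
            rec["group"] = group[i]
        recs.append(rec)
    with open(path, "w") as fh:
        json.dump({"shapes": recs}, fh)


def read_dataset(path) -> tuple:
    """Read a JSON shape collection; returns (list of Contour, groups or None)."""
    with open(path) as fh:
        doc = json.load(fh)
    if "shapes" not in doc:
        raise ContourIOError(f"{path}: dataset JSON must contain a 'shapes' list")
    shapes, groups = [], []
    for rec in doc["shapes"]:
        shapes.append(Contour(points=np.asarray(rec["points"], dtype=float),
                              shape_id=str(rec.get("id", ""))))
        groups.append(rec.get("group"))
    if all(g is None for g in groups):
        return shapes, None
    return shapes, groups


def read_design(path) -> DesignTable:
    """Read a design CSV (shape_id, group, optional numeric covariates)."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "shape_id" not in df.columns or "group" not in df.columns:
        raise ValidationError(f"{path}: design CSV must have 'shape_id' and 'group' columns")
    df["shape_id"] = df["shape_id"].astype(str)
    for col in df.columns:
        if col in ("shape_id", "group"):
            continue
        df[col] = pd.to_numeric(df[col])
    return DesignTable(table=df)


def write_results(result: InferenceResult, path) -> None:
    """Serialize an InferenceResult to JSON (round-trips via read_results)."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def read_results(path) -> InferenceResult:
    with open(path) as fh:
        return InferenceResult.from_dict(json.load(fh))
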