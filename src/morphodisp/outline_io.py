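"""Reading, validating, resampling and writing closed specimen outlines.

An outline is an ordered, implicitly closed sequence of 2-D points in
arbitrary planar units (mathematical y-up convention; image-derived
outlines digitised y-down must be flipped before import, because
reflection changes the chirality of asymmetric shapes).  Outlines carry a
specimen id, a group label and a time slice.

Supported interchange formats:

* a TPS outline dialect (``LM=0`` / ``CURVES=1`` / ``POINTS=<k>`` /
  coordinate lines / ``ID=<specimen_id>``), with labels in a sidecar CSV
  (``specimen_id,group,time_slice``) because TPS has no label fields;
* Freeman 8-direction chain codes, one record per line
  (``<id> <x0> <y0> <d1 ... dn> -1``), the input format of classic
  outline-harmonics software;
* a wide coefficient CSV for normalised harmonic coefficient matrices.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "TIME_SLICES",
    "Outline",
    "Dataset",
    "OutlineError",
    "ParseError",
    "ValidationError",
    "LabelError",
    "signed_area",
    "perimeter",
    "read_tps",
    "write_tps",
    "read_chaincode",
    "read_labels",
    "resample_outline",
    "write_coeff_table",
    "read_coeff_table",
]

TIME_SLICES = ("cretaceous", "eocene", "miocene", "extant", "other")

#: Freeman 8-direction steps: 0 = +x, counterclockwise in 45-degree increments.
FREEMAN_STEPS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=float,
)


class OutlineError(Exception):
    """Base class for outline I/O and validation failures."""


class ParseError(OutlineError):
    """A file did not follow the declared dialect."""


class ValidationError(OutlineError):
    """An outline violated a geometric invariant."""


class LabelError(OutlineError):
    """A specimen was missing a required label."""


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon; positive = counterclockwise."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    """Total length of the closed polygonal outline."""
    d = np.roll(points, -1, axis=0) - points
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class Outline:
    """A closed specimen outline with labels.

    The last point implicitly connects back to the first; the closing
    point is never stored twice.  Stored orientation is counterclockwise
    (positive signed area); constructors and readers reorient clockwise
    input and record that they did in ``provenance``.
    """

    specimen_id: str
    points: np.ndarray
    group: str = ""
    time_slice: str = "other"
    provenance: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"{self.specimen_id}: points must be (k, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")
        # drop an explicitly repeated closing point
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValidationError(f"{self.specimen_id}: fewer than 3 points")
        if np.any(np.all(pts == np.roll(pts, -1, axis=0), axis=1)):
            raise ValidationError(
                f"{self.specimen_id}: consecutive duplicate points"
            )
        if self.time_slice not in TIME_SLICES:
            raise ValidationError(
                f"{self.specimen_id}: unknown time slice {self.time_slice!r}"
            )
        area = signed_area(pts)
        if area == 0.0:
            raise ValidationError(f"{self.specimen_id}: degenerate (zero area)")
        if area < 0.0:
            pts = pts[::-1].copy()
            self.provenance = (self.provenance + ";" if self.provenance else "") + (
                "reoriented-ccw"
            )
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def validate(self, min_points: int = 8) -> "Outline":
        """Full geometric validation: point count and polygon simplicity.

        Validation failure raises; outlines are never silently repaired.
        """
        distinct = np.unique(self.points, axis=0)
        if len(distinct) < min_points:
            raise ValidationError(
                f"{self.specimen_id}: {len(distinct)} distinct points < {min_points}"
            )
        if not Polygon(self.points).is_valid:
            raise ValidationError(f"{self.specimen_id}: self-intersecting outline")
        return self


@dataclass
class Dataset:
    """A labelled collection of outlines with unique specimen ids."""

    outlines: list[Outline] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [o.specimen_id for o in self.outlines]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.outlines)

    def __iter__(self):
        return iter(self.outlines)

    def require_labels(self) -> "Dataset":
        for o in self.outlines:
            if not o.group:
                raise LabelError(f"{o.specimen_id}: missing group label")
        return self

    def filter_groups(self, exclude: list[str]) -> "Dataset":
        """Drop every outline whose group is in ``exclude``."""
        keep = [o for o in self.outlines if o.group not in set(exclude)]
        return Dataset(outlines=keep)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [o.specimen_id for o in self.outlines],
                "group": [o.group for o in self.outlines],
                "time_slice": [o.time_slice for o in self.outlines],
                "n_points": [o.n_points for o in self.outlines],
                "provenance": [o.provenance for o in self.outlines],
            }
        )


# ---------------------------------------------------------------------------
# TPS outline dialect


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read a label sidecar CSV with columns specimen_id, group, time_slice."""
    tab = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "group", "time_slice"}
    if not required.issubset(tab.columns):
        raise ParseError(f"label table missing columns {required - set(tab.columns)}")
    return tab


def read_tps(
    path: str | os.PathLike,
    labels: pd.DataFrame | str | os.PathLike | None = None,
    require_labels: bool = False,
) -> Dataset:
    """Read a TPS outline file into a :class:`Dataset`.

    Records consist of ``LM=0``, ``CURVES=1``, ``POINTS=<k>``, ``k``
    coordinate lines and ``ID=<specimen_id>``; ``IMAGE=`` and ``SCALE=``
    lines are tolerated and ignored.  Clockwise records are reoriented
    counterclockwise and flagged in provenance.  When ``labels`` is given
    (a DataFrame or a CSV path) group/time_slice are joined on specimen id.
    """
    if labels is not None and not isinstance(labels, pd.DataFrame):
        labels = read_labels(labels)
    label_map = {}
    if labels is not None:
        label_map = {
            r.specimen_id: (r.group, r.time_slice) for r in labels.itertuples()
        }

    outlines: list[Outline] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    rec = 0
    while i < len(lines):
        rec += 1
        # header lines up to POINTS=
        npoints = None
        while i < len(lines):
            ln = lines[i]
            up = ln.upper()
            if up.startswith("POINTS="):
                npoints = int(ln.split("=", 1)[1])
                i += 1
                break
            if up.startswith(("LM=", "CURVES=", "IMAGE=", "SCALE=")):
                i += 1
                continue
            raise ParseError(f"record {rec}: unexpected line {ln!r}")
        if npoints is None:
            raise ParseError(f"record {rec}: missing POINTS= line")
        coords = []
        while i < len(lines) and not lines[i].upper().startswith("ID="):
            if lines[i].upper().startswith(("IMAGE=", "SCALE=")):
                i += 1
                continue
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(f"record {rec}: bad coordinate line {lines[i]!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"record {rec}: {exc}") from exc
            i += 1
        if i >= len(lines):
            raise ParseError(f"record {rec}: missing ID= line")
        specimen_id = lines[i].split("=", 1)[1].strip()
        i += 1
        if len(coords) != npoints:
            raise ParseError(
                f"record {rec} ({specimen_id}): POINTS={npoints} but "
                f"{len(coords)} coordinate lines"
            )
        group, slice_ = "", "other"
        if specimen_id in label_map:
            group, slice_ = label_map[specimen_id]
        elif label_map or require_labels:
            if require_labels:
                raise LabelError(f"no label for specimen {specimen_id!r}")
        outlines.append(
            Outline(
                specimen_id=specimen_id,
                points=np.array(coords),
                group=group,
                time_slice=slice_,
                provenance=f"tps:{os.fspath(path)}",
            )
        )
    return Dataset(outlines=outlines)


def write_tps(dataset: Dataset, path: str | os.PathLike) -> None:
    """Write a dataset in the TPS outline dialect (6 decimals)."""
    with open(path, "w") as fh:
        for o in dataset:
            fh.write("LM=0\nCURVES=1\n")
            fh.write(f"POINTS={o.n_points}\n")
            for x, y in o.points:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={o.specimen_id}\n")


def write_labels(dataset: Dataset, path: str | os.PathLike) -> None:
    """Write the sidecar label CSV for a dataset."""
    dataset.metadata()[["specimen_id", "group", "time_slice"]].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Freeman chain codes


def read_chaincode(path: str | os.PathLike) -> Dataset:
    """Read Freeman 8-direction chain-code records.

    One record per line: ``<specimen_id> <x0> <y0> <d1 ... dn> -1`` with
    directions 0..7 (0 = +x, counterclockwise).  Chains must close exactly
    on the integer lattice; an open chain is a validation error.
    """
    outlines: list[Outline] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            ln = raw.strip()
            if not ln:
                continue
            parts = ln.split()
            if len(parts) < 5 or parts[-1] != "-1":
                raise ParseError(f"line {lineno}: malformed chain record")
            specimen_id = parts[0]
            try:
                origin = np.array([float(parts[1]), float(parts[2])])
                digits = [int(p) for p in parts[3:-1]]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if any(d < 0 or d > 7 for d in digits):
                bad = [d for d in digits if d < 0 or d > 7]
                raise ParseError(
                    f"line {lineno} ({specimen_id}): chain digits {bad} outside 0-7"
                )
            steps = FREEMAN_STEPS[digits]
            pts = origin + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            if not np.array_equal(pts[-1], pts[0]):
                raise ValidationError(
                    f"line {lineno} ({specimen_id}): open chain, "
                    f"ends at {tuple(pts[-1])} not {tuple(pts[0])}"
                )
            outlines.append(
                Outline(
                    specimen_id=specimen_id,
                    points=pts[:-1],
                    provenance=f"chaincode:{os.fspath(path)}",
                )
            )
    return Dataset(outlines=outlines)


# ---------------------------------------------------------------------------
# Resampling


def resample_outline(outline: Outline, k: int) -> Outline:
    """Resample to ``k`` points equally spaced by arc length.

    The first resampled point coincides with the original first point,
    preserving the digitisation starting point.  The default pipeline uses
    k = 200, at least twice the Nyquist need of a 20-harmonic series.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ValidationError(f"{outline.specimen_id}: zero perimeter")
    s = np.linspace(0.0, total, k, endpoint=False)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    return replace(outline, points=np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Coefficient tables

_FLOAT_FMT = "%.12g"


def write_coeff_table(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a normalised-coefficient matrix as CSV.

    Expects metadata columns ``specimen_id, group, time_slice`` followed by
    coefficient columns (``d1, a2, b2, c2, d2, ...``).  Output is
    bit-stable for identical input: fixed column order, 12-significant-digit
    floats.
    """
    if matrix["specimen_id"].duplicated().any():
        dupes = matrix.loc[matrix["specimen_id"].duplicated(), "specimen_id"]
        raise ValidationError(f"duplicate specimen ids: {sorted(set(dupes))}")
    matrix.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_coeff_table(path: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    """Read a coefficient CSV written by :func:`write_coeff_table`."""
    tab = pd.read_csv(path)
    for col in ("specimen_id", "group", "time_slice"):
        if col not in tab.columns:
            raise ParseError(f"coefficient table missing column {col!r}")
    return tab
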