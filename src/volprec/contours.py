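"""Planar ROI contours, slice stacks, and their CSV formats.

A :class:`Contour` is one hand-traced region of interest (ROI) on one CT
slice: an ordered, implicitly closed polygon in the slice plane.  A
:class:`SliceStack` collects every contour of one organ in one scan together
with the slice thickness, and is the input to slice-summation volumetry.

Units are millimetres for lengths and coordinates, cm² for areas, matching
how clinical CT volumetry is reported.

Two plain-text formats are defined here:

* the contour CSV (one row per polygon vertex) with columns
  ``patient_id, scan_id, organ_label, slice_index, z_mm, slice_thickness_mm,
  vertex_index, x_mm, y_mm``;
* the series CSV (one row per scan volume) with columns
  ``patient_id, scan_id, scan_date, organ_label, volume_cm3``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CONTOUR_COLUMNS = [
    "patient_id",
    "scan_id",
    "organ_label",
    "slice_index",
    "z_mm",
    "slice_thickness_mm",
    "vertex_index",
    "x_mm",
    "y_mm",
]

SERIES_COLUMNS = ["patient_id", "scan_id", "scan_date", "organ_label", "volume_cm3"]

#: tolerance (mm) for the slice-spacing / duplicate-z checks
Z_TOLERANCE_MM = 1e-6


def polygon_area(vertices) -> float:
    """Absolute shoelace area of an implicitly closed polygon, in cm².

    Parameters
    ----------
    vertices
        A :class:`Contour` or an (n, 2) array of in-plane coordinates in mm.
        The polygon is closed implicitly (last vertex connects to the first).

    Returns
    -------
    float
        Enclosed area in cm² (mm² / 100).  Orientation independent; a
        degenerate (e.g. collinear) polygon returns 0.0 — callers that
        require a positive area must check (``validate_stack`` flags it).

    Raises
    ------
    ValidationError
        If fewer than 3 vertices remain or any coordinate is non-finite.
    """
    if isinstance(vertices, Contour):
        vertices = vertices.vertices
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValidationError(f"vertices must be an (n, 2) array, got shape {v.shape}")
    if v.shape[0] < 3:
        raise ValidationError(f"a contour needs at least 3 vertices, got {v.shape[0]}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("contour contains non-finite coordinates")
    x, y = v[:, 0], v[:, 1]
    area_mm2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_mm2) / 100.0


@dataclasses.dataclass(eq=False)
class Contour:
    """One closed ROI polygon on one CT slice.

    ``vertices`` is an (n, 2) float array of (x, y) mm coordinates; the
    polygon is implicitly closed.  An explicitly repeated first vertex (the
    other common export convention of freehand PACS tools) is dropped on
    construction.  ``thickness_mm`` is optional and overrides the stack-level
    slice thickness, supporting scans with mixed section thickness.
    """

    patient_id: str
    scan_id: str
    organ_label: str
    slice_index: int
    z_mm: float
    vertices: np.ndarray
    thickness_mm: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError(
                f"{self._label()}: vertices must be (n, 2), got shape {v.shape}"
            )
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1], atol=1e-12):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValidationError(f"{self._label()}: fewer than 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self._label()}: non-finite coordinates")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValidationError(f"{self._label()}: slice thickness must be > 0")
        self.vertices = v

    def _label(self) -> str:
        return (
            f"contour(patient={self.patient_id!r}, scan={self.scan_id!r}, "
            f"organ={self.organ_label!r}, z={self.z_mm} mm)"
        )

    @property
    def area_cm2(self) -> float:
        return polygon_area(self.vertices)


@dataclasses.dataclass(eq=False)
class SliceStack:
    """All contours of one organ in one scan, ordered by z position.

    ``slice_thickness_mm`` is the nominal section thickness; individual
    contours may carry their own ``thickness_mm`` (mixed-thickness scans),
    in which case the stack-level value records the most common one.
    """

    patient_id: str
    scan_id: str
    organ_label: str
    slice_thickness_mm: float
    contours: list[Contour]

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValidationError(
                f"{self._label()}: slice thickness must be > 0, "
                f"got {self.slice_thickness_mm}"
            )
        self.contours = sorted(self.contours, key=lambda c: c.z_mm)

    def _label(self) -> str:
        return (
            f"stack(patient={self.patient_id!r}, scan={self.scan_id!r}, "
            f"organ={self.organ_label!r})"
        )

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([c.z_mm for c in self.contours], dtype=float)

    def contour_thickness(self, contour: Contour) -> float:
        """Effective slice thickness for one contour (per-contour override)."""
        return (
            contour.thickness_mm
            if contour.thickness_mm is not None
            else self.slice_thickness_mm
        )


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str


def validate_stack(
    stack: SliceStack, partial_coverage_fraction: float = 0.5
) -> list[ValidationIssue]:
    """Check a stack against the volumetry invariants; report, don't throw.

    Errors reported: duplicate z positions, slice spacing that is not an
    integer multiple of the slice thickness (within ``Z_TOLERANCE_MM``), and
    zero-area (degenerate) contours.  A warning is reported when the first or
    last contour's area exceeds ``partial_coverage_fraction`` of the maximum
    contour area — the area profile does not taper off at the ends, so the
    scan likely imaged the organ only partially and the summed volume would
    be truncated.
    """
    issues: list[ValidationIssue] = []
    if not stack.contours:
        issues.append(ValidationIssue("error", "empty-stack", f"{stack._label()}: no contours"))
        return issues

    z = stack.z_positions
    if len(z) > 1:
        dz = np.diff(z)
        if np.any(dz < Z_TOLERANCE_MM):
            issues.append(
                ValidationIssue(
                    "error",
                    "duplicate-z",
                    f"{stack._label()}: more than one contour at the same z position",
                )
            )
        t = stack.slice_thickness_mm
        ratio = dz / t
        if np.any(np.abs(ratio - np.round(ratio)) * t > Z_TOLERANCE_MM):
            issues.append(
                ValidationIssue(
                    "error",
                    "slice-spacing",
                    f"{stack._label()}: consecutive z positions are not integer "
                    f"multiples of the slice thickness ({t} mm)",
                )
            )

    areas = []
    for c in stack.contours:
        a = polygon_area(c.vertices)
        areas.append(a)
        if a <= 0.0:
            issues.append(
                ValidationIssue(
                    "error", "zero-area", f"{c._label()}: degenerate (zero-area) contour"
                )
            )
    areas_arr = np.asarray(areas)
    if np.max(areas_arr) > 0:
        frac_first = areas_arr[0] / areas_arr.max()
        frac_last = areas_arr[-1] / areas_arr.max()
        if max(frac_first, frac_last) > partial_coverage_fraction:
            issues.append(
                ValidationIssue(
                    "warning",
                    "partial-coverage",
                    f"{stack._label()}: outermost contour area is "
                    f"{100 * max(frac_first, frac_last):.0f}% of the maximum — the organ "
                    "may be only partially imaged",
                )
            )
    return issues


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_contours(path) -> list[SliceStack]:
    """Read a contour CSV into validated slice stacks.

    Rows are grouped by (patient_id, scan_id, organ_label); within a contour
    vertices are ordered by ``vertex_index``.  Validation invariants are
    enforced: a stack whose :func:`validate_stack` report contains errors
    raises :class:`~volprec.errors.ValidationError`.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "scan_id": str, "organ_label": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a readable CSV file ({exc})") from exc
    _require_columns(df, CONTOUR_COLUMNS, path)

    dup_key = ["patient_id", "scan_id", "organ_label", "z_mm", "vertex_index"]
    if df.duplicated(subset=dup_key).any():
        raise FormatError(
            f"{path}: duplicate (scan, organ, z, vertex_index) rows"
        )

    stacks: list[SliceStack] = []
    for (pid, sid, organ), g in df.groupby(
        ["patient_id", "scan_id", "organ_label"], sort=True
    ):
        contours = []
        for (z, sl_idx, t), cg in g.groupby(["z_mm", "slice_index", "slice_thickness_mm"]):
            cg = cg.sort_values("vertex_index")
            contours.append(
                Contour(
                    patient_id=pid,
                    scan_id=sid,
                    organ_label=organ,
                    slice_index=int(sl_idx),
                    z_mm=float(z),
                    vertices=cg[["x_mm", "y_mm"]].to_numpy(dtype=float),
                    thickness_mm=float(t),
                )
            )
        thickness = _mode([c.thickness_mm for c in contours])
        stack = SliceStack(
            patient_id=pid,
            scan_id=sid,
            organ_label=organ,
            slice_thickness_mm=thickness,
            contours=contours,
        )
        errors = [i for i in validate_stack(stack) if i.severity == "error"]
        if errors:
            raise ValidationError("; ".join(i.message for i in errors))
        stacks.append(stack)
    return stacks


def _mode(values: Iterable[float]) -> float:
    counts = Counter(values)
    best = max(counts.values())
    # ties broken toward the smallest thickness, deterministically
    return min(v for v, c in counts.items() if c == best)


def write_contours(stacks: Iterable[SliceStack], path) -> None:
    """Write stacks to a contour CSV with a deterministic row order.

    Rows are sorted by (patient, scan, organ, slice_index, vertex_index) and
    floats are printed with 6 decimals, so write → read → write is
    byte-stable.
    """
    rows = []
    for s in stacks:
        for c in s.contours:
            t = s.contour_thickness(c)
            for vi, (x, y) in enumerate(c.vertices):
                rows.append(
                    (s.patient_id, s.scan_id, c.organ_label, c.slice_index,
                     c.z_mm, t, vi, x, y)
                )
    df = pd.DataFrame(rows, columns=CONTOUR_COLUMNS)
    df = df.sort_values(
        ["patient_id", "scan_id", "organ_label", "slice_index", "vertex_index"],
        kind="mergesort",
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_series(path) -> pd.DataFrame:
    """Read a longitudinal volume-series CSV.

    Returns a DataFrame with columns ``patient_id, scan_id, scan_date,
    organ_label, volume_cm3``; ``scan_date`` is optional in the file and
    filled with NA when absent.  Non-positive volumes are rejected.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "scan_id": str, "organ_label": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a readable CSV file ({exc})") from exc
    required = [c for c in SERIES_COLUMNS if c != "scan_date"]
    _require_columns(df, required, path)
    if "scan_date" not in df.columns:
        df["scan_date"] = pd.NA
    df = df[SERIES_COLUMNS]
    vols = df["volume_cm3"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vols)) or np.any(vols <= 0):
        raise ValidationError(f"{path}: volumes must be finite and > 0")
    return df


def write_series(df: pd.DataFrame, path) -> None:
    """Write a series DataFrame in the series CSV dialect (deterministic)."""
    out = df.copy()
    if "scan_date" not in out.columns:
        out["scan_date"] = pd.NA
    out = out[SERIES_COLUMNS].sort_values(
        ["patient_id", "organ_label", "scan_id"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.6f")
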