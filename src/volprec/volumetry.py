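"""Slice-summation volumetry and linear↔volumetric conversions.

The volume estimator is the one used in clinical CT tumour volumetry from
hand-traced ROIs: each slice contributes its contour area times the full
nominal slice thickness,

    V_total = sum_j A_j * t_j,

with no end-cap or partial-volume correction — the accuracy loss at coarse
slice thickness is a property of the method under study, not of the
implementation.

The analytic helpers relate sphere volume to diameter and isotropic linear
change to volumetric change (the bridge between unidimensional RECIST-style
response criteria and volumetric ones), and model in-plane pixel size and
cursor-positioning error.
"""

from __future__ import annotations

import dataclasses
import math

from .contours import SliceStack, polygon_area
from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class VolumeMeasurement:
    """One organ volume from one scan."""

    patient_id: str
    scan_id: str
    organ_label: str
    volume_cm3: float
    n_slices: int
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if self.volume_cm3 <= 0:
            raise ValidationError(f"volume must be > 0, got {self.volume_cm3}")
        if self.n_slices < 1:
            raise ValidationError("a measurement needs at least one slice")


def volume_from_stack(stack: SliceStack) -> VolumeMeasurement:
    """Slice-summation volume of a stack: sum of area × thickness.

    Areas are in cm², thicknesses in mm, so each slice contributes
    ``area_cm2 * t_mm / 10`` cm³.  Mixed slice thickness is supported via
    per-contour thickness overrides.

    Raises
    ------
    ValidationError
        For an empty stack or any degenerate (zero-area) contour.
    """
    if not stack.contours:
        raise ValidationError(f"{stack._label()}: cannot compute volume of an empty stack")
    total = 0.0
    for c in stack.contours:
        a = polygon_area(c.vertices)
        if a <= 0.0:
            raise ValidationError(f"{c._label()}: degenerate contour in volume computation")
        total += a * stack.contour_thickness(c) / 10.0
    return VolumeMeasurement(
        patient_id=stack.patient_id,
        scan_id=stack.scan_id,
        organ_label=stack.organ_label,
        volume_cm3=total,
        n_slices=len(stack.contours),
        slice_thickness_mm=stack.slice_thickness_mm,
    )


def sphere_volume(diameter_mm: float) -> float:
    """Volume of a sphere of the given diameter (mm), in cm³: π d³ / 6."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_mm}")
    return math.pi * diameter_mm**3 / 6.0 / 1000.0


def equivalent_sphere_diameter(volume_cm3: float) -> float:
    """Diameter (mm) of the sphere with the given volume (cm³): (6V/π)^⅓."""
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be > 0, got {volume_cm3}")
    return (6.0 * volume_cm3 * 1000.0 / math.pi) ** (1.0 / 3.0)


def volume_change_to_linear(volume_fraction_change: float) -> float:
    """Isotropic linear change equivalent to a fractional volume change.

    Under isotropic growth all three linear dimensions scale equally, so
    ΔL = (1 + ΔV)^⅓ − 1.
    """
    if volume_fraction_change <= -1:
        raise ValueError("volume change must be > -1 (volume cannot vanish)")
    return (1.0 + volume_fraction_change) ** (1.0 / 3.0) - 1.0


def linear_change_to_volume(linear_fraction_change: float) -> float:
    """Fractional volume change from an isotropic linear change: (1+ΔL)³ − 1.

    The remaining-volume fraction is ``1 +`` the returned value; e.g. a 30%
    linear shrinkage leaves 0.70³ = 0.343 of the initial volume.
    """
    if linear_fraction_change <= -1:
        raise ValueError("linear change must be > -1")
    return (1.0 + linear_fraction_change) ** 3 - 1.0


def pixel_size(field_of_view_mm: float, matrix: int) -> float:
    """In-plane pixel size (mm) of a reconstruction: field of view / matrix."""
    if field_of_view_mm <= 0 or matrix <= 0:
        raise ValueError("field of view and matrix must be > 0")
    return field_of_view_mm / matrix


def pixel_error_linear_fraction(
    pixel_mm: float, object_diameter_mm: float, n_pixels: int = 1
) -> float:
    """Fractional linear-dimension error from an n-pixel cursor misplacement."""
    if pixel_mm <= 0 or object_diameter_mm <= 0:
        raise ValueError("pixel size and object diameter must be > 0")
    if n_pixels < 0:
        raise ValueError("n_pixels must be >= 0")
    return n_pixels * pixel_mm / object_diameter_mm
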