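"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: polygon
areas are re-measured by counting grid points inside the polygon, summary
statistics by explicit two-pass loops, and t-distribution tail areas by
numerical integration of the density.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from volprec import Contour, SliceStack


# ---------------------------------------------------------------------------
# oracles


def rasterized_area_cm2(vertices_mm: np.ndarray, grid_mm: float = 0.05) -> float:
    """Brute-force polygon area: count grid-cell centres inside the polygon."""
    v = np.asarray(vertices_mm, dtype=float)
    path = MplPath(np.vstack([v, v[:1]]), closed=True)
    xmin, ymin = v.min(axis=0) - grid_mm
    xmax, ymax = v.max(axis=0) + grid_mm
    xs = np.arange(xmin + grid_mm / 2, xmax, grid_mm)
    ys = np.arange(ymin + grid_mm / 2, ymax, grid_mm)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = path.contains_points(pts)
    return inside.sum() * grid_mm * grid_mm / 100.0


def two_pass_summary(values) -> tuple[int, float, float, float]:
    """Textbook two-pass mean / sample SD / COV, plain Python loops."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    sd = math.sqrt(ss / (n - 1))
    return n, mean, sd, sd / mean


def t_two_sided_p_by_quadrature(t_stat: float, df: int) -> float:
    """Two-sided t-test p-value via numerical integration of the density."""
    from scipy.integrate import quad
    from scipy.special import gammaln

    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)

    def density(x: float) -> float:
        return math.exp(logc - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _err = quad(density, abs(t_stat), math.inf, epsabs=1e-13, epsrel=1e-13)
    return 2.0 * tail


def random_star_polygon(rng: np.random.Generator, n_min: int = 5, n_max: int = 30) -> np.ndarray:
    """Seeded random simple polygon: sorted angles with positive radii (mm)."""
    n = int(rng.integers(n_min, n_max + 1))
    # quasi-regular angular spacing: jittered but never clustered, so the
    # polygon stays chunky enough for the fixed-resolution grid oracle
    angles = 2.0 * np.pi * (np.arange(n) + rng.uniform(0.1, 0.9, n)) / n
    radii = rng.uniform(5.0, 15.0, n)
    center = rng.uniform(-20.0, 20.0, 2)
    return center + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def series_with_exact_summary(
    mean: float, cov: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Volumes with exactly the requested mean and COV (sample SD, ddof=1)."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    v = mean + mean * cov * z
    assert np.all(v > 0), "requested COV too large for a positive series"
    return v


@pytest.fixture
def area_oracle():
    return rasterized_area_cm2


@pytest.fixture
def summary_oracle():
    return two_pass_summary


@pytest.fixture
def p_value_oracle():
    return t_two_sided_p_by_quadrature


@pytest.fixture
def polygon_factory():
    return random_star_polygon


@pytest.fixture
def exact_series_factory():
    return series_with_exact_summary


# ---------------------------------------------------------------------------
# geometry builders


def square_contour(
    side_mm: float,
    z_mm: float = 0.0,
    slice_index: int = 0,
    thickness_mm: float | None = None,
    **ids,
) -> Contour:
    s = side_mm / 2.0
    return Contour(
        patient_id=ids.get("patient_id", "p1"),
        scan_id=ids.get("scan_id", "s1"),
        organ_label=ids.get("organ_label", "organ"),
        slice_index=slice_index,
        z_mm=z_mm,
        vertices=np.array([[-s, -s], [s, -s], [s, s], [-s, s]]),
        thickness_mm=thickness_mm,
    )


def circle_contour(
    radius_mm: float,
    z_mm: float = 0.0,
    slice_index: int = 0,
    n_vertices: int = 512,
    **ids,
) -> Contour:
    th = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    return Contour(
        patient_id=ids.get("patient_id", "p1"),
        scan_id=ids.get("scan_id", "s1"),
        organ_label=ids.get("organ_label", "organ"),
        slice_index=slice_index,
        z_mm=z_mm,
        vertices=np.column_stack(
            [radius_mm * np.cos(th), radius_mm * np.sin(th)]
        ),
    )


def stack_of_areas(
    areas_cm2, thickness_mm: float, z0: float = 0.0, **ids
) -> SliceStack:
    """Stack of square contours with the given areas at consecutive slices."""
    contours = [
        square_contour(
            math.sqrt(100.0 * a),
            z_mm=z0 + i * thickness_mm,
            slice_index=i,
            **ids,
        )
        for i, a in enumerate(areas_cm2)
    ]
    return SliceStack(
        patient_id=ids.get("patient_id", "p1"),
        scan_id=ids.get("scan_id", "s1"),
        organ_label=ids.get("organ_label", "organ"),
        slice_thickness_mm=thickness_mm,
        contours=contours,
    )


@pytest.fixture
def make_square_contour():
    return square_contour


@pytest.fixture
def make_circle_contour():
    return circle_contour


@pytest.fixture
def make_stack():
    return stack_of_areas
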