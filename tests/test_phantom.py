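"""Phantom cross-sections, simulated tracing, scans and series."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import volprec as vp
from volprec import (
    Bilobed,
    Ellipsoid,
    PhantomSpec,
    Sphere,
    ValidationError,
    cross_section_area,
    generate_contour,
    polygon_area,
    simulate_longitudinal_series,
    simulate_scan,
    sphere_for_volume,
    volume_from_stack,
)


def noiseless_spec(shape, **kw):
    defaults = dict(radial_noise_sd=0.0, boundary_bias_sd_mm=0.0, pixel_quantization_mm=None)
    defaults.update(kw)
    return PhantomSpec(shape=shape, **defaults)


class TestCrossSection:
    def test_sphere_equator(self):
        assert cross_section_area(Sphere(20.0), 0.0) == pytest.approx(math.pi, abs=1e-12)

    def test_sphere_tangent_planes(self):
        assert cross_section_area(Sphere(20.0), 10.0) == 0.0
        assert cross_section_area(Sphere(20.0), -10.0) == 0.0

    def test_ellipsoid_mid_plane(self):
        e = Ellipsoid(12.0, 8.0, 10.0)
        assert cross_section_area(e, 0.0) == pytest.approx(math.pi * 12 * 8 / 100)
        assert cross_section_area(e, 10.0) == 0.0

    def test_fully_overlapping_lobes_degenerate_to_larger(self, area_oracle):
        big = Ellipsoid(12.0, 8.0, 10.0)
        small = Ellipsoid(6.0, 4.0, 5.0)
        shape = Bilobed(big, small, (0.0, 0.0, 0.0))
        a_union = cross_section_area(shape, 2.0)
        a_big = cross_section_area(big, 2.0)
        assert a_union == pytest.approx(a_big, rel=0.005)
        # and the union area agrees with a grid-count oracle on the section
        spec = noiseless_spec(shape)
        c = generate_contour(spec, 2.0, np.random.default_rng(0))
        assert polygon_area(c.vertices) == pytest.approx(area_oracle(c.vertices, 0.05), rel=0.005)

    def test_disjoint_lobes_keep_dominant_component(self):
        shape = Bilobed(Ellipsoid(5, 5, 5), Ellipsoid(3, 3, 3), (30.0, 0.0, 0.0))
        a = cross_section_area(shape, 0.0)
        assert a == pytest.approx(math.pi * 25 / 100, rel=1e-3)

    def test_offset_bilobed_union_less_than_sum(self):
        lobe = Ellipsoid(8.0, 6.0, 9.0)
        shape = Bilobed(lobe, lobe, (6.0, 0.0, 2.0))
        a = cross_section_area(shape, 0.0)
        assert cross_section_area(lobe, 0.0) < a < 2 * cross_section_area(lobe, 0.0)


class TestGenerateContour:
    def test_noiseless_circle_matches_inscribed_polygon_area(self):
        spec = noiseless_spec(Sphere(20.0), n_vertices=64)
        c = generate_contour(spec, 0.0, np.random.default_rng(0))
        r = 10.0
        expected = (64 / 2) * r * r * math.sin(2 * math.pi / 64) / 100.0
        assert polygon_area(c.vertices) == pytest.approx(expected, rel=1e-12)

    def test_fixed_seed_reproducible(self):
        spec = PhantomSpec(shape=Sphere(20.0), seed=3)
        c1 = generate_contour(spec, 2.0, np.random.default_rng(5))
        c2 = generate_contour(spec, 2.0, np.random.default_rng(5))
        assert np.array_equal(c1.vertices, c2.vertices)

    def test_empty_cross_section_signalled_as_none(self):
        spec = noiseless_spec(Sphere(20.0))
        assert generate_contour(spec, 11.0, np.random.default_rng(0)) is None

    def test_vertex_noise_statistics_match_first_order_theory(self):
        # iid radial jitter: mean area nearly unbiased, relative SD ≈ 2σ/√n
        sigma, n = 0.05, 64
        spec = PhantomSpec(
            shape=Sphere(20.0), radial_noise_sd=sigma,
            boundary_bias_sd_mm=0.0, pixel_quantization_mm=None, n_vertices=n,
        )
        rng = np.random.default_rng(42)
        areas = np.array(
            [polygon_area(generate_contour(spec, 0.0, rng).vertices) for _ in range(10000)]
        )
        noiseless = (n / 2) * 100 * math.sin(2 * math.pi / n) / 100.0
        assert areas.mean() == pytest.approx(noiseless, rel=0.005)
        assert areas.std() / areas.mean() == pytest.approx(2 * sigma / math.sqrt(n), rel=0.10)


class TestSimulateScan:
    def test_noiseless_sphere_volume_range_and_slice_count(self):
        # frozen from an exhaustive 0.01 mm sweep of the slice offset:
        # attainable slice-summation volumes lie in [3.9270, 4.3197] cm³
        # (times the inscribed-64-gon factor) with 3-4 slices
        spec = noiseless_spec(Sphere(20.0))
        poly_factor = (64 / 2) * math.sin(2 * math.pi / 64) / math.pi
        for seed in range(40):
            stack = simulate_scan(spec, np.random.default_rng(seed))
            assert len(stack) in (3, 4)
            v = volume_from_stack(stack).volume_cm3
            assert 3.92699 * poly_factor - 1e-9 <= v <= 4.31969 + 1e-9

    def test_fine_slicing_converges_to_analytic_volume(self):
        spec = noiseless_spec(Sphere(20.0), slice_thickness_mm=0.1, n_vertices=256)
        stack = simulate_scan(spec, np.random.default_rng(1))
        assert volume_from_stack(stack).volume_cm3 == pytest.approx(
            vp.sphere_volume(20.0), rel=0.005
        )

    def test_fixed_seed_gives_identical_stack(self):
        spec = PhantomSpec(shape=sphere_for_volume(3.4), seed=0)
        s1 = simulate_scan(spec, np.random.default_rng(9))
        s2 = simulate_scan(spec, np.random.default_rng(9))
        assert len(s1) == len(s2)
        for c1, c2 in zip(s1.contours, s2.contours):
            assert c1.z_mm == c2.z_mm
            assert np.array_equal(c1.vertices, c2.vertices)

    def test_tiny_object_yields_single_slice_with_warning(self):
        spec = noiseless_spec(Sphere(3.0))
        with pytest.warns(UserWarning, match="single slice"):
            stack = simulate_scan(spec, np.random.default_rng(2))
        assert len(stack) >= 1

    def test_stacks_pass_validation(self):
        spec = PhantomSpec(shape=sphere_for_volume(3.4), seed=0)
        stack = simulate_scan(spec, np.random.default_rng(4))
        assert [i for i in vp.validate_stack(stack) if i.severity == "error"] == []


class TestLongitudinalSeries:
    def test_same_seed_identical_csv_bytes(self, tmp_path):
        spec = PhantomSpec(shape=sphere_for_volume(3.4), n_scans=5, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_longitudinal_series(spec, out_dir=d1)
        simulate_longitudinal_series(spec, out_dir=d2)
        for name in ("contours.csv", "series.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_prefix_stable_when_n_scans_grows(self):
        short = PhantomSpec(shape=sphere_for_volume(3.4), n_scans=4, seed=8)
        long = PhantomSpec(shape=sphere_for_volume(3.4), n_scans=8, seed=8)
        s_short, _ = simulate_longitudinal_series(short)
        s_long, _ = simulate_longitudinal_series(long)
        assert s_short.volumes.tolist() == s_long.volumes[:4].tolist()

    def test_noiseless_fine_slices_give_near_zero_cov(self):
        spec = noiseless_spec(sphere_for_volume(3.4), slice_thickness_mm=0.5, n_scans=10)
        series, _ = simulate_longitudinal_series(spec)
        assert vp.series_summary(series).cov < 0.01

    def test_calibrated_noise_reproduces_adrenal_scale_cov(self):
        # default noise, 3.4 cm³ sphere, t = 5 mm: series COV sits in the
        # 14-24% band typical of hand-outlined adrenal-sized objects
        covs = []
        for i in range(60):
            spec = PhantomSpec(shape=sphere_for_volume(3.4), n_scans=20, seed=3000 + i)
            series, _ = simulate_longitudinal_series(spec)
            covs.append(vp.series_summary(series).cov)
        covs = np.array(covs)
        assert 0.14 <= np.median(covs) <= 0.24
        assert 0.14 <= covs.mean() <= 0.24

    def test_unbiased_at_fine_sampling(self):
        # t = d/100 and zero noise: mean volume within 0.2% of πd³/6
        d = 20.0
        spec = noiseless_spec(Sphere(d), slice_thickness_mm=d / 100, n_scans=50, n_vertices=256)
        series, _ = simulate_longitudinal_series(spec)
        assert series.volumes.mean() == pytest.approx(vp.sphere_volume(d), rel=0.002)

    def test_cov_decreases_with_volume(self):
        medians = []
        for j, volume in enumerate([1.0, 4.0, 16.0]):
            covs = []
            for i in range(60):
                spec = PhantomSpec(
                    shape=sphere_for_volume(volume), n_scans=10, seed=7000 + 100 * j + i
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    series, _ = simulate_longitudinal_series(spec)
                covs.append(vp.series_summary(series).cov)
            medians.append(np.median(covs))
        assert medians[0] > medians[1] > medians[2]

    def test_equivalent_diameter_cov_follows_delta_method(self):
        spec = PhantomSpec(shape=sphere_for_volume(3.4), n_scans=200, seed=99)
        series, _ = simulate_longitudinal_series(spec)
        v = series.volumes
        d = np.array([vp.equivalent_sphere_diameter(x) for x in v])
        cov_v = v.std(ddof=1) / v.mean()
        cov_d = d.std(ddof=1) / d.mean()
        assert cov_d == pytest.approx(cov_v / 3.0, rel=0.15)


class TestSpecValidation:
    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            Sphere(0.0)
        with pytest.raises(ValidationError):
            Ellipsoid(1.0, -2.0, 3.0)

    def test_bad_acquisition_parameters_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(shape=Sphere(10.0), slice_thickness_mm=0.0)
        with pytest.raises(ValidationError):
            PhantomSpec(shape=Sphere(10.0), n_vertices=4)
        with pytest.raises(ValidationError):
            PhantomSpec(shape=Sphere(10.0), radial_noise_sd=-0.1)
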