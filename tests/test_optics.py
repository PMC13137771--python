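"""Ray, bundle, intersection, and refraction primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoprint import (BundleSpec, DropletSpec, InvalidGeometryError, Ray,
                       half_angle_from_na, intersect_sphere, make_bundle,
                       refract, trace_through_droplet)
from cytoprint.optics import bundle_arrays


def ray(o, d):
    d = np.asarray(d, float)
    return Ray(np.asarray(o, float), d / np.linalg.norm(d))


class TestRay:
    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError):
            Ray(np.zeros(3), np.array([0.0, 0.0, 2.0]))

    def test_origin_must_be_finite(self):
        with pytest.raises(ValueError):
            Ray(np.array([np.inf, 0, 0]), np.array([0.0, 0.0, 1.0]))


class TestBundle:
    @pytest.mark.parametrize("sampling", ["grid", "fibonacci", "random"])
    def test_rays_converge_on_nominal_focus(self, sampling):
        # with no droplet every ray line passes through the nominal focus
        spec = BundleSpec(nominal_focus=np.array([0.4, -0.2, 5.0]),
                          n_rays=200, sampling=sampling, seed=7)
        for r in make_bundle(spec):
            t = (spec.nominal_focus[2] - r.origin[2]) / r.direction[2]
            assert np.linalg.norm(r.point_at(t) - spec.nominal_focus) < 1e-9

    def test_grid_sampling_large_bundle_exact_convergence(self):
        spec = BundleSpec(n_rays=2500, sampling="grid")
        o, d = bundle_arrays(spec)
        assert len(o) == 2500
        t = (spec.nominal_focus[2] - o[:, 2]) / d[:, 2]
        pts = o + t[:, None] * d
        assert np.max(np.linalg.norm(pts - spec.nominal_focus, axis=1)) < 1e-9

    def test_single_ray_degenerate_bundle(self):
        spec = BundleSpec(n_rays=1)
        rays = make_bundle(spec)
        assert len(rays) == 1
        r = rays[0]
        t = (spec.nominal_focus[2] - r.origin[2]) / r.direction[2]
        assert np.linalg.norm(r.point_at(t) - spec.nominal_focus) < 1e-12

    def test_default_bundle_size_is_2500(self):
        assert BundleSpec().n_rays == 2500

    @pytest.mark.parametrize("sampling", ["grid", "fibonacci"])
    def test_deterministic_sampling(self, sampling):
        a, _ = bundle_arrays(BundleSpec(sampling=sampling, n_rays=123))
        b, _ = bundle_arrays(BundleSpec(sampling=sampling, n_rays=123))
        np.testing.assert_array_equal(a, b)

    def test_random_sampling_reproducible_by_seed(self):
        a, _ = bundle_arrays(BundleSpec(sampling="random", seed=3, n_rays=50))
        b, _ = bundle_arrays(BundleSpec(sampling="random", seed=3, n_rays=50))
        c, _ = bundle_arrays(BundleSpec(sampling="random", seed=4, n_rays=50))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_origins_fill_cone_disc_homogeneously(self):
        spec = BundleSpec(n_rays=2000)
        o, _ = bundle_arrays(spec)
        height = spec.nominal_focus[2] - spec.origin_plane_z
        disc_r = height * math.tan(spec.half_angle)
        radii = np.hypot(o[:, 0] - spec.nominal_focus[0],
                         o[:, 1] - spec.nominal_focus[1])
        assert radii.max() <= disc_r + 1e-9
        # homogeneous disc: fraction of points within r/2 of center ~ 1/4
        assert abs(np.mean(radii < disc_r / 2) - 0.25) < 0.02

    def test_origin_plane_above_focus_rejected(self):
        spec = BundleSpec(nominal_focus=np.array([0.0, 0.0, 1.0]),
                          origin_plane_z=2.0)
        with pytest.raises(InvalidGeometryError):
            make_bundle(spec)

    def test_na_cap_keeps_half_angle_physical(self):
        theta = half_angle_from_na(na=1.4, n_outside=1.37, cap_fraction=0.95)
        assert 0 < theta < math.pi / 2
        assert math.isclose(math.sin(theta), 0.95, rel_tol=1e-12)
        # objective NA below the cap is used directly
        theta2 = half_angle_from_na(na=0.8, n_outside=1.37)
        assert math.isclose(math.sin(theta2), 0.8 / 1.37, rel_tol=1e-12)


class TestIntersectSphere:
    def test_axial_ray_hits_south_pole(self, droplet):
        hit = intersect_sphere(ray([0, 0, -3], [0, 0, 1]), droplet)
        np.testing.assert_allclose(hit.point, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(hit.normal, [0, 0, -1], atol=1e-12)

    def test_miss_returns_none(self, droplet):
        assert intersect_sphere(ray([20, 0, -3], [0, 0, 1]), droplet) is None

    def test_hit_points_lie_on_sphere(self, droplet, rng):
        for _ in range(200):
            o = rng.uniform(-12, 12, 3)
            d = rng.normal(size=3)
            h = intersect_sphere(ray(o, d), droplet)
            if h is not None:
                assert abs(np.linalg.norm(h.point - droplet.center)
                           - droplet.radius) < 1e-9
                assert abs(np.linalg.norm(h.normal) - 1.0) < 1e-12
                assert h.t > 0


class TestRefract:
    def test_normal_incidence_unchanged(self):
        r = ray([0, 0, 0], [0, 0, 1])
        out = refract(r, np.array([0.0, 0.0, -1.0]), 1.37, 1.48)
        np.testing.assert_allclose(out.direction, r.direction, atol=1e-12)

    def test_matched_indices_unchanged(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            r = ray([0, 0, 0], d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            out = refract(r, n, 1.4, 1.4)
            np.testing.assert_allclose(out.direction, r.direction, atol=1e-12)

    def test_30_degree_incidence_scalar_snell(self):
        # sin(30)/1.08 -> theta_t = 27.583 degrees
        inc = math.radians(30.0)
        d = np.array([math.sin(inc), 0.0, math.cos(inc)])
        out = refract(Ray(np.zeros(3), d), np.array([0.0, 0.0, -1.0]),
                      1.0, 1.08)
        theta_t = math.degrees(math.asin(abs(out.direction[0])))
        oracle = math.degrees(math.asin(math.sin(inc) / 1.08))  # 27.5785 deg
        assert abs(theta_t - oracle) < 1e-3

    @settings(max_examples=100, derandomize=True)
    @given(theta=st.floats(0.0, 1.45),
           phi=st.floats(0.0, 2 * math.pi),
           nf=st.floats(1.0, 1.8), nt=st.floats(1.0, 1.8))
    def test_snell_law_residual_and_coplanarity(self, theta, phi, nf, nt):
        d = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi),
                      math.cos(theta)])
        n = np.array([0.0, 0.0, -1.0])
        try:
            out = refract(Ray(np.zeros(3), d), n, nf, nt)
        except ValueError:
            assert nf * math.sin(theta) > nt  # only TIR may refuse
            return
        sin_i = np.linalg.norm(np.cross(d, n))
        sin_t = np.linalg.norm(np.cross(out.direction, n))
        assert abs(nf * sin_i - nt * sin_t) <= 1e-10
        assert abs(np.linalg.norm(out.direction) - 1.0) <= 1e-12
        # transmitted direction stays in the plane of incidence
        assert abs(np.dot(out.direction, np.cross(d, n))) <= 1e-12


class TestTraceThroughDroplet:
    def test_matched_index_keeps_rays_collinear(self):
        droplet = DropletSpec(n_inside=1.4, n_outside=1.4)
        rays = make_bundle(BundleSpec(nominal_focus=np.array([1.0, 0.5, 6.0]),
                                      n_rays=100))
        out = trace_through_droplet(rays, droplet)
        assert len(out) == len(rays)
        for a, b in zip(rays, out):
            np.testing.assert_allclose(a.direction, b.direction, atol=1e-12)
            # new origin lies on the original line
            cross = np.cross(b.origin - a.origin, a.direction)
            assert np.linalg.norm(cross) < 1e-9

    def test_center_aimed_bundle_unrefracted(self, droplet):
        rays = make_bundle(BundleSpec(nominal_focus=droplet.center, n_rays=200))
        out = trace_through_droplet(rays, droplet)
        for a, b in zip(rays, out):
            np.testing.assert_allclose(a.direction, b.direction, atol=1e-12)

    def test_off_center_refraction_matches_scalar_snell(self, droplet):
        rays = make_bundle(BundleSpec(nominal_focus=np.array([2.0, 0.0, 6.5]),
                                      n_rays=64))
        out = trace_through_droplet(rays, droplet)
        changed = 0
        for a, b in zip(rays, out):
            if not b.refracted:
                continue
            n = (b.origin - droplet.center) / droplet.radius
            sin_i = np.linalg.norm(np.cross(a.direction, n))
            sin_t = np.linalg.norm(np.cross(b.direction, n))
            assert abs(droplet.n_outside * sin_i
                       - droplet.n_inside * sin_t) < 1e-10
            if np.linalg.norm(a.direction - b.direction) > 1e-9:
                changed += 1
        assert changed > 0

    def test_mirror_symmetry_of_traced_bundle(self, droplet):
        # reflecting every input ray across the x=0 plane and tracing must
        # equal reflecting the traced outputs: the droplet is axisymmetric
        from cytoprint.optics import bundle_arrays, trace_arrays

        flip = np.array([-1.0, 1.0, 1.0])
        o, d = bundle_arrays(BundleSpec(nominal_focus=np.array([1.5, 0.3, 6.0]),
                                        n_rays=100))
        to, td, _ = trace_arrays(o, d, droplet)
        mo, md, _ = trace_arrays(o * flip, d * flip, droplet)
        np.testing.assert_allclose(mo, to * flip, atol=1e-9)
        np.testing.assert_allclose(md, td * flip, atol=1e-9)
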