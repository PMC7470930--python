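"""Geometric primitives against closed-form oracles and invariances."""

import math

import numpy as np
import pytest

from spinemorph.geometry import (
    GeometryError,
    contour_area,
    dendrite_path_length,
    neck_length_from_anchors,
    object_surface_area,
    object_volume,
    path_length,
    psd_area,
    spine_density,
)
from spinemorph.trace_io import Contour

from conftest import make_contour, sphere_circle_contours, square_contour


class TestContourArea:
    def test_unit_square(self):
        assert contour_area(square_contour()) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self):
        assert contour_area(square_contour(offset=(5.0, 5.0))) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_regular_64gon_closed_form(self):
        n, r = 64, 0.5
        ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
        poly = make_contour(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        expected = 0.5 * n * r**2 * math.sin(2 * math.pi / n)
        assert contour_area(poly) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.5])
    def test_rotation_invariance(self, angle):
        pts = np.array([[0, 0], [2, 0], [2, 1], [0.5, 1.5]], dtype=float)
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        assert contour_area(make_contour(pts @ rot.T)) == pytest.approx(
            contour_area(make_contour(pts)), abs=1e-12
        )

    def test_self_intersecting_rejected(self):
        bowtie = make_contour([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError):
            contour_area(bowtie)


class TestObjectVolume:
    def test_single_slab(self):
        assert object_volume([square_contour()], 0.05) == pytest.approx(0.05)

    def test_sum_rule(self):
        c1 = square_contour(side=math.sqrt(0.2), section=0)
        c2 = square_contour(side=math.sqrt(0.3), section=1)
        assert object_volume([c1, c2], 0.04) == pytest.approx(0.020, abs=1e-12)

    def test_no_closed_contours(self):
        trace = make_contour([(0, 0), (1, 0)], closed=False)
        with pytest.raises(GeometryError):
            object_volume([trace], 0.05)

    def test_sliced_sphere_within_5pct(self):
        r = 0.3
        contours = sphere_circle_contours(r, thickness=r / 20)
        expected = 4.0 / 3.0 * math.pi * r**3
        assert object_volume(contours, r / 20) == pytest.approx(expected, rel=0.05)

    def test_thickness_ladder_converges_monotonically(self):
        r = 0.3
        expected = 4.0 / 3.0 * math.pi * r**3
        errors = []
        for t in (0.1, 0.05, 0.025):
            v = object_volume(sphere_circle_contours(r, t), t)
            errors.append(abs(v - expected) / expected)
        assert errors[0] > errors[1] > errors[2]


class TestSurfaceArea:
    def test_perimeter_times_thickness_no_caps(self):
        a = object_surface_area([square_contour()], 0.05, include_end_caps=False)
        assert a == pytest.approx(0.2, abs=1e-12)

    def test_caps_added(self):
        a = object_surface_area([square_contour()], 0.05, include_end_caps=True)
        assert a == pytest.approx(2.2, abs=1e-12)

    def test_sliced_sphere_stairstep_bias(self):
        # summed perimeter x thickness converges to the integral of the
        # circumference, pi^2 r^2 — a factor pi/4 below the true sphere area
        # 4 pi r^2.  The bias is a property of the convention, not noise.
        r = 0.3
        t = 0.005
        lateral = object_surface_area(
            sphere_circle_contours(r, t), t, include_end_caps=False
        )
        assert lateral == pytest.approx(math.pi**2 * r**2, rel=0.02)
        assert lateral < 4.0 * math.pi * r**2
        with_caps = object_surface_area(
            sphere_circle_contours(r, t), t, include_end_caps=True
        )
        assert with_caps > lateral


class TestPsdArea:
    def test_direct_formula(self):
        traces = [
            make_contour([(0, 0), (length, 0)], section=i, closed=False)
            for i, length in enumerate([0.4, 0.5, 0.4])
        ]
        assert psd_area(traces, 0.05) == pytest.approx(0.065, abs=1e-12)

    def test_single_trace(self):
        tr = make_contour([(0, 0), (1.0, 0)], closed=False)
        assert psd_area([tr], 0.04) == pytest.approx(0.04, abs=1e-12)

    def test_disc_chord_integral_convergence(self):
        # flat disc of radius rho cut into per-section chords: the summed
        # chord lengths x thickness approach pi*rho^2 as thickness -> 0
        rho = 0.3
        expected = math.pi * rho**2
        errors = []
        for t in (0.02, 0.01, 0.005):
            traces = []
            k = -math.floor(rho / t)
            while k * t < rho:
                z = k * t
                half = math.sqrt(rho**2 - z**2)
                traces.append(
                    make_contour([(-half, 0), (half, 0)], section=k + 100, closed=False)
                )
                k += 1
            errors.append(abs(psd_area(traces, t) - expected) / expected)
        assert errors[-1] < 0.01
        assert errors[0] > errors[-1]

    def test_linear_in_thickness(self):
        tr = make_contour([(0, 0), (1.0, 0)], closed=False)
        assert psd_area([tr], 0.10) == pytest.approx(2 * psd_area([tr], 0.05))


class TestPathLength:
    def test_unit_segment(self):
        assert path_length(np.array([[0, 0, 0], [1, 0, 0]])) == pytest.approx(1.0)

    def test_right_angle_additivity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert path_length(pts) == pytest.approx(2.0)

    def test_helix_arc_length(self):
        r, c, turns = 0.5, 0.2, 3.0
        t = np.linspace(0, 2 * math.pi * turns, 100)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
        expected = math.sqrt(r**2 + c**2) * 2 * math.pi * turns
        assert path_length(pts) == pytest.approx(expected, rel=0.01)

    def test_exceeds_straight_line(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        assert path_length(pts) >= np.linalg.norm(pts[-1] - pts[0])

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            path_length(np.array([[0.0, 0.0, 0.0]]))


class TestDendritePathLength:
    def _straight_stack(self, n_sections=201, thickness=0.05, offset=(0.0, 0.0)):
        return [
            square_contour(side=0.6, offset=offset, section=k, object_id="d")
            for k in range(n_sections)
        ]

    def test_straight_cylinder(self):
        # 201 sections at 0.05 µm span exactly 10 µm of collinear centroids
        length, _ = dendrite_path_length(self._straight_stack(), 0.05)
        assert length == pytest.approx(10.0, abs=1e-9)

    def test_translation_invariance(self):
        l0, _ = dendrite_path_length(self._straight_stack(), 0.05)
        l1, _ = dendrite_path_length(self._straight_stack(offset=(3.0, -2.0)), 0.05)
        assert l1 == pytest.approx(l0, abs=1e-12)

    def test_single_section_rejected(self):
        with pytest.raises(GeometryError):
            dendrite_path_length([square_contour()], 0.05)

    def test_tortuous_generated_axis_within_2pct(self, tiny_group):
        from spinemorph.geometry import measure_series

        _, truth, series, _ = tiny_group
        true_lengths = {d.dendrite_id: d.arc_length for d in truth.dendrites}
        for md, contours, hier in series:
            m = measure_series(md, contours, hier)
            for d in m.dendrites:
                assert d.path_length == pytest.approx(
                    true_lengths[d.dendrite_id], rel=0.02
                )


class TestSpineDensity:
    def test_direct(self):
        assert spine_density(13, 10.0) == pytest.approx(1.3)

    def test_zero_spines(self):
        assert spine_density(0, 8.0) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(GeometryError):
            spine_density(5, 0.0)

    def test_density_times_length_recovers_count(self):
        for n, length in [(7, 9.3), (0, 5.1), (23, 17.7)]:
            assert round(spine_density(n, length) * length) == n


class TestNeckLength:
    def test_anchor_surrogate_straight_shaft(self):
        axis = np.array([[0.0, 0.0, z] for z in np.linspace(0, 10, 201)])
        head_center = np.array([1.5, 0.0, 5.0])
        # gap = 1.5 - head_radius 0.2 - shaft_radius 0.3 = 1.0
        assert neck_length_from_anchors(head_center, 0.2, axis, 0.3) == pytest.approx(1.0)

    def test_sessile_spine_clamps_to_zero(self):
        axis = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        head_center = np.array([0.4, 0.0, 0.5])
        assert neck_length_from_anchors(head_center, 0.2, axis, 0.3) == 0.0


class TestRigidInvariance:
    def test_series_metrics_invariant_under_rotation(self, tiny_group):
        """Rotating every contour in-plane leaves all metrics unchanged."""
        from spinemorph.geometry import measure_series
        from spinemorph.trace_io import Contour

        _, _, series, _ = tiny_group
        md, contours, hier = series[0]
        angle = 0.7
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        rotated = [
            Contour(section=c.section, object_id=c.object_id,
                    points=c.points @ rot.T + np.array([2.0, 3.0]), closed=c.closed)
            for c in contours
        ]
        m0 = measure_series(md, contours, hier)
        m1 = measure_series(md, rotated, hier)
        assert m1.dendrites[0].path_length == pytest.approx(
            m0.dendrites[0].path_length, rel=1e-9
        )
        for s0, s1 in zip(m0.spines, m1.spines):
            assert s1.head_volume == pytest.approx(s0.head_volume, rel=1e-9)
            assert s1.psd_area == pytest.approx(s0.psd_area, rel=1e-9)
            assert s1.neck_length == pytest.approx(s0.neck_length, rel=1e-6, abs=1e-9)
            assert s1.perforated == s0.perforated
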