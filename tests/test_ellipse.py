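"""Conic fitting, ellipse geometry, goodness of fit and loop orientation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoloop import ellipse as el
from thermoloop.exceptions import (
    ContractViolationError,
    DegenerateDataError,
    InsufficientDataError,
)
from thermoloop.simulate import sample_ellipse


def _axis_aligned_points(a=2.0, b=1.0, n=12):
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(theta), b * np.sin(theta)])


class TestFitConic:
    def test_recovers_axis_aligned_ellipse(self):
        """x^2/4 + y^2 = 1 sampled noiselessly: coefficients proportional
        to (1/4, 0, 1, 0, 0, -1)."""
        pts = _axis_aligned_points(2.0, 1.0, 12)
        fit = el.fit_conic(pts)
        ref = np.array([0.25, 0, 1, 0, 0, -1.0])
        ref = ref / np.linalg.norm(ref)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-9)

    def test_unit_circle_is_ellipse(self):
        fit = el.fit_conic(_axis_aligned_points(1.0, 1.0, 10))
        assert fit.is_ellipse and fit.discriminant < 0

    def test_collinear_points_rejected(self):
        x = np.linspace(0, 1, 8)
        with pytest.raises(DegenerateDataError):
            el.fit_conic(np.column_stack([x, 2 * x + 1]))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            el.fit_conic(_axis_aligned_points(n=12)[:5])

    def test_zero_variance_axis_rejected(self):
        pts = np.column_stack([np.ones(8), np.linspace(0, 1, 8)])
        with pytest.raises(DegenerateDataError):
            el.fit_conic(pts)

    def test_normalization_convention(self):
        fit = el.fit_conic(_axis_aligned_points())
        assert np.linalg.norm(fit.coefficients) == pytest.approx(1.0)
        assert fit.a + fit.c > 0


class TestGeometry:
    def test_unit_circle_geometry(self):
        fit = el.fit_conic(_axis_aligned_points(1.0, 1.0, 10))
        g = el.conic_to_geometry(fit)
        assert g.center == pytest.approx((0.0, 0.0), abs=1e-9)
        assert g.semi_major == pytest.approx(1.0, abs=1e-9)
        assert g.semi_minor == pytest.approx(1.0, abs=1e-9)
        assert g.y_max_point == pytest.approx((0.0, 1.0), abs=1e-8)

    def test_round_trip_recovery(self):
        """Known rotated/translated ellipse sampled noiselessly, refit."""
        true = (39.9, 9.1, 2.1, 0.7, 0.4)
        pts = sample_ellipse(true, n=18)
        g = el.conic_to_geometry(el.fit_conic(pts))
        assert g.center == pytest.approx((39.9, 9.1), abs=1e-6)
        assert g.semi_major == pytest.approx(2.1, abs=1e-6)
        assert g.semi_minor == pytest.approx(0.7, abs=1e-6)
        assert g.rotation == pytest.approx(0.4, abs=1e-6)

    def test_tangency_points_satisfy_conic(self):
        pts = sample_ellipse((1.0, -2.0, 3.0, 1.5, -0.7), n=20)
        fit = el.fit_conic(pts)
        g = el.conic_to_geometry(fit)
        for p in (g.y_max_point, g.y_min_point, g.x_max_point, g.x_min_point):
            assert abs(el.conic_value(fit.coefficients, *p)) < 1e-8

    def test_tangency_against_dense_parametric_oracle(self):
        pts = sample_ellipse((5.0, 3.0, 2.5, 1.2, 0.9), n=24)
        g = el.conic_to_geometry(el.fit_conic(pts))
        dense = g.point_at(np.linspace(0, 2 * np.pi, 100_000, endpoint=False))
        assert g.y_max_point[1] >= dense[:, 1].max() - 1e-9
        assert abs(g.y_max_point[1] - dense[:, 1].max()) < 1e-6
        assert abs(g.x_max_point[0] - dense[:, 0].max()) < 1e-6
        assert abs(g.y_min_point[1] - dense[:, 1].min()) < 1e-6
        assert abs(g.x_min_point[0] - dense[:, 0].min()) < 1e-6

    def test_scale_invariance_of_coefficients(self):
        pts = sample_ellipse((0.0, 0.0, 2.0, 1.0, 0.3), n=12)
        fit = el.fit_conic(pts)
        scaled = el.ConicFit(*(3.7 * fit.coefficients / np.linalg.norm(3.7 * fit.coefficients)),
                             n_points=fit.n_points)
        g1, g2 = el.conic_to_geometry(fit), el.conic_to_geometry(scaled)
        assert g1.center == pytest.approx(g2.center, abs=1e-10)
        assert g1.semi_major == pytest.approx(g2.semi_major, abs=1e-10)

    def test_equivariance_under_rigid_motion(self, rng):
        base = sample_ellipse((2.0, 1.0, 1.8, 0.9, 0.2), n=18, noise_sd=0.02, rng=rng)
        g0 = el.conic_to_geometry(el.fit_conic(base), time_order=base)
        r2_0 = el.ellipse_r2(base, el.fit_conic(base))
        phi, tx, ty = 0.6, 4.0, -2.5
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        moved = base @ rot.T + np.array([tx, ty])
        g1 = el.conic_to_geometry(el.fit_conic(moved), time_order=moved)
        r2_1 = el.ellipse_r2(moved, el.fit_conic(moved))
        expected_center = rot @ np.array(g0.center) + np.array([tx, ty])
        assert g1.center == pytest.approx(tuple(expected_center), abs=1e-8)
        assert g1.semi_major == pytest.approx(g0.semi_major, abs=1e-8)
        assert g1.semi_minor == pytest.approx(g0.semi_minor, abs=1e-8)
        assert g1.direction == g0.direction
        assert r2_1.sampson == pytest.approx(r2_0.sampson, abs=1e-8)

    def test_requires_ellipse(self):
        hyperbola = el.ConicFit(*el._normalize_coef(np.array([1.0, 0, -1.0, 0, 0, -1.0])), n_points=8)
        with pytest.raises(ContractViolationError):
            el.conic_to_geometry(hyperbola)


def _brute_force_response_r2(pts, coef, geometry):
    """Independent naive reimplementation of the responding-variable R^2."""
    a, b, c, d, e, f = coef
    x_lo, x_hi = geometry.x_min_point[0], geometry.x_max_point[0]
    residuals = []
    for xi, yi in pts:
        if xi < x_lo:
            pred = geometry.x_min_point[1]
        elif xi > x_hi:
            pred = geometry.x_max_point[1]
        else:
            qa, qb, qc = c, b * xi + e, a * xi * xi + d * xi + f
            disc = max(qb * qb - 4 * qa * qc, 0.0)
            r = math.sqrt(disc)
            lo, hi = sorted([(-qb - r) / (2 * qa), (-qb + r) / (2 * qa)])
            pred = hi if abs(yi - hi) <= abs(yi - lo) else lo
        residuals.append((yi - pred) ** 2)
    ybar = sum(y for _, y in pts) / len(pts)
    ss_tot = sum((y - ybar) ** 2 for _, y in pts)
    return 1.0 - sum(residuals) / ss_tot


class TestGoodnessOfFit:
    def test_noiseless_fit_is_perfect(self):
        pts = sample_ellipse((1.0, 2.0, 2.0, 1.0, 0.5), n=16)
        fit = el.fit_conic(pts)
        r2 = el.ellipse_r2(pts, fit)
        assert r2.response == pytest.approx(1.0, abs=1e-9)
        assert r2.sampson == pytest.approx(1.0, abs=1e-9)

    def test_heavy_noise_degrades_r2(self, rng):
        pts = sample_ellipse((0.0, 0.0, 2.0, 1.0, 0.0), n=40, noise_sd=1.5, rng=rng)
        try:
            fit = el.fit_conic(pts)
        except Exception:
            return  # structure fully swamped; nothing left to assert
        r2 = el.ellipse_r2(pts, fit)
        assert r2.response < 0.9

    def test_matches_brute_force_oracle(self, rng):
        pts = sample_ellipse((39.9, 9.1, 2.1, 0.7, 0.4), n=18, noise_sd=0.1, rng=rng)
        fit = el.fit_conic(pts)
        geom = el.conic_to_geometry(fit)
        r2 = el.ellipse_r2(pts, fit, geom)
        oracle = _brute_force_response_r2(pts, fit.coefficients, geom)
        assert r2.response == pytest.approx(oracle, abs=1e-12)

    def test_zero_sstot_flagged(self):
        pts = sample_ellipse((0.0, 0.0, 2.0, 1.0, 0.0), n=12)
        fit = el.fit_conic(pts)
        flat = np.column_stack([pts[:, 0], np.zeros(len(pts))])
        r2 = el.ellipse_r2(flat, fit)
        assert r2.undefined and math.isnan(r2.response)


class TestTraversalDirection:
    def test_square_orientation(self):
        square = [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert el.traversal_direction(square) == "clockwise"
        assert el.traversal_direction(square[::-1]) == "counterclockwise"

    def test_circle_quadrant_order(self):
        ccw = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        assert el.traversal_direction(ccw) == "counterclockwise"
        assert el.traversal_direction(ccw[::-1]) == "clockwise"

    def test_collinear_undetermined(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 3)]
        assert el.traversal_direction(pts) == "undetermined"

    @given(
        n=st.integers(6, 30),
        phase=st.floats(0, 2 * math.pi),
        noise=st.floats(0, 0.05),
        seed=st.integers(0, 2**16),
    )
    def test_antisymmetry_under_time_reversal(self, n, phase, noise, seed):
        pts = sample_ellipse(
            (0.0, 0.0, 2.0, 1.0, 0.3),
            n=n,
            noise_sd=noise,
            rng=np.random.default_rng(seed),
            theta0=phase,
        )
        fwd = el.traversal_direction(pts)
        rev = el.traversal_direction(pts[::-1])
        flip = {"clockwise": "counterclockwise", "counterclockwise": "clockwise"}
        assert rev == flip[fwd]


class TestDescribeEllipse:
    def test_one_call_summary(self):
        pts = sample_ellipse((39.9, 9.1, 2.1, 0.7, 0.4), n=18, direction="clockwise")
        g = el.describe_ellipse(pts)
        assert g.direction == "clockwise"
        assert g.r2.response == pytest.approx(1.0, abs=1e-9)

    def test_json_serialization(self):
        pts = sample_ellipse((1.0, 1.0, 2.0, 1.0, 0.1), n=12)
        import json

        payload = json.loads(el.fit_to_json(pts, x_name="rt", y_name="dmi"))
        assert payload["x_name"] == "rt"
        assert payload["discriminant"] < 0
        assert set("abcdef") == set(payload["coefficients"])
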