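"""Debye intensities, Guinier analysis and chi-square fitting."""

import numpy as np
import pytest

from flexsaxs.saxs import (SAXSProfile, chi2_fit, debye_intensity,
                           ensemble_intensity, guinier_fit, interpolate_to)
from flexsaxs.topology import radius_of_gyration

from .conftest import random_rigid_transform


def naive_debye(coords, q_grid, f):
    """Literal double-loop Debye sum (oracle)."""
    n = len(coords)
    out = np.zeros(len(q_grid))
    for iq, q in enumerate(q_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                r = np.linalg.norm(coords[i] - coords[j])
                x = q * r
                sinc = 1.0 if x < 1e-12 else np.sin(x) / x
                total += f[i] * f[j] * sinc
        out[iq] = total
    return out


class TestDebyeIntensity:
    def test_single_bead_constant(self):
        q = np.linspace(0.0, 0.5, 10)
        prof = debye_intensity(np.zeros((1, 3)), q, form_factors=2.0)
        np.testing.assert_allclose(prof.intensity, 4.0)

    def test_two_bead_closed_form(self):
        q = np.linspace(0.0, 0.5, 50)
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        prof = debye_intensity(coords, q)
        with np.errstate(invalid="ignore"):
            expected = 2 * (1 + np.sinc(10 * q / np.pi))
        assert prof.intensity[0] == pytest.approx(4.0)
        np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        coords = rng.uniform(-20, 20, (8, 3))
        f = rng.uniform(0.5, 2.0, 8)
        q = np.linspace(0.0, 0.4, 25)
        prof = debye_intensity(coords, q, form_factors=f)
        np.testing.assert_allclose(prof.intensity, naive_debye(coords, q, f),
                                   rtol=1e-10)

    def test_rotation_translation_invariance(self, rng):
        coords = rng.uniform(-15, 15, (20, 3))
        q = np.linspace(0.01, 0.3, 30)
        rot, shift = random_rigid_transform(rng)
        a = debye_intensity(coords, q).intensity
        b = debye_intensity(coords @ rot.T + shift, q).intensity
        np.testing.assert_allclose(b, a, rtol=1e-9)

    def test_forward_intensity_is_total_scattering_squared(self, rng):
        coords = rng.uniform(-10, 10, (12, 3))
        f = rng.uniform(0.5, 3.0, 12)
        prof = debye_intensity(coords, np.array([0.0]), form_factors=f)
        assert prof.intensity[0] == pytest.approx(f.sum() ** 2, rel=1e-12)

    def test_empty_conformation_rejected(self):
        with pytest.raises(ValueError):
            debye_intensity(np.zeros((0, 3)), np.linspace(0, 1, 5))


class TestChi2Fit:
    def test_identical_profiles(self):
        q = np.linspace(0.01, 0.3, 40)
        i = 100 * np.exp(-(q * 20) ** 2 / 3)
        target = SAXSProfile(q, i, np.ones_like(q))
        res = chi2_fit(target, SAXSProfile(q, i))
        assert res.scale == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_proportional_model(self):
        q = np.linspace(0.01, 0.3, 40)
        i = 100 * np.exp(-(q * 20) ** 2 / 3)
        target = SAXSProfile(q, i, np.ones_like(q))
        res = chi2_fit(target, SAXSProfile(q, 2 * i))
        assert res.scale == pytest.approx(0.5)
        assert res.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_scale_matches_dense_grid_search(self, rng):
        q = np.linspace(0.01, 0.3, 50)
        for _ in range(10):
            target_i = rng.uniform(1, 10, 50)
            model_i = rng.uniform(1, 10, 50)
            sigma = rng.uniform(0.1, 1.0, 50)
            target = SAXSProfile(q, target_i, sigma)
            res = chi2_fit(target, SAXSProfile(q, model_i))
            scales = np.linspace(max(res.scale - 0.5, 1e-3), res.scale + 0.5,
                                 20001)
            chis = np.array([
                np.sum(((target_i - a * model_i) / sigma) ** 2) for a in scales
            ]) / 50
            k = np.argmin(chis)
            assert res.scale == pytest.approx(scales[k], abs=1e-4)
            assert res.chi2 <= chis[k] + 1e-12

    def test_optimality_of_closed_form_scale(self, rng):
        q = np.linspace(0.01, 0.3, 30)
        target = SAXSProfile(q, rng.uniform(1, 5, 30), rng.uniform(0.1, 1, 30))
        model = SAXSProfile(q, rng.uniform(1, 5, 30))
        res = chi2_fit(target, model)
        for a in res.scale * rng.uniform(0.5, 1.5, 50):
            alt = np.sum(((target.intensity - a * model.intensity)
                          / target.sigma) ** 2) / 30
            assert res.chi2 <= alt + 1e-12

    def test_zero_model_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        target = SAXSProfile(q, np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            chi2_fit(target, SAXSProfile(q, np.zeros(10)))

    def test_extrapolation_forbidden(self):
        target = SAXSProfile(np.linspace(0.01, 0.4, 20), np.ones(20),
                             np.ones(20))
        model = SAXSProfile(np.linspace(0.05, 0.3, 20), np.ones(20))
        with pytest.raises(ValueError, match="extrapolation"):
            chi2_fit(target, model)

    def test_interpolated_grid_fit(self):
        q_model = np.linspace(0.005, 0.45, 2000)
        i_model = 50 * np.exp(-(q_model * 25) ** 2 / 3)
        q_target = np.linspace(0.01, 0.4, 37)
        i_target = 50 * np.exp(-(q_target * 25) ** 2 / 3)
        target = SAXSProfile(q_target, i_target, 0.01 * i_target)
        res = chi2_fit(target, SAXSProfile(q_model, i_model))
        assert res.scale == pytest.approx(1.0, rel=1e-3)
        assert res.chi2 < 0.05  # only interpolation error remains


class TestEnsembleIntensity:
    def test_single_profile_identity(self):
        q = np.linspace(0.01, 0.2, 10)
        p = SAXSProfile(q, np.arange(10.0) + 1)
        out = ensemble_intensity([p], [1.0])
        np.testing.assert_allclose(out.intensity, p.intensity)

    def test_mean_of_identical_profiles(self):
        q = np.linspace(0.01, 0.2, 10)
        p = SAXSProfile(q, np.arange(10.0) + 1)
        out = ensemble_intensity([p, p], [0.5, 0.5])
        np.testing.assert_allclose(out.intensity, p.intensity)

    def test_fifty_fifty_mixture_arithmetic(self):
        q = np.linspace(0.01, 0.2, 5)
        p1 = SAXSProfile(q, np.full(5, 1.0))
        p2 = SAXSProfile(q, np.full(5, 3.0))
        out = ensemble_intensity([p1, p2], [0.5, 0.5])
        np.testing.assert_allclose(out.intensity, 2.0)

    def test_weight_length_mismatch(self):
        q = np.linspace(0.01, 0.2, 5)
        p = SAXSProfile(q, np.ones(5))
        with pytest.raises(ValueError):
            ensemble_intensity([p, p], [1.0])


class TestGuinier:
    def test_exact_gaussian_recovery(self):
        q = np.linspace(0.001, 0.1, 150)
        prof = SAXSProfile(q, 100 * np.exp(-(q * 43) ** 2 / 3))
        res = guinier_fit(prof)
        assert res.rg == pytest.approx(43.0, rel=1e-3)
        assert res.i0 == pytest.approx(100.0, rel=1e-3)
        assert res.qmax_rg <= 1.3 + 1e-9

    def test_uniform_sphere_debye_profile(self):
        # deterministic lattice filling of a ball: coordinate Rg matches
        # the continuum sqrt(3/5) R closely, so Guinier bias is isolated
        radius = 30.0
        grid = np.arange(-radius, radius + 1e-9, 3.0)
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        q = np.linspace(0.002, 0.1, 50)
        res = guinier_fit(debye_intensity(pts, q))
        assert res.rg == pytest.approx(np.sqrt(3 / 5) * radius, rel=0.02)

    def test_low_q_agreement_with_coordinate_rg(self, rng):
        # globular cloud: Guinier Rg tracks the direct coordinate Rg
        pts = rng.standard_normal((200, 3)) * 8.0
        q = np.linspace(0.002, 0.15, 100)
        res = guinier_fit(debye_intensity(pts, q))
        assert res.rg == pytest.approx(radius_of_gyration(pts), rel=0.03)

    def test_window_starts_too_high(self):
        q = np.linspace(0.05, 0.2, 30)
        prof = SAXSProfile(q, 100 * np.exp(-(q * 43) ** 2 / 3))
        with pytest.raises(ValueError, match="window"):
            guinier_fit(prof)


class TestProfileValidation:
    def test_decreasing_q_rejected(self):
        with pytest.raises(ValueError):
            SAXSProfile(np.array([0.2, 0.1]), np.ones(2))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            SAXSProfile(np.array([0.1, 0.2]), np.ones(2), np.array([1.0, 0.0]))
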