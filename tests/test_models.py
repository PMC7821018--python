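"""Orientation models, their algebraic identities and TR attenuation."""

import numpy as np
import pytest

from mworient import (
    ModelCoefficients,
    OrientationR2Model,
    TrAttenuationParams,
    apparent_mwf_vs_tr,
    fit_orientation_model,
    magic_angle,
    model_identity_transform,
    true_mwf_from_apparent,
)

THETA = np.arange(2.5, 90.0, 5.0)  # 18 bin centers


def knight_curve(a, b, c, theta=THETA):
    s2 = np.sin(np.deg2rad(theta)) ** 2
    return a + b * s2 + c * s2**2


class TestModelFits:
    def test_knight_recovers_exact_coefficients(self):
        r2 = knight_curve(12.0, 2.0, 1.0)
        coeffs = fit_orientation_model(THETA, r2, "knight")
        assert coeffs.a == pytest.approx(12.0, abs=1e-10)
        assert coeffs.b == pytest.approx(2.0, abs=1e-10)
        assert coeffs.c == pytest.approx(1.0, abs=1e-10)
        assert coeffs.rss == pytest.approx(0.0, abs=1e-18)

    def test_dipole_and_sin2_fits_superimpose(self, rng):
        # the dipole model is an affine function of sin^2, so both fits
        # produce the same curve on any data
        r2 = 15.0 + rng.normal(0, 0.5, THETA.size)
        fit_d = fit_orientation_model(THETA, r2, "dipole")
        fit_s = fit_orientation_model(THETA, r2, "sin2_only")
        assert np.allclose(fit_d.predict(THETA), fit_s.predict(THETA), atol=1e-10)
        assert fit_d.rss == pytest.approx(fit_s.rss, abs=1e-12)

    def test_knight_fit_of_squared_dipole_data(self):
        # data from a + b (3cos^2 - 1)^2 with (10, 1) refits as (14, -12, 9)
        c2 = np.cos(np.deg2rad(THETA)) ** 2
        r2 = 10.0 + 1.0 * (3 * c2 - 1) ** 2
        coeffs = fit_orientation_model(THETA, r2, "knight")
        assert coeffs.a == pytest.approx(14.0, abs=1e-9)
        assert coeffs.b == pytest.approx(-12.0, abs=1e-9)
        assert coeffs.c == pytest.approx(9.0, abs=1e-9)

    def test_nested_model_rss_inequality(self, rng):
        r2 = knight_curve(12.0, 2.0, 1.0) + rng.normal(0, 0.3, THETA.size)
        rss_knight = fit_orientation_model(THETA, r2, "knight").rss
        rss_sq = fit_orientation_model(THETA, r2, "dipole_squared").rss
        assert rss_knight <= rss_sq + 1e-12

    def test_weighted_fit_uses_counts(self):
        r2 = knight_curve(12.0, 2.0, 1.0)
        r2_noisy = r2.copy()
        r2_noisy[0] += 10.0  # corrupt the first bin
        w = np.ones(THETA.size)
        w[0] = 1e-9  # ...but give it negligible weight
        coeffs = fit_orientation_model(THETA, r2_noisy, "knight", weights=w)
        assert coeffs.a == pytest.approx(12.0, abs=1e-4)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_orientation_model(THETA[:2], np.ones(2), "knight")

    def test_missing_bins_are_dropped(self):
        r2 = knight_curve(12.0, 2.0, 1.0)
        r2[5] = np.nan
        coeffs = fit_orientation_model(THETA, r2, "knight")
        assert coeffs.n_points == 17
        assert coeffs.a == pytest.approx(12.0, abs=1e-9)

    def test_estimator_api(self):
        est = OrientationR2Model(model="dipole")
        est.fit(THETA, knight_curve(7.0, -3.0, 0.0))
        pred = est.predict(THETA)
        assert np.allclose(pred, knight_curve(7.0, -3.0, 0.0), atol=1e-10)
        assert est.get_params()["model"] == "dipole"


class TestIdentities:
    def test_dipole_rewrite(self):
        c = ModelCoefficients("dipole", a=5.0, b=1.0, c=None, rss=0.0, n_points=18)
        k = model_identity_transform(c)
        assert (k.a, k.b, k.c) == (7.0, -3.0, 0.0)

    def test_dipole_squared_rewrite(self):
        c = ModelCoefficients("dipole_squared", a=0.0, b=1.0, c=None, rss=0.0, n_points=18)
        k = model_identity_transform(c)
        assert (k.a, k.b, k.c) == (4.0, -12.0, 9.0)

    def test_zero_orientation_term(self):
        c = ModelCoefficients("dipole", a=5.0, b=0.0, c=None, rss=0.0, n_points=18)
        k = model_identity_transform(c)
        assert (k.a, k.b, k.c) == (5.0, 0.0, 0.0)

    @pytest.mark.parametrize("model,a,b", [("dipole", 5.0, 1.3), ("dipole_squared", 2.0, 0.7)])
    def test_transform_preserves_curve_everywhere(self, model, a, b):
        c = ModelCoefficients(model, a=a, b=b, c=None, rss=0.0, n_points=18)
        theta = np.linspace(0.0, 90.0, 181)
        assert np.allclose(c.predict(theta), model_identity_transform(c).predict(theta), atol=1e-12)


class TestMagicAngle:
    def test_value(self):
        assert magic_angle() == pytest.approx(54.7356, abs=1e-4)
        assert round(magic_angle(), 1) == 54.7

    def test_dipolar_term_vanishes(self):
        term = 3 * np.cos(np.deg2rad(magic_angle())) ** 2 - 1
        assert abs(term) < 1e-12

    def test_dipole_model_reduces_to_baseline(self):
        c = ModelCoefficients("dipole", a=9.0, b=2.0, c=None, rss=0.0, n_points=18)
        assert c.predict(np.array([magic_angle()]))[0] == pytest.approx(9.0, abs=1e-12)


class TestTrAttenuation:
    def test_infinite_tr_returns_true_fraction(self):
        p = TrAttenuationParams(true_mwf=0.1)
        assert apparent_mwf_vs_tr(p, 1e9) == pytest.approx(0.1, abs=1e-12)

    def test_myelin_water_nearly_relaxed_at_shortest_tr(self):
        e_mw = 1.0 - np.exp(-1073.0 / 200.0)
        assert e_mw == pytest.approx(0.99532, abs=1e-5)
        assert e_mw > 0.995  # "almost fully relaxed" at the shortest TR

    def test_apparent_exceeds_true_and_decreases_with_tr(self):
        p = TrAttenuationParams(true_mwf=0.1)
        apps = [apparent_mwf_vs_tr(p, tr) for tr in (1073.0, 1500.0, 2000.0, 5000.0)]
        assert all(a > 0.1 for a in apps[:3])
        assert np.all(np.diff(apps) < 0)

    def test_calibration_roundtrip(self):
        f = true_mwf_from_apparent(0.079, 1073.0)
        assert apparent_mwf_vs_tr(TrAttenuationParams(true_mwf=f), 1073.0) == pytest.approx(0.079, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            TrAttenuationParams(true_mwf=1.5)
        with pytest.raises(ValueError):
            TrAttenuationParams(true_mwf=0.1, t1_mw_ms=1200.0)
        with pytest.raises(ValueError):
            apparent_mwf_vs_tr(TrAttenuationParams(true_mwf=0.1), -5.0)
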