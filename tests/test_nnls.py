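"""Spectrum inversion: basis construction, regularization, recovery."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from mworient import (
    RelaxParams,
    SequenceParams,
    T2Grid,
    T2SpectrumNNLS,
    build_basis,
    epg_echo_amplitudes,
    epg_echo_amplitudes_multi,
    fit_spectrum,
)


def two_pool_decay(seq, f_mw=0.15, t2_mw=10.0, t2_ie=80.0, alpha=160.0):
    mw = epg_echo_amplitudes_multi(seq, [t2_mw], alpha_deg=alpha)[:, 0]
    ie = epg_echo_amplitudes_multi(seq, [t2_ie], alpha_deg=alpha)[:, 0]
    return f_mw * mw + (1.0 - f_mw) * ie


class TestBasis:
    def test_mono_exponential_columns_at_180(self, seq48):
        grid = T2Grid(np.array([20.0, 80.0]))
        basis = build_basis(seq48, grid, 180.0)
        n = np.arange(1, 49)
        assert np.allclose(basis[:, 0], np.exp(-8.0 * n / 20.0), atol=1e-10)
        assert np.allclose(basis[:, 1], np.exp(-8.0 * n / 80.0), atol=1e-10)

    def test_entries_bounded(self, seq48, grid40):
        for alpha in (100.0, 137.5, 180.0):
            basis = build_basis(seq48, grid40, alpha)
            assert np.all(basis >= 0.0) and np.all(basis <= 1.0)

    def test_shortest_t2_first_entry(self, seq48):
        # T2 = TE = 8 ms at perfect refocusing: first echo is exp(-1)
        grid = T2Grid(np.array([8.0, 2000.0]))
        basis = build_basis(seq48, grid, 180.0)
        assert basis[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-10)

    def test_columns_match_single_curve_api(self, seq48):
        grid = T2Grid(np.array([15.0, 60.0, 300.0]))
        basis = build_basis(seq48, grid, 155.0)
        for j, t2 in enumerate(grid.t2_ms):
            single = epg_echo_amplitudes(
                SequenceParams(n_echoes=48, te_ms=8.0, tr_ms=1073.0, refocus_deg=155.0),
                RelaxParams(t2_ms=t2, t1_ms=1000.0),
            )
            assert np.allclose(basis[:, j], single, atol=1e-12)


class TestFitSpectrum:
    def test_noiseless_single_pool_recovery(self, seq48):
        decay = epg_echo_amplitudes_multi(seq48, [20.0], alpha_deg=180.0)[:, 0]
        spec = fit_spectrum(decay, seq48)
        t2 = spec.grid.t2_ms
        below = t2[t2 <= 20.0][-1]
        above = t2[t2 >= 20.0][0]
        bracket = (t2 >= below) & (t2 <= above)
        assert spec.amplitudes[bracket].sum() / spec.total >= 0.99
        assert spec.amplitudes[t2 <= 25.0].sum() / spec.total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("search", ["grid", "golden"])
    def test_noiseless_two_pool_recovery(self, seq48, search):
        decay = two_pool_decay(seq48)
        spec = fit_spectrum(decay, seq48, alpha_search=search)
        t2 = spec.grid.t2_ms
        mwf = spec.amplitudes[t2 <= 25.0].sum() / spec.total
        assert mwf == pytest.approx(0.15, abs=0.02)
        assert spec.chosen_alpha_deg == pytest.approx(160.0, abs=5.0)

    def test_all_zero_decay_rejected(self, seq48):
        with pytest.raises(ValueError, match="zero"):
            fit_spectrum(np.zeros(48), seq48)

    def test_negative_decay_rejected(self, seq48):
        bad = np.ones(48)
        bad[5] = -0.1
        with pytest.raises(ValueError):
            fit_spectrum(bad, seq48)

    def test_wrong_length_rejected(self, seq48):
        with pytest.raises(ValueError):
            fit_spectrum(np.ones(32), seq48)


class TestRegularization:
    def test_chi2_ratio_hits_target_within_one_percent(self, seq48, rng):
        decay = two_pool_decay(seq48)
        sigma = decay[0] / 100.0
        noisy = np.abs(decay + rng.normal(0, sigma, 48))
        for factor in (1.005, 1.02):
            spec = fit_spectrum(noisy, seq48, reg_factor=factor)
            seqp = SequenceParams(n_echoes=48, te_ms=8.0, tr_ms=1073.0)
            basis = build_basis(seqp, spec.grid, spec.chosen_alpha_deg)
            _, rnorm = scipy_nnls(basis, noisy)
            ratio = spec.residual_norm**2 / rnorm**2
            assert ratio == pytest.approx(factor, rel=0.01)
            assert spec.residual_norm**2 >= rnorm**2  # regularization can't fit better

    def test_amplitudes_nonnegative_under_noise(self, seq48, rng):
        decay = two_pool_decay(seq48)
        sigma = decay[0] / 50.0
        noisy = np.abs(decay + rng.normal(0, sigma, (20, 48)))
        est = T2SpectrumNNLS().fit(noisy)
        assert np.all(est.amplitudes_ >= 0.0)

    def test_reconstruction_error_at_noise_level(self, seq48, rng):
        decay = two_pool_decay(seq48)
        sigma = decay[0] / 100.0
        noisy = np.abs(decay + rng.normal(0, sigma, 48))
        spec = fit_spectrum(noisy, seq48)
        seqp = SequenceParams(n_echoes=48, te_ms=8.0, tr_ms=1073.0)
        basis = build_basis(seqp, spec.grid, spec.chosen_alpha_deg)
        resid_rms = np.sqrt(np.mean((basis @ spec.amplitudes - noisy) ** 2))
        assert resid_rms <= 2.0 * sigma


class TestParameterRecovery:
    def test_mean_mwf_and_alpha_recovery_100_voxels(self, seq48):
        # two-pool voxels at SNR 100 (first echo), effective flip angle 160
        rng = np.random.default_rng(7)
        decay = two_pool_decay(seq48)
        sigma = decay[0] / 100.0
        re = decay + rng.normal(0, sigma, (100, 48))
        im = rng.normal(0, sigma, (100, 48))
        noisy = np.sqrt(re**2 + im**2)
        est = T2SpectrumNNLS(rician_correction=True).fit(noisy)
        t2 = est.grid_.t2_ms
        mwf = est.amplitudes_[:, t2 <= 25.0].sum(axis=1) / est.amplitudes_.sum(axis=1)
        assert abs(mwf.mean() - 0.15) <= 0.01
        assert abs(est.alpha_deg_.mean() - 160.0) <= 2.0

    def test_grid_and_golden_search_agree(self, seq48, rng):
        decay = two_pool_decay(seq48, alpha=147.0)
        sigma = decay[0] / 200.0
        noisy = np.abs(decay + rng.normal(0, sigma, 48))
        s_grid = fit_spectrum(noisy, seq48, alpha_search="grid")
        s_gold = fit_spectrum(noisy, seq48, alpha_search="golden")
        assert s_grid.chosen_alpha_deg == pytest.approx(s_gold.chosen_alpha_deg, abs=2.0)


class TestEstimatorAPI:
    def test_get_set_params_roundtrip(self):
        est = T2SpectrumNNLS()
        params = est.get_params()
        est2 = T2SpectrumNNLS(**params).set_params(reg_factor=1.02)
        assert est2.get_params()["reg_factor"] == 1.02
        with pytest.raises(ValueError):
            est2.set_params(not_a_param=1)

    def test_fit_transform_matches_attributes(self, seq48):
        decay = two_pool_decay(seq48)
        est = T2SpectrumNNLS()
        spectra = est.fit_transform(np.vstack([decay, decay]))
        assert spectra.shape == (2, 40)
        assert np.allclose(spectra[0], spectra[1])
        assert np.allclose(spectra, est.amplitudes_)
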