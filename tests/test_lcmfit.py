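"""Linear-combination fitting tests: exact recovery, broadening recovery,
CRLB calibration and validity, water referencing, pairs and reliability."""

import numpy as np
import pytest

from fmrsglu import (
    AcquisitionParams,
    DataError,
    FitConfig,
    build_default_basis,
    combine_pairs,
    filter_reliable,
    fit_spectrum,
    spectrum,
    synthesize_fid,
    water_reference_scale,
)
from fmrsglu.lcmfit import FitResult
from fmrsglu.synthdata import DEFAULT_CONCENTRATIONS


@pytest.fixture(scope="module")
def cfg():
    return FitConfig(basis_fwhm=9.72)


def _noisy_spec(params, basis, conc, fwhm, sigma, rng, n_avg=1):
    fid = n_avg * synthesize_fid(basis, conc, fwhm, params)
    noise = sigma * np.sqrt(n_avg) * (
        rng.standard_normal(params.n_points)
        + 1j * rng.standard_normal(params.n_points))
    return spectrum(fid + noise, params)


class TestExactRecovery:
    def test_single_metabolite_noiseless(self, params, basis, cfg):
        spec = spectrum(synthesize_fid(basis, {"Glu": 10.0}, 9.72, params),
                        params)
        fit = fit_spectrum(spec, basis, cfg, params)
        assert fit.amplitudes["Glu"] == pytest.approx(10.0, rel=1e-3)
        others = [v for m, v in fit.amplitudes.items() if m != "Glu"]
        assert max(others) < 0.01 * fit.amplitudes["Glu"]

    def test_two_metabolite_mixture_noiseless(self, params, basis, cfg):
        spec = spectrum(
            synthesize_fid(basis, {"Glu": 10.0, "Cr": 8.0}, 9.72, params),
            params)
        fit = fit_spectrum(spec, basis, cfg, params)
        assert fit.amplitudes["Glu"] == pytest.approx(10.0, rel=5e-3)
        # Cr/PCr are nearly collinear; their sum is the identified quantity
        assert fit.amplitudes["Cr"] + fit.amplitudes["PCr"] == \
            pytest.approx(8.0, rel=5e-3)

    def test_full_panel_noiseless(self, params, basis, cfg):
        """All panel amplitudes with >= 5 % share recovered to 0.1 %."""
        spec = spectrum(
            synthesize_fid(basis, DEFAULT_CONCENTRATIONS, 9.72, params),
            params)
        fit = fit_spectrum(spec, basis, cfg, params)
        for m, truth in DEFAULT_CONCENTRATIONS.items():
            if m in ("Cr", "PCr", "GPC", "PCho"):
                continue  # identified via their sums
            assert fit.amplitudes[m] == pytest.approx(truth, rel=2e-3), m
        assert fit.amplitudes["Cr"] + fit.amplitudes["PCr"] == \
            pytest.approx(8.0, rel=2e-3)
        assert fit.amplitudes["GPC"] + fit.amplitudes["PCho"] == \
            pytest.approx(1.3, rel=2e-3)

    def test_injected_broadening_recovered(self, params, basis, cfg):
        spec = spectrum(
            synthesize_fid(basis, DEFAULT_CONCENTRATIONS, 9.72 + 2.0, params),
            params)
        fit = fit_spectrum(spec, basis, cfg, params)
        assert fit.global_extra_fwhm == pytest.approx(2.0, abs=0.2)


class TestCrlb:
    def test_noiseless_crlb_vanishes(self, params, basis, cfg):
        spec = spectrum(
            synthesize_fid(basis, DEFAULT_CONCENTRATIONS, 9.72, params),
            params)
        fit = fit_spectrum(spec, basis, cfg, params)
        assert fit.crlb_pct["Glu"] < 0.01

    def test_binned_glu_crlb_in_study_range(self, params, basis, cfg, rng):
        """4-average bins at the default SNR-10 calibration give glutamate
        CRLBs in the 6-11 % range reported for this protocol."""
        from fmrsglu import GroundTruth
        sigma = GroundTruth().resolved_noise_sd(params, basis)
        conc = {k: v * (1 - 0.0816) for k, v in DEFAULT_CONCENTRATIONS.items()}
        crlbs = []
        for _ in range(3):
            spec = _noisy_spec(params, basis, conc, 9.72, sigma, rng, n_avg=4)
            fit = fit_spectrum(spec, basis, cfg, params, n_averages=4)
            crlbs.append(fit.crlb_pct["Glu"])
        assert 6.0 <= np.mean(crlbs) <= 11.0

    def test_doubling_averages_scales_crlb(self, params, basis, cfg, rng):
        """Summing two equal-signal spectra cuts CRLB% by ~1/sqrt(2)."""
        from fmrsglu import GroundTruth
        sigma = GroundTruth().resolved_noise_sd(params, basis)
        ratios = []
        for _ in range(5):
            s1 = _noisy_spec(params, basis, DEFAULT_CONCENTRATIONS, 9.72,
                             sigma, rng, n_avg=4)
            s2 = _noisy_spec(params, basis, DEFAULT_CONCENTRATIONS, 9.72,
                             sigma, rng, n_avg=8)
            f1 = fit_spectrum(s1, basis, cfg, params, n_averages=4)
            f2 = fit_spectrum(s2, basis, cfg, params, n_averages=8)
            ratios.append(f2.crlb_pct["Glu"] / f1.crlb_pct["Glu"])
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(2), rel=0.10)

    def test_crlb_matches_monte_carlo_sd(self, params, basis, cfg):
        """Empirical SD of the glutamate estimate across noise realizations
        lies within [0.7, 1.5]x the mean reported CRLB."""
        from fmrsglu import GroundTruth
        sigma = GroundTruth().resolved_noise_sd(params, basis)
        rng = np.random.default_rng(991)
        est, crlb = [], []
        for _ in range(60):
            spec = _noisy_spec(params, basis, DEFAULT_CONCENTRATIONS, 9.72,
                               sigma, rng, n_avg=8)
            fit = fit_spectrum(spec, basis, cfg, params, n_averages=8,
                               fast=True)
            est.append(fit.amplitudes["Glu"] / 8)
            crlb.append(fit.crlb_pct["Glu"])
        emp_sd_pct = 100 * np.std(est, ddof=1) / DEFAULT_CONCENTRATIONS["Glu"]
        ratio = emp_sd_pct / np.mean(crlb)
        assert 0.7 <= ratio <= 1.5

    def test_crlb_monotone_in_noise(self, params, basis, cfg, rng):
        from fmrsglu import GroundTruth
        sigma0 = GroundTruth().resolved_noise_sd(params, basis)
        crlbs = []
        for mult in (0.5, 1.0, 2.0):
            spec = _noisy_spec(params, basis, DEFAULT_CONCENTRATIONS, 9.72,
                               sigma0 * mult, rng, n_avg=4)
            fit = fit_spectrum(spec, basis, cfg, params, fast=True)
            crlbs.append(fit.crlb_pct["Glu"])
        assert crlbs[0] < crlbs[1] < crlbs[2]


class TestWaterReferenceScale:
    def _fit(self):
        return FitResult(amplitudes={"Glu": 56.0}, crlb_pct={"Glu": 2.0},
                         global_extra_fwhm=0.0, global_shift=0.0,
                         zero_order_phase=0.0,
                         baseline_coeffs=np.zeros(1), residual_rms=0.0,
                         noise_sd=1.0, amp_names=["Glu"], n_averages=56)

    def test_pure_water_ratio_at_zero_csf(self):
        water = np.array([2.0 + 0j, 1.0])
        fit = water_reference_scale(self._fit(), water, 0.0)
        assert fit.concentrations_iu["Glu"] == pytest.approx(0.5)

    def test_csf_partial_volume_factor(self):
        """CSF fraction 0.0816 inflates concentrations by 1/(1-0.0816)."""
        water = np.array([1.0 + 0j])
        f0 = water_reference_scale(self._fit(), water, 0.0)
        f1 = water_reference_scale(self._fit(), water, 0.0816)
        assert f1.concentrations_iu["Glu"] / f0.concentrations_iu["Glu"] == \
            pytest.approx(1 / (1 - 0.0816))

    def test_doubling_water_halves_concentrations(self):
        f1 = water_reference_scale(self._fit(), np.array([1.0 + 0j]), 0.0)
        f2 = water_reference_scale(self._fit(), np.array([2.0 + 0j]), 0.0)
        assert f2.concentrations_iu["Glu"] == \
            pytest.approx(f1.concentrations_iu["Glu"] / 2)

    def test_csf_one_rejected(self):
        with pytest.raises(DataError):
            water_reference_scale(self._fit(), np.array([1.0 + 0j]), 1.0)

    def test_scaling_equivariance(self, params, basis, cfg):
        """Scaling spectrum and water by any alpha leaves I.U. unchanged."""
        fid = synthesize_fid(basis, DEFAULT_CONCENTRATIONS, 9.72, params)
        water = np.array([1.0 + 0j])
        out = []
        for alpha in (1.0, 7.3):
            fit = fit_spectrum(alpha * spectrum(fid, params), basis, cfg,
                               params, fast=True)
            fit = water_reference_scale(fit, alpha * water, 0.0)
            out.append(fit.concentrations_iu["Glu"])
        assert out[1] == pytest.approx(out[0], rel=1e-6)


class TestCombinePairs:
    def test_pair_sums(self):
        fit = FitResult(
            amplitudes={"GPC": 1.0, "PCho": 0.5, "PCr": 4.0, "Cr": 4.2},
            crlb_pct={m: 5.0 for m in ("GPC", "PCho", "PCr", "Cr")},
            global_extra_fwhm=0.0, global_shift=0.0, zero_order_phase=0.0,
            baseline_coeffs=np.zeros(1), residual_rms=0.0, noise_sd=1.0,
            amp_names=["GPC", "PCho", "PCr", "Cr"])
        fit.amp_covariance = np.diag([0.1, 0.1, 0.2, 0.2])
        fit = combine_pairs(fit)
        assert fit.amplitudes["tCho"] == pytest.approx(1.5)
        assert fit.amplitudes["tCr"] == pytest.approx(8.2)

    def test_anticorrelation_tightens_pair_crlb(self, params, basis, cfg,
                                                rng):
        """Cr and PCr are anticorrelated in the fit, so CRLB(tCr) is below
        both constituent CRLBs."""
        from fmrsglu import GroundTruth
        sigma = GroundTruth().resolved_noise_sd(params, basis)
        spec = _noisy_spec(params, basis, DEFAULT_CONCENTRATIONS, 9.72,
                           sigma, rng, n_avg=8)
        fit = fit_spectrum(spec, basis, cfg, params, fast=True)
        fit = combine_pairs(fit)
        i, j = fit.amp_names.index("Cr"), fit.amp_names.index("PCr")
        assert fit.amp_covariance[i, j] < 0
        assert fit.crlb_pct["tCr"] < max(fit.crlb_pct["Cr"],
                                         fit.crlb_pct["PCr"])


class TestFilterReliable:
    def _result(self, crlb):
        return FitResult(amplitudes={"X": 1.0}, crlb_pct={"X": crlb},
                         global_extra_fwhm=0.0, global_shift=0.0,
                         zero_order_phase=0.0, baseline_coeffs=np.zeros(1),
                         residual_rms=0.0, noise_sd=1.0, amp_names=["X"])

    def test_strict_threshold_boundary(self):
        assert filter_reliable([self._result(19.9)])["X"] is True
        assert filter_reliable([self._result(20.0)])["X"] is False

    def test_empty_input(self):
        assert filter_reliable([]) == {}
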