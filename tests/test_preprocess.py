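"""Preprocessing-chain tests: Klose eddy-current correction, NAA-singlet
frequency alignment, least-squares phasing, block reduction and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrsglu import (
    build_default_basis,
    BASELINE,
    STIMULATION,
    AcquisitionParams,
    BlockDesign,
    DataError,
    FidSeries,
    GroundTruth,
    align_frequency,
    bin_averages,
    combine_by_condition,
    eddy_current_correct,
    phase_correct,
    reduce_block_data,
    simulate_subject,
    spectrum,
)
from fmrsglu.preprocess import _phase_grid
from fmrsglu.synthdata import eddy_phase


def _series(subject):
    """Fresh FidSeries copy (fixtures are session-scoped)."""
    s = subject.fids
    return FidSeries(fids=s.fids.copy(), condition_labels=s.condition_labels,
                     params=s.params, subject_id=s.subject_id)


class TestEddyCurrentCorrect:
    def test_zero_phase_water_is_identity(self, clean_subject):
        series = _series(clean_subject)
        t = series.params.time_axis()
        water = np.exp(-np.pi * 9.72 * t).astype(complex)  # real, zero phase
        out = eddy_current_correct(series, water)
        np.testing.assert_allclose(out.fids, series.fids, atol=0)

    def test_inverts_known_distortion(self, clean_subject, params):
        series = _series(clean_subject)
        t = params.time_axis()
        phi = eddy_phase(t, 0.8, 0.04, 25.0)
        distorted = series.replaced(series.fids * np.exp(1j * phi), "tmp")
        distorted.provenance_flags.clear()
        water = np.exp(-np.pi * 9.72 * t) * np.exp(1j * phi)
        out = eddy_current_correct(distorted, water)
        err = np.abs(out.fids - series.fids).max() / np.abs(series.fids).max()
        assert err < 1e-10

    def test_magnitudes_preserved(self, default_subject):
        series = _series(default_subject)
        out = eddy_current_correct(series, default_subject.water_reference)
        np.testing.assert_allclose(np.abs(out.fids), np.abs(series.fids),
                                   rtol=1e-12)

    def test_vanishing_water_rejected(self, clean_subject):
        series = _series(clean_subject)
        water = np.zeros(series.params.n_points, dtype=complex)
        water[:10] = 1.0
        with pytest.raises(DataError, match="sample"):
            eddy_current_correct(series, water)

    def test_double_application_guarded(self, clean_subject):
        series = _series(clean_subject)
        out = eddy_current_correct(series, clean_subject.water_reference)
        with pytest.raises(DataError, match="already applied"):
            eddy_current_correct(out, clean_subject.water_reference)


class TestAlignFrequency:
    def test_drift_free_series_has_near_zero_shifts(self, clean_subject,
                                                    params):
        _, result = align_frequency(_series(clean_subject))
        assert np.abs(result.frequency_shift).max() <= \
            params.spectral_resolution / 2

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(shift=st.floats(-5.0, 5.0))
    def test_injected_shift_recovered(self, shift):
        """Shift recovery to 0.3 Hz; run at SNR 20 (the estimator is
        near-efficient and the information bound at SNR 10 is ~0.5 Hz)."""
        params = AcquisitionParams()
        design = BlockDesign()
        basis = build_default_basis()
        half_noise = GroundTruth().resolved_noise_sd(params, basis) / 2
        truth = GroundTruth(drift_rate=0.0, phase_jitter_sd=0.0,
                            eddy_params=None, noise_sd=half_noise)
        ds = simulate_subject(params, design, truth, seed=77)
        series = ds.fids
        t = params.time_axis()
        fids = series.fids.copy()
        fids[10] *= np.exp(2j * np.pi * shift * t)  # move one TR off
        shifted = FidSeries(fids=fids, condition_labels=series.condition_labels,
                            params=params)
        _, result = align_frequency(shifted)
        rel = result.frequency_shift[10] - np.median(result.frequency_shift)
        assert rel == pytest.approx(shift, abs=0.3)

    def test_linear_drift_slope_recovered(self, params, design):
        truth = GroundTruth(drift_rate=0.05, phase_jitter_sd=0.0,
                            eddy_params=None)
        ds = simulate_subject(params, design, truth, seed=42)
        _, result = align_frequency(ds.fids)
        slope = np.polyfit(np.arange(128), result.frequency_shift, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.01)


class TestPhaseCorrect:
    def test_self_reference_phase_zero(self, clean_subject):
        series, _ = align_frequency(_series(clean_subject))
        spec = spectrum(series.fids[0], series.params)
        out, phases = phase_correct(series, reference=spec)
        assert abs(phases[0]) < 0.5

    def test_injected_rotation_recovered(self, clean_subject):
        series, _ = align_frequency(_series(clean_subject))
        ref = spectrum(series.fids, series.params).mean(axis=0)
        rotated = series.replaced(series.fids * np.exp(1j * np.deg2rad(30.0)),
                                  "tmp")
        rotated.provenance_flags = ["align"]
        _, phases = phase_correct(rotated, reference=ref)
        np.testing.assert_allclose(phases, -30.0, atol=1.0)

    def test_random_phase_scatter_removed(self, params, design, basis):
        """25-degree phase scatter reduced below 2 degrees; run at SNR 50
        because the real-part least-squares phase estimate carries ~5
        degrees of intrinsic noise at single-TR SNR 10."""
        noise = GroundTruth().resolved_noise_sd(params, basis) / 5
        truth = GroundTruth(drift_rate=0.0, eddy_params=None,
                            phase_jitter_sd=25.0, noise_sd=noise)
        ds = simulate_subject(params, design, truth, seed=11)
        series, _ = align_frequency(ds.fids)
        out, phases = phase_correct(series)
        # residual phase scatter: per-TR phase of the windowed inner
        # product with the corrected mean (noise-robust readout)
        spec = spectrum(out.fids, params)
        ppm = params.ppm_axis()
        win = (ppm >= 1.8) & (ppm <= 3.5)
        mean = spec[:, win].mean(axis=0)
        resid = np.angle(spec[:, win] @ mean.conj(), deg=True)
        assert np.deg2rad(resid).std() < np.deg2rad(2.0)

    def test_requires_alignment_first(self, clean_subject):
        with pytest.raises(DataError, match="alignment"):
            phase_correct(_series(clean_subject))

    def test_energy_conserved(self, default_subject):
        series, _ = align_frequency(_series(default_subject))
        out, _ = phase_correct(series)
        np.testing.assert_allclose(np.abs(out.fids), np.abs(series.fids),
                                   rtol=1e-10)


class TestPhaseGridSolver:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(phi=st.floats(-44.0, 44.0))
    def test_exact_rotation_recovery(self, phi):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        rotated = base * np.exp(1j * np.deg2rad(phi))
        est = _phase_grid(rotated.real, rotated.imag, base.real)
        assert np.rad2deg(est) == pytest.approx(-phi, abs=0.5)


class TestReduceBlockData:
    def test_default_design_bookkeeping(self, clean_subject, design):
        """2 of 16 TRs dropped per block: 112 retained (12.5 % excluded),
        14 averages per block, 56 per condition."""
        out = reduce_block_data(_series(clean_subject), design)
        assert len(out) == 112
        assert 1 - len(out) / 128 == pytest.approx(0.125)
        labels = out.condition_labels
        assert (labels == BASELINE).sum() == (labels == STIMULATION).sum() == 56
        per_block = len(out) / design.n_blocks()
        assert per_block == 14

    def test_discard_zero_is_identity(self, clean_subject):
        d0 = BlockDesign(discard_per_block=0)
        out = reduce_block_data(_series(clean_subject), d0)
        np.testing.assert_array_equal(out.fids, clean_subject.fids.fids)

    def test_mismatched_design_rejected(self, clean_subject):
        bad = BlockDesign(block_length=32.0, n_cycles=4, discard_per_block=1)
        with pytest.raises(DataError):
            reduce_block_data(_series(clean_subject), bad)


class TestBinAverages:
    def test_default_binning_geometry(self, clean_subject):
        """128 TRs in 4-average bins -> 32 points at 16-s resolution."""
        out = bin_averages(_series(clean_subject), 4)
        assert len(out) == 32
        dt = np.diff(out.times)
        np.testing.assert_allclose(dt, 16.0)
        assert set(out.n_summed) == {4}

    def test_bin_zero_is_sum_of_first_four(self, clean_subject):
        series = _series(clean_subject)
        out = bin_averages(series, 4)
        np.testing.assert_allclose(out.fids[0], series.fids[:4].sum(axis=0))

    def test_bin_size_one_is_identity(self, clean_subject):
        out = bin_averages(_series(clean_subject), 1)
        np.testing.assert_array_equal(out.fids, clean_subject.fids.fids)

    def test_indivisible_length_rejected(self, clean_subject):
        with pytest.raises(DataError, match="truncate"):
            bin_averages(_series(clean_subject), 5)


def test_null_chain_is_identity(clean_subject):
    """On an eddy-free, drift-free, phase-clean series the full correction
    chain changes nothing (up to numerical tolerance)."""
    series = _series(clean_subject)
    t = series.params.time_axis()
    water = np.exp(-np.pi * 9.72 * t).astype(complex)
    out = eddy_current_correct(series, water)
    out, _ = align_frequency(out)
    out, _ = phase_correct(out)
    scale = np.abs(series.fids).max()
    assert np.abs(out.fids - series.fids).max() / scale < 1e-3


def test_condition_sums(clean_subject, design):
    reduced = reduce_block_data(_series(clean_subject), design)
    sums = combine_by_condition(reduced)
    for lab in (BASELINE, STIMULATION):
        fid, n = sums[lab]
        assert n == 56
        np.testing.assert_allclose(
            fid, reduced.fids[reduced.condition_labels == lab].sum(axis=0))
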