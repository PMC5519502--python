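"""Spectral preprocessing: eddy-current correction, frequency alignment to
the NAA singlet, least-squares zero-order phasing, block-wise data reduction
and 4-average binning.

Two analysis paths are supported downstream:

* condition path — ``reduce_block_data`` then ``combine_by_condition``
  (first two TRs of every block dropped, retained TRs summed per condition);
* time-course path — ``bin_averages`` over all TRs (no exclusion), giving
  the 16-s-resolution series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    BASELINE,
    STIMULATION,
    BlockDesign,
    DataError,
    FidSeries,
    spectrum,
)

NAA_PPM = 2.008
PHASE_WINDOW = (1.8, 3.5)   # ppm range for least-squares phasing
NOISE_REGION = (0.0, 0.4)   # signal-free ppm range


@dataclass
class AlignmentResult:
    """Per-TR frequency shifts (Hz) estimated during alignment."""

    frequency_shift: np.ndarray
    flagged: np.ndarray  # TRs whose shift was imputed from neighbours


def eddy_current_correct(series: FidSeries, water: np.ndarray) -> FidSeries:
    """Klose correction: divide out the phase of the unsuppressed water FID.

    ``fid(t) * exp(-i * arg(water(t)))`` — a unit-modulus operation, so
    per-sample magnitudes are untouched.
    """
    series.require_absent("eddy")
    water = np.asarray(water, dtype=complex)
    if water.shape != (series.fids.shape[1],):
        raise DataError("water FID length must match metabolite FIDs")
    mag = np.abs(water)
    bad = np.nonzero(mag < 1e-8 * mag.max())[0]
    if bad.size:
        raise DataError(f"water magnitude vanishes at sample {bad[0]}; "
                        "cannot define its phase")
    phase = np.exp(-1j * np.angle(water))
    return series.replaced(series.fids * phase[None, :], "eddy")


def _spectral_noise_sd(mag: np.ndarray, ppm: np.ndarray) -> float:
    mask = (ppm >= NOISE_REGION[0]) & (ppm <= NOISE_REGION[1])
    return float(mag[..., mask].std())


def _singlet_freq(w_spec: np.ndarray, w_nu: np.ndarray,
                  f0_init: float | None = None,
                  fixed_fwhm: float | None = None,
                  ) -> tuple[float, float] | None:
    """Centre frequency (and FWHM) of the dominant singlet in a spectral
    window by a complex-Lorentzian + linear-baseline least-squares fit.

    With ``fixed_fwhm`` the linewidth is pinned (per-TR refits then only
    estimate amplitude, phase, centre and baseline, which roughly halves
    the centre-frequency noise at low SNR).  Returns None when the
    optimiser fails; callers keep their coarse estimate in that case.
    """
    from scipy.optimize import least_squares

    x = np.linspace(-1.0, 1.0, len(w_nu))
    if f0_init is None:
        f0_init = float(w_nu[np.argmax(np.abs(w_spec))])
    peak = float(np.abs(w_spec).max())
    fwhm0 = fixed_fwhm if fixed_fwhm is not None else 10.0

    def unpack(p):
        if fixed_fwhm is None:
            return p[0], p[1], p[2], p[3], p[4:]
        return p[0], p[1], p[2], fixed_fwhm, p[3:]

    def resid(p):
        amp, phi, f0, fwhm, b = unpack(p)
        lor = amp * np.exp(1j * phi) / (np.pi * fwhm
                                        + 2j * np.pi * (w_nu - f0))
        d = w_spec - lor - (b[0] + b[1] * x) - 1j * (b[2] + b[3] * x)
        return np.concatenate([d.real, d.imag])

    p0 = [peak * np.pi * fwhm0, 0.0, f0_init]
    lo_b = [0.0, -np.pi, w_nu[0]]
    hi_b = [np.inf, np.pi, w_nu[-1]]
    if fixed_fwhm is None:
        p0 += [fwhm0]
        lo_b += [1.0]
        hi_b += [80.0]
    p0 += [0.0] * 4
    lo_b += [-np.inf] * 4
    hi_b += [np.inf] * 4
    p0[2] = float(np.clip(p0[2], lo_b[2], hi_b[2]))
    try:
        sol = least_squares(resid, p0, bounds=(lo_b, hi_b), method="trf",
                            xtol=1e-10, ftol=1e-10)
    except Exception:
        return None
    if not sol.success:
        return None
    fwhm = fixed_fwhm if fixed_fwhm is not None else float(sol.x[3])
    return float(sol.x[2]), fwhm


def align_frequency(series: FidSeries, target_ppm: float = NAA_PPM,
                    window: float = 0.15,
                    ) -> tuple[FidSeries, AlignmentResult]:
    """Align every TR to the series-mean spectrum around the NAA singlet.

    Shifts are estimated in two stages: parabolic-interpolated
    cross-correlation of the windowed magnitude spectra (2x zero-filled,
    grid-robust), then a per-TR complex-Lorentzian fit of the NAA singlet
    with a free centre frequency (noise-limited, near maximum likelihood).
    The shift is the fitted centre relative to the series-mean centre and
    is applied as a time-domain linear phase ramp.  TRs whose windowed peak
    is below 3x the spectral noise SD are flagged and their shift imputed
    from the nearest neighbours.
    """
    series.require_absent("align")
    params = series.params
    zf = 2
    specs = np.abs(spectrum(series.fids, params, zero_fill=zf))
    ppm = params.ppm_axis(params.n_points * zf)
    dnu = params.spectral_width / (params.n_points * zf)
    ref = specs.mean(axis=0)
    lo, hi = target_ppm - window, target_ppm + window
    idx = np.nonzero((ppm >= lo) & (ppm <= hi))[0]
    max_lag = max(3, int(round(window * params.hz_per_ppm / (2 * dnu))))
    noise_sd = _spectral_noise_sd(specs, ppm)

    n = len(series)
    shifts = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    ref_win = ref[idx]
    for i in range(n):
        s = specs[i]
        if s[idx].max() < 3.0 * noise_sd:
            flagged[i] = True
            continue
        lags = np.arange(-max_lag, max_lag + 1)
        corr = np.array([float(s[idx + L] @ ref_win) for L in lags])
        k = int(np.argmax(corr))
        if 0 < k < len(corr) - 1:
            c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
            denom = c0 - 2 * c1 + c2
            frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
        else:
            frac = 0.0
        shifts[i] = (lags[k] + frac) * dnu

    if flagged.all():
        raise DataError("no TR has a resolvable peak in the alignment window")

    # refinement: per-TR Lorentzian singlet fit with free centre frequency
    full = spectrum(series.fids, params)
    ppm1 = params.ppm_axis()
    win = np.nonzero((ppm1 >= lo) & (ppm1 <= hi))[0]
    nu_win = params.freq_axis()[win]
    ref_fit = _singlet_freq(full[~flagged].mean(axis=0)[win], nu_win)
    if ref_fit is None:
        raise DataError("could not fit the NAA singlet on the mean spectrum")
    ref_f0, ref_fwhm = ref_fit
    for i in range(n):
        if flagged[i]:
            continue
        fit = _singlet_freq(full[i][win], nu_win,
                            f0_init=ref_f0 + shifts[i],
                            fixed_fwhm=ref_fwhm)
        if fit is not None:
            shifts[i] = fit[0] - ref_f0

    good = np.nonzero(~flagged)[0]
    for i in np.nonzero(flagged)[0]:
        j = good[np.argmin(np.abs(good - i))]
        shifts[i] = shifts[j]

    t = params.time_axis()
    ramp = np.exp(-2j * np.pi * shifts[:, None] * t[None, :])
    out = series.replaced(series.fids * ramp, "align")
    return out, AlignmentResult(frequency_shift=shifts, flagged=flagged)


def _phase_grid(u: np.ndarray, v: np.ndarray, r: np.ndarray) -> float:
    """Zero-order phase minimising ||cos(p)*u - sin(p)*v - r||^2.

    Coarse 0.5-degree grid followed by a parabolic refinement; the objective
    is smooth and 2*pi-periodic so this is globally reliable.
    """
    phis = np.deg2rad(np.arange(-180.0, 180.0, 0.5))
    uu, vv = u @ u, v @ v
    uv, ur, vr = u @ v, u @ r, v @ r
    c, s = np.cos(phis), np.sin(phis)
    obj = c * c * uu + s * s * vv - 2 * c * s * uv - 2 * c * ur + 2 * s * vr
    k = int(np.argmin(obj))
    km, kp = (k - 1) % len(phis), (k + 1) % len(phis)
    c0, c1, c2 = obj[km], obj[k], obj[kp]
    denom = c0 - 2 * c1 + c2
    frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
    return float(phis[k] + frac * np.deg2rad(0.5))


def phase_correct(series: FidSeries, reference: np.ndarray | None = None,
                  ) -> tuple[FidSeries, np.ndarray]:
    """Per-TR zero-order phase by least squares against a reference spectrum.

    The phase minimises the squared difference between the real parts of the
    phased spectrum and the reference over 1.8-3.5 ppm.  By default each TR
    is referenced to the mean spectrum of *its own condition*: a pooled
    reference lets the fitted phase rotate away part of any real
    between-condition signal difference (a measurable few-percent
    attenuation of condition contrasts), whereas per-condition references
    keep the correction orthogonal to the effect of interest.  Returns the
    phased series and the applied phases (degrees).  Requires alignment
    first.
    """
    series.require_absent("phase")
    if "align" not in series.provenance_flags:
        raise DataError("phase correction requires frequency alignment first")
    params = series.params
    specs = spectrum(series.fids, params)
    ppm = params.ppm_axis()
    mask = (ppm >= PHASE_WINDOW[0]) & (ppm <= PHASE_WINDOW[1])
    if reference is None:
        # Per-condition references keep the per-TR phase fit orthogonal to
        # any real between-condition signal change (a pooled reference lets
        # the fitted phases rotate part of that change away).  Mutual
        # coherence of the conditions is restored from the tCr-singlet
        # window, where conditions differ in width but not in phase or
        # amplitude, so this step cannot touch the effect of interest.
        tcr = (ppm >= 3.03 - 0.05) & (ppm <= 3.03 + 0.05)
        g_tcr = specs[:, tcr].mean(axis=0)
        refs = {}
        for lab in np.unique(series.condition_labels):
            m_full = specs[series.condition_labels == lab].mean(axis=0)
            coh = np.angle(np.vdot(g_tcr, m_full[tcr]))
            refs[lab] = (m_full[mask] * np.exp(-1j * coh)).real
    else:
        r_g = np.asarray(reference).real[mask]
        refs = {lab: r_g for lab in np.unique(series.condition_labels)}
    phases = np.zeros(len(series))
    for i in range(len(series)):
        u = specs[i].real[mask]
        v = specs[i].imag[mask]
        phases[i] = _phase_grid(u, v, refs[series.condition_labels[i]])
    out = series.replaced(series.fids * np.exp(1j * phases)[:, None], "phase")
    return out, np.rad2deg(phases)


def reduce_block_data(series: FidSeries, design: BlockDesign) -> FidSeries:
    """Drop the first ``discard_per_block`` TRs of every block.

    For the default design (16-TR blocks, discard 2) this retains 14 averages
    per block, i.e. excludes 12.5 % of the data.
    """
    series.require_absent("reduced")
    tr = series.params.tr
    labels = design.labels(tr)
    if len(labels) != len(series) or np.any(labels != series.condition_labels):
        raise DataError("series labels do not match the block design")
    per = design.trs_per_block(tr)
    within = np.arange(len(series)) % per
    keep = within >= design.discard_per_block
    return series.replaced(series.fids[keep], "reduced",
                           condition_labels=series.condition_labels[keep],
                           times=series.times[keep],
                           n_summed=series.n_summed[keep])


def bin_averages(series: FidSeries, bin_size: int = 4) -> FidSeries:
    """Sum consecutive non-overlapping groups of ``bin_size`` TRs.

    Bin label is the majority condition of its members; bin time is the
    centre of the spanned TRs.  For 128 TRs and bin 4 this yields the 32
    time-course points at 16-s resolution.
    """
    series.require_absent("binned")
    if bin_size == 1:
        return series.replaced(series.fids.copy(), "binned")
    n = len(series)
    if n % bin_size:
        raise DataError(f"series length {n} not divisible by bin_size "
                        f"{bin_size}; truncate the series first")
    nb = n // bin_size
    fids = series.fids.reshape(nb, bin_size, -1).sum(axis=1)
    labels = []
    for b in range(nb):
        labs = series.condition_labels[b * bin_size:(b + 1) * bin_size]
        vals, counts = np.unique(labs, return_counts=True)
        labels.append(vals[np.argmax(counts)])
    times = series.times.reshape(nb, bin_size).mean(axis=1)
    n_summed = series.n_summed.reshape(nb, bin_size).sum(axis=1)
    return series.replaced(fids, "binned",
                           condition_labels=np.array(labels),
                           times=times, n_summed=n_summed)


def combine_by_condition(series: FidSeries) -> dict[str, tuple[np.ndarray, int]]:
    """Sum all retained FIDs per condition -> {label: (fid, n_averages)}."""
    out = {}
    for lab in (BASELINE, STIMULATION):
        mask = series.condition_labels == lab
        if mask.any():
            out[lab] = (series.fids[mask].sum(axis=0),
                        int(series.n_summed[mask].sum()))
    return out
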