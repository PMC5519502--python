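# Methods

This note documents the models, estimators, defaults and numerical choices
behind `fmrsglu`, and what the synthetic data do and do not emulate.

## Signal model and conventions

A free-induction decay on `N = 2048` complex points at spectral width
`sw = 6000` Hz is

    s(t) = Σ_m c_m Σ_k w_{mk} · exp( (i·2π f_{mk} − π·(Δν_cond + b_m)) t ),

where `c_m` is the concentration of metabolite `m`, `w_{mk}` are multiplet
weights normalised to sum to one, `f_{mk} = (δ_{mk} − 4.7 ppm)·297.2 Hz`
places the resonance relative to the carrier on water, `Δν_cond` is the
condition-dependent global Lorentzian width, and `b_m` is extra width for
broad components (macromolecules, +30 Hz).  Spectra are FFTs with the first
point halved (flat baseline for a Lorentzian) and `fftshift` applied;
arrays ascend in ppm.  The spectrometer frequency (297.2 MHz) and
digitization are fixed package conventions: neither alters any reported
contrast, they only set the ppm↔Hz map and grid resolution (2.93 Hz/pt).

The metabolite panel is a reduced, documented table of Lorentzian
multiplets (Glu, Gln, GABA, sNAA, mNAA, Cr, PCr, GPC, PCho, Ins, GSH, Lac
plus four macromolecule humps at 0.91/1.21/1.43/2.05 ppm).  Chemical shifts
follow standard in-vivo assignments; weights approximate proton counts.
This deliberately preserves the structure of the fitting problem — the
Glu/Gln/GABA/NAA overlap around 2.0–2.5 ppm, the near-degenerate Cr/PCr and
GPC/PCho pairs, a broad background under everything — at desk scale.  It is
not a density-matrix simulation: J-evolution, TE-dependent phase
distortions of multiplets, and measured macromolecule lineshapes are out of
scope, so absolute fit quality on real 7 T data will differ.

## Study conditions (generator defaults)

| quantity | default | note |
|---|---|---|
| TR / TE / averages | 4 s / 36 ms / 128 | interleaved fMRI-MRS protocol |
| blocks | 64 s × 4 cycles, baseline first | 16 TRs per block |
| data reduction | first 2 TRs of each block dropped | 12.5 %, 56 averages/condition |
| baseline glutamate | 7.8125 I.U. | so +1.92 % = +0.15 I.U. |
| stimulation glutamate | +1.92 % | applied on stimulation TRs only |
| tCr width baseline/stimulation | 9.72 / 9.51 Hz | global (T2*) narrowing, all lines |
| BOLD amplitude | 1.43 % plateau, double-gamma HRF | per-TR noise 0.3 % |
| frequency drift | 0.02 Hz/TR, linear | ~2.6 Hz over the run |
| phase jitter | 5° SD per TR | |
| eddy-current phase | 0.5·e^{−t/50 ms}·sin(2π·20 Hz·t) rad | shared with the water reference |
| noise | calibrated: single-TR NAA-singlet peak SNR = 10 | gives binned (4-average) Glu CRLB ≈ 8–9 % |
| CSF fraction | 0.0816 | metabolite signal scaled by (1 − f_CSF); water not |

Between-subject spreads (`TruthDistribution`): baseline width SD 0.85 Hz
and narrowing SD 0.05 Hz (the observed cohort spreads, essentially
biological at condition-level measurement precision); BOLD amplitude SD
0.61 %; CSF SD 0.0358; concentration scale SD 5 %; glutamate-increase SD
0.6 percentage points — deliberately smaller than the observed across-
subject s.e.m. of the percent change, because at this SNR that observed
spread is already nearly saturated by spectral measurement noise.

The stated protocol duration (8 min 24 s) and 128 × 4 s = 512 s disagree by
8 s; the simulator uses 128 TRs (512 s).

## Preprocessing estimators

**Eddy-current correction** divides out the water-FID phase (Klose); it is
exactly unit-modulus, so magnitude spectra are untouched.  With the carrier
on water the water FID is on-resonance and its phase is purely the
eddy-current term, making the correction exact in the noiseless limit.

**Frequency alignment** is two-stage: parabolic-interpolated
cross-correlation of 2×-zero-filled magnitude spectra in a ±0.15 ppm window
around 2.01 ppm (grid-robust coarse estimate), then a per-TR
complex-Lorentzian refit of the NAA singlet with the linewidth pinned to
the series-mean fit (near-maximum-likelihood refinement).  The measured
per-TR scatter, ~0.57 Hz at SNR 10 and ~0.29 Hz at SNR 20, matches the
joint Cramér–Rao bound for this estimation problem (~0.5 Hz at SNR 10 with
free amplitude/phase/baseline) — sub-0.3 Hz per-TR alignment is
information-theoretically unavailable at SNR 10, which is why the
inject–recover tests run at SNR 20.  Residual scatter blurs condition sums
by well under 0.05 Hz (Voigt arithmetic) and is condition-symmetric.
TRs whose windowed peak is below 3× the spectral noise SD are flagged and
imputed from the nearest non-flagged neighbour.

**Phase correction** minimises ‖Re{e^{iφ}S} − Re{S_ref}‖² over 1.8–3.5 ppm
on a 0.5° grid with parabolic refinement (the objective is smooth and
periodic, so this is globally reliable).  The estimator's intrinsic noise
is ~4.7° per TR at SNR 10 — again at the statistical floor of the stated
objective — costing < 0.4 % coherent amplitude in 56-average sums, equally
in both conditions.  Zero-order only: at short TE with echo sampling the
first-order term is small and is absorbed by the fit's phase/baseline.

The reference is the mean spectrum of each TR's *own condition*.  This
matters: against a pooled reference, the fitted phase of a stimulation TR
systematically rotates part of its (real) glutamate surplus into the
imaginary channel through the absorption/dispersion overlap — paired
common-seed simulations showed the pooled-reference chain transferring
only ~95 % of an injected concentration change, versus ~98.5 % with
per-condition references.  Mutual coherence of the condition sums is then
restored from the tCr-singlet window (3.03 ± 0.05 ppm), where the
conditions differ only in linewidth, so that one-number correction is
orthogonal to the effect of interest.  The residual ~1.5 % transfer loss
(noise-driven per-TR correction residuals) is a known limitation below
the study's measurement precision.

## Linear-combination fitting

The dictionary is synthesised from the same resonance table at a reference
linewidth and modified online by a global extra Lorentzian broadening
`δ ∈ [0, 10] Hz`, a global shift `|Δf| ≤ 3` Hz and a zero-order phase
`|φ| ≤ 45°`; amplitudes (non-negative) and a Legendre baseline (order 4
over 0.5–4.2 ppm) are solved by bounded linear least squares at each
nonlinear iterate.  The nonlinear search uses variable projection — the
search sees the residual of the unconstrained linear solve, which is smooth
in the nonlinear parameters — with three deterministic starts and a final
bounded (BVLS) polish; ties break by residual, then smaller broadening.

**The width-reference convention is the crux of the BOLD confound.**  The
pipeline generates the dictionary at the subject's *measured baseline* tCr
width and models only additional broadening.  A spectrum narrower than the
reference is then fit with a mismatched width, inflating every amplitude by
approximately `(w_ref − w_data)/(2·w_ref)` — for 2 % narrowing, about +1 %.
This reproduces, by construction, the known behaviour of
measured-lineshape linear-combination fitting under BOLD line narrowing;
broadening stimulation FIDs to the baseline width before fitting removes
the mismatch, and because baseline and corrected-stimulation spectra are
then referenced identically, width-measurement error cancels in the
contrast (verified by common-random-number simulation to < 0.02
percentage points).

On top of subject-specific line matching, every quantified condition
spectrum receives a common 1-Hz exponential apodization (and the
dictionary reference shifts accordingly).  Lorentzian apodization leaves
fitted amplitudes unchanged, but it makes the noise in baseline and
line-matched stimulation spectra identically processed, so the small
finite-noise artefacts of the bounded fit cancel in the contrast instead
of entering it with different magnitudes; it also slightly reduces the
contrast variance (mild matched filtering).

**CRLB.**  `F = JᵀJ/σ̂²` over all free parameters (amplitudes, broadening,
shift, phase, baseline), with σ̂ the SD of the fit residual in the
signal-free 0.0–0.4 ppm region; `CRLB% = 100·√(F⁻¹)_mm / c_m`.  Cr/PCr and
GPC/PCho are individually ill-conditioned (5-Hz-separated CH₂ lines and
3-mHz-separated cholines); their sums tCr/tCho are reported with the
summed-covariance rule and are well determined.  A singular Fisher matrix
falls back to the pseudo-inverse.  Reliability: group-mean CRLB strictly
below 20 %.

**Institutional units.**  `IU_m = k·(c_m/n_averages)/A_water/(1 − f_CSF)`
with `k = 1` and `A_water` the water-FID first-point magnitude.  No T1/T2
correction, so only differences and ratios of I.U. are interpretable;
absolute values are not comparable across scaling conventions.

## Line-narrowing estimation and correction

The tCr singlet at 3.03 ppm is fit in a ±0.1 ppm window with one complex
Lorentzian plus a complex linear baseline (`scipy.optimize.least_squares`).
The fit refuses pure-noise windows (SNR < 5), centre-at-edge and
large-residual solutions.  GABA's 3.01-ppm line sits inside the window and
both conditions carry it equally; its effect on the absolute width is below
0.05 Hz here.  Narrowing is `100·(w_base − w_stim)/w_base`; broadening a
FID multiplies by `exp(−πΔw·t)` (an exact Lorentzian-width semigroup) and
narrowing is refused.  Per-condition width precision at the default SNR is
~0.2–0.3 Hz per subject, so a single 13-subject cohort determines the ~2 %
narrowing only to ±1 percentage point; replicate averaging sharpens this.

Correction is applied per subject on summed condition spectra; in the
time-course path each stimulation-labelled bin is broadened by the same
condition-level Δw.  Broadening precedes fitting and water scaling.

## Group statistics

Condition contrasts are per-subject stimulation − baseline I.U. values with
a one-sample t-test (df = n − 1); percent change uses each subject's own
baseline.  ΔGlu time courses are smoothed per subject (3-point centred
moving average, shrinking at edges) before group averaging; BOLD is binned
identically, z-normalised per subject, left unsmoothed, and the group
correlation is Pearson on the 32-bin group means with df reported as
n_pairs − 2 (30, or 26 when the first baseline block — a familiarization
period — is dropped).  Multiple metabolites are tested without correction,
matching single-metabolite practice; a Holm-adjusted column is emitted for
transparency.  The sham analysis runs the identical pipeline on resting
simulations (no condition-dependent truth).

## What passing tests show — and what they do not

The generator reproduces the statistical structure the pipeline assumes:
Lorentzian lines, global T2* narrowing, linear drift, white phase jitter, a
deterministic eddy-current phase, additive complex Gaussian noise, and a
noiseless water reference.  Real 7 T data add J-modulated multiplets,
non-Lorentzian (shim) lineshapes, physiological noise and motion, subject-
specific macromolecules, and imperfect water suppression.  Passing tests
therefore demonstrate correctness of the estimators under the stated model
and faithful recovery of injected effects — not performance bounds on real
data.

## Problem sizes and runtimes

Tests run cohorts of 13 subjects (occasionally 5) with up to 12 replicate
experiments per check, and Monte-Carlo loops of 40–1000 draws where a
distributional property is asserted; the full suite takes roughly 10–15
minutes on one CPU.  `scripts/acceptance.py` averages 20 replicate
13-subject experiments through the full fitting chain (plus 8 cheaper
linewidth-only and 20 BOLD-only replicate cohorts), chosen so the
Monte-Carlo error of each reported group statistic is several times
smaller than the band it is compared against; it completes in about 8–10
minutes.

## Known limitations

* Simplified Lorentzian basis (no J-evolution); NAAG omitted (unreliable at
  this protocol's CRLB threshold); Voigt/Gaussian lineshapes deferred.
* Zero-order phase only; first-order phase untested territory for the
  phasing objective.
* The I.U. scale is internally consistent but arbitrary (`k = 1`).
* Per-TR alignment/phasing noise is at the information bound of the stated
  estimators; pipelines needing tighter per-TR registration at SNR 10 must
  change the acquisition, not the estimator.
* The corrected condition contrast carries a small systematic
  under-recovery at the default SNR (replicate audits place it at roughly
  0.2–0.4 percentage points on a 1.92 % effect: ~97–98 % effect transfer
  through the noisy per-TR corrections plus a comparable additive term),
  well below the across-subject s.e.m. of a single cohort.
* The sham/resting control shares the task generator with
  `stim_glu_increase = 0` and equal condition widths; it does not model
  resting-state physiological fluctuations.
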