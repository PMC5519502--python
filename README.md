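# fmrsglu

Analysis pipeline for **combined fMRI-MRS**: interleaved acquisitions in
which every 4-s TR yields both a short-TE ¹H spectrum from a visual-cortex
voxel and an ROI-mean BOLD sample.  The package turns per-TR free-induction
decays (FIDs), an unsuppressed-water reference, and the co-acquired BOLD
series into BOLD-corrected glutamate concentration changes, difference
spectra, and glutamate–BOLD time-course statistics.  A first-class
synthetic-data generator emulates the 7 T acquisition (semi-LASER-like
spectra, TE 36 ms, TR 4 s, 128 averages, 64-s baseline/stimulation blocks ×
4 cycles), so every stage is testable without scanner data.

It is written for fMRS methodologists: people who want a desk-scale,
fully-inspectable re-implementation of the standard functional-MRS analysis
chain, including the line-narrowing confound and its correction.

## The analysis in brief

1. **Preprocessing** — Klose eddy-current correction with the water FID
   (`fid·e^{-i·arg(water)}`), frequency alignment to the NAA singlet at
   2.01 ppm, least-squares zero-order phasing over 1.8–3.5 ppm, exclusion
   of the first 2 TRs of every block (12.5 % of the data), and per-condition
   summation (condition path) or 4-average binning into 32 points at 16-s
   resolution (time-course path).
2. **Linear-combination fitting** — each spectrum is modelled as
   `min ‖Re{e^{iφ}(S(ν) − Σ_m c_m B_m(ν; δ, Δf))} − baseline(ν)‖²` with
   `c_m ≥ 0`, a global extra Lorentzian broadening `δ ∈ [0, δ_max]`, a
   global shift, a zero-order phase and a polynomial baseline.  Amplitude
   precision is reported as Cramér–Rao lower bounds (CRLB %), metabolites
   with group-mean CRLB ≥ 20 % are flagged unreliable, GPC+PCho and Cr+PCr
   are reported as tCho and tCr, and concentrations are water-referenced
   institutional units (I.U.) with CSF partial-volume correction
   `1/(1 − f_CSF)` and no relaxation correction.
3. **BOLD correction** — the T2* increase during activation narrows all
   lines.  The tCr singlet at 3.03 ppm is fit with a single complex
   Lorentzian per condition; under the assumption that creatine itself is
   stable, the measured narrowing (≈ 9.72 → 9.51 Hz, ~2 %) is attributed to
   the BOLD effect and stimulation FIDs are broadened back to the baseline
   width (`fid·e^{-πΔw·t}`) before quantification.  Uncorrected, the
   narrowing masquerades as a ~1 % apparent concentration increase.
4. **Functional statistics** — per-subject stimulation−baseline contrasts
   with one-sample t-tests, ΔGlu(%) = 100·(G_i − G_baseline)/G_baseline
   time courses (3-point moving average, group mean), Pearson correlation
   with the z-normalised binned BOLD, a difference spectrum from
   line-matched condition sums, and a sham analysis that applies the task
   pipeline to resting data as a specificity control.

## Worked example

```python
import fmrsglu as F
from fmrsglu.functional_stats import group_condition_analysis

datasets = F.simulate_group(n_subjects=13, seed=1)   # the study conditions
results, corrected, uncorrected = group_condition_analysis(datasets)

g = corrected["Glu"]
print(f"dGlu = {g.delta_iu:+.3f} +/- {g.delta_iu_sem:.3f} I.U. "
      f"({g.delta_pct:+.2f} +/- {g.delta_pct_sem:.2f} %), "
      f"t({g.df}) = {g.t_stat:.2f}, p = {g.p:.4f}")
print(f"uncorrected dGlu = {uncorrected['Glu'].delta_pct:+.2f} %")
print("narrowing = {:.2f} %".format(
    sum(r.narrowing_pct for r in results) / len(results)))
```

Output from this exact invocation:

```
dGlu = +0.012 +/- 0.062 I.U. (+0.18 +/- 0.81 %), t(12) = 0.19, p = 0.8524
uncorrected dGlu = +1.72 %
narrowing = 2.51 %
```

Reading it: the cohort was simulated with a true +1.92 % (0.15 I.U.)
stimulation glutamate increase and 9.72→9.51 Hz line narrowing.  The tCr
fits recover the ~2 % narrowing, and the uncorrected estimate sits about
1.5 percentage points above the corrected one — that gap is the
line-narrowing artefact the correction exists to remove.  The corrected
estimate itself illustrates the realistic measurement problem: a single
13-subject cohort at this SNR carries an s.e.m. of ~0.8 %, and this
particular realization landed two standard errors low.  Averaging
replicate cohorts (as `scripts/acceptance.py` does) converges on the
injected truth; at 20 replicate cohorts the recovered group-mean increase
is 1.77 %.

The same objects feed the time-course path
(`fmrsglu.functional_stats.group_timecourse`), which returns the 32-point
group ΔGlu curve, the z-normalised BOLD curve and their correlation.

A thin CLI mirrors the library:
`fmrsglu simulate|preprocess|fit|correct-bold|analyze|all`
(`fmrsglu all --subjects 13 --seed 1 --out results/`).

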