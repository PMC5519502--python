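"""Group statistics: condition contrasts, difference spectra, glutamate
time courses, glutamate-BOLD coupling, and the sham (resting-state) control.

Percent glutamate change is defined relative to the mean baseline
concentration, dGlu_i = 100 * (G_i - G_baseline) / G_baseline, on 16-s bins
smoothed per subject with a 3-point moving average before group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lcmfit import FitConfig, FitResult
from .params import BASELINE, STIMULATION, DataError
from .pipeline import (
    SubjectConditionResult,
    analyze_subject_conditions,
    analyze_subject_timecourse,
)
from .synthdata import BasisSet, SubjectDataset


@dataclass
class TimeCourse:
    """Binned per-subject quantity at 16-s resolution."""

    values: np.ndarray
    bin_times: np.ndarray            # s, bin centres
    condition_per_bin: np.ndarray
    units: str = "I.U."              # one of I.U. | percent | z
    baseline_mean: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_times) or \
                len(self.values) != len(self.condition_per_bin):
            raise DataError("time-course fields must share one length")
        if self.baseline_mean is None:
            base = self.values[self.condition_per_bin == BASELINE]
            self.baseline_mean = float(base.mean()) if base.size else None


@dataclass
class GroupStats:
    """One metabolite's stimulation-baseline contrast across subjects."""

    metabolite: str
    delta_iu: float
    delta_iu_sem: float
    delta_pct: float
    delta_pct_sem: float
    t_stat: float
    df: int
    p: float
    n_subjects: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    df: int          # n_pairs - 2
    n: int


def difference_spectrum(stim_sum: np.ndarray,
                        base_sum: np.ndarray) -> np.ndarray:
    """Pointwise stimulation - baseline spectrum (same ppm grid required)."""
    stim_sum = np.asarray(stim_sum)
    base_sum = np.asarray(base_sum)
    if stim_sum.shape != base_sum.shape:
        raise DataError("spectra live on different ppm grids")
    return stim_sum - base_sum


def delta_glu_timecourse(tc: TimeCourse) -> TimeCourse:
    """Percent change from the mean baseline concentration."""
    if tc.baseline_mean is None or tc.baseline_mean <= 0:
        raise DataError("baseline mean must be positive to form percent change")
    vals = 100.0 * (tc.values - tc.baseline_mean) / tc.baseline_mean
    return TimeCourse(values=vals, bin_times=tc.bin_times.copy(),
                      condition_per_bin=tc.condition_per_bin.copy(),
                      units="percent", baseline_mean=0.0)


def smooth_moving_average(tc: TimeCourse, k: int = 3) -> TimeCourse:
    """Centred k-point moving average with shrinking windows at the edges."""
    if k % 2 == 0:
        raise DataError("moving-average length must be odd")
    n = len(tc.values)
    if k >= n:
        raise DataError("moving-average length must be shorter than the series")
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = tc.values[lo:hi].mean()
    return TimeCourse(values=out, bin_times=tc.bin_times.copy(),
                      condition_per_bin=tc.condition_per_bin.copy(),
                      units=tc.units, baseline_mean=tc.baseline_mean)


def z_normalize(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise DataError("cannot z-normalize a constant series")
    return (values - values.mean()) / sd


def correlate_with_bold(glu_tc: TimeCourse, bold_tc: TimeCourse,
                        drop_first_baseline: bool = False,
                        ) -> CorrelationResult:
    """Pearson correlation of the glutamate and BOLD time courses.

    With ``drop_first_baseline`` the bins of the first baseline block (a
    familiarization period) are excluded.  Degrees of freedom are reported
    as n_pairs - 2.
    """
    g, b = glu_tc.values, bold_tc.values
    if len(g) != len(b):
        raise DataError("time courses have different lengths")
    keep = np.ones(len(g), dtype=bool)
    if drop_first_baseline:
        first = glu_tc.condition_per_bin[0]
        i = 0
        while i < len(g) and glu_tc.condition_per_bin[i] == first:
            i += 1
        keep[:i] = False
    g, b = g[keep], b[keep]
    if g.std() == 0 or b.std() == 0:
        raise DataError("zero-variance input to correlation")
    r, p = stats.pearsonr(g, b)
    return CorrelationResult(r=float(r), p=float(p), df=len(g) - 2, n=len(g))


def condition_contrast(base_fits: list[FitResult],
                       stim_fits: list[FitResult],
                       metabolites: list[str] | None = None,
                       ) -> dict[str, GroupStats]:
    """Per-metabolite stimulation - baseline contrast with a one-sample
    t-test against zero across subjects (df = n_subjects - 1)."""
    if len(base_fits) != len(stim_fits) or len(base_fits) < 2:
        raise DataError("need matched per-subject fits for >= 2 subjects")
    n = len(base_fits)
    names = metabolites or sorted(
        set(base_fits[0].concentrations_iu) & set(stim_fits[0].concentrations_iu))
    out = {}
    for m in names:
        base = np.array([f.concentrations_iu[m] for f in base_fits])
        stim = np.array([f.concentrations_iu[m] for f in stim_fits])
        delta = stim - base
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(base > 0, 100.0 * delta / base, np.nan)
        if np.allclose(delta, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(delta, 0.0)
        out[m] = GroupStats(
            metabolite=m,
            delta_iu=float(delta.mean()),
            delta_iu_sem=float(delta.std(ddof=1) / np.sqrt(n)),
            delta_pct=float(np.nanmean(pct)) if np.isfinite(pct).any() else np.nan,
            delta_pct_sem=(float(np.nanstd(pct, ddof=1) / np.sqrt(np.isfinite(pct).sum()))
                           if np.isfinite(pct).sum() > 1 else np.nan),
            t_stat=float(t), df=n - 1, p=float(p), n_subjects=n)
    return out


def contrast_table(contrasts: dict[str, GroupStats]):
    """Tidy DataFrame of contrasts with a Holm-corrected p column
    (the primary inference is uncorrected, mirroring single-metabolite
    hypotheses; the Holm column is for transparency)."""
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    rows = [vars(g).copy() for g in contrasts.values()]
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p"].values, method="holm")[1]
    return df


@dataclass
class GroupTimecourseResult:
    glu_pct_mean: TimeCourse         # group-mean smoothed dGlu (%)
    bold_z_mean: TimeCourse          # group-mean z-normalised BOLD
    correlation: CorrelationResult
    correlation_no_first: CorrelationResult
    subject_glu_pct: list[TimeCourse] = field(default_factory=list)


def bin_bold(bold: np.ndarray, bin_size: int = 4) -> np.ndarray:
    bold = np.asarray(bold, dtype=float)
    if len(bold) % bin_size:
        raise DataError("BOLD series length not divisible by bin size")
    return bold.reshape(-1, bin_size).mean(axis=1)


def group_timecourse(datasets: list[SubjectDataset],
                     basis: BasisSet | None = None,
                     config: FitConfig | None = None,
                     bin_size: int = 4, smooth_k: int = 3,
                     correct_bold_narrowing: bool = True,
                     ) -> GroupTimecourseResult:
    """Group glutamate/BOLD time-course analysis.

    Per subject: binned glutamate quantification, percent change from mean
    baseline, 3-point smoothing; BOLD binned identically and z-normalised.
    Group curves are subject means; the correlation is computed on them,
    with and without the first baseline block.
    """
    glu_curves, bold_curves = [], []
    times = labels = None
    for ds in datasets:
        glu, binned, _ = analyze_subject_timecourse(
            ds, basis=basis, config=config, bin_size=bin_size,
            correct_bold_narrowing=correct_bold_narrowing)
        times, labels = binned.times, binned.condition_labels
        tc = TimeCourse(values=glu, bin_times=times, condition_per_bin=labels)
        tc = smooth_moving_average(delta_glu_timecourse(tc), smooth_k)
        glu_curves.append(tc)
        bold_curves.append(z_normalize(bin_bold(ds.bold, bin_size)))

    glu_mean = TimeCourse(
        values=np.mean([t.values for t in glu_curves], axis=0),
        bin_times=times, condition_per_bin=labels, units="percent",
        baseline_mean=0.0)
    bold_mean = TimeCourse(values=np.mean(bold_curves, axis=0),
                           bin_times=times, condition_per_bin=labels,
                           units="z")
    return GroupTimecourseResult(
        glu_pct_mean=glu_mean, bold_z_mean=bold_mean,
        correlation=correlate_with_bold(glu_mean, bold_mean),
        correlation_no_first=correlate_with_bold(glu_mean, bold_mean,
                                                 drop_first_baseline=True),
        subject_glu_pct=glu_curves)


def group_condition_analysis(datasets: list[SubjectDataset],
                             basis: BasisSet | None = None,
                             config: FitConfig | None = None,
                             fit_uncorrected: bool = True,
                             ) -> tuple[list[SubjectConditionResult],
                                        dict[str, GroupStats],
                                        dict[str, GroupStats] | None]:
    """Condition contrasts for a cohort: per-subject results plus corrected
    (and optionally uncorrected) group statistics."""
    results = [analyze_subject_conditions(ds, basis=basis, config=config,
                                          fit_uncorrected=fit_uncorrected)
               for ds in datasets]
    base = [r.fits[BASELINE] for r in results]
    stim = [r.fits[STIMULATION] for r in results]
    corrected = condition_contrast(base, stim)
    if not fit_uncorrected:
        return results, corrected, None
    stim_unc = [r.fits["stimulation_uncorrected"] for r in results]
    return results, corrected, condition_contrast(base, stim_unc)


def sham_analysis(resting: list[SubjectDataset],
                  basis: BasisSet | None = None,
                  config: FitConfig | None = None) -> dict[str, GroupStats]:
    """Apply the task analysis to resting data as if stimulation had been
    delivered; with no condition-dependent truth the expected contrast is
    null."""
    _, corrected, _ = group_condition_analysis(resting, basis=basis,
                                               config=config)
    return corrected


def group_difference_spectrum(datasets: list[SubjectDataset],
                              basis: BasisSet | None = None,
                              ) -> tuple[np.ndarray, int]:
    """Across-subject difference spectrum (stimulation - baseline) built
    from line-matched condition sums; returns the difference and the number
    of contributing spectra per condition."""
    from .params import spectrum as _spectrum
    from .pipeline import preprocess_series
    from .preprocess import combine_by_condition, reduce_block_data
    from .boldcorrect import condition_linewidths, match_linewidth

    stim_total = base_total = None
    n_per_condition = 0
    for ds in datasets:
        params = ds.fids.params
        series, _, _ = preprocess_series(ds)
        reduced = reduce_block_data(series, ds.design)
        sums = combine_by_condition(reduced)
        base_fid, n_base = sums[BASELINE]
        stim_fid, _ = sums[STIMULATION]
        lw_base, lw_stim = condition_linewidths(base_fid, stim_fid, params)
        if lw_base.fwhm > lw_stim.fwhm:
            stim_fid = match_linewidth(stim_fid, lw_stim.fwhm, lw_base.fwhm,
                                       params)
        s = _spectrum(stim_fid, params)
        b = _spectrum(base_fid, params)
        stim_total = s if stim_total is None else stim_total + s
        base_total = b if base_total is None else base_total + b
        n_per_condition += n_base
    return difference_spectrum(stim_total, base_total), n_per_condition
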