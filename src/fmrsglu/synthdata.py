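"""Synthetic combined fMRI-MRS datasets.

This module generates per-TR short-TE proton spectra with the statistical
structure the analysis pipeline assumes: a metabolite panel of simplified
Lorentzian multiplets, a ~2 % glutamate elevation during stimulation blocks,
global BOLD-induced line narrowing (9.72 -> 9.51 Hz on the tCr singlet by
default), frequency drift, per-TR phase jitter, an eddy-current phase shared
with the unsuppressed-water reference, complex Gaussian noise, and an
HRF-convolved block BOLD series with a 1.43 % plateau.

The defaults *are* the study conditions; they are not tuning knobs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .params import (
    BASELINE,
    STIMULATION,
    AcquisitionParams,
    BlockDesign,
    ConfigError,
    DataError,
    FidSeries,
    spectrum,
)

WATER_PPM = 4.7
WATER_AMPLITUDE = 1.0  # water-reference scale; institutional units are
                       # defined relative to this amplitude (k = 1)


@dataclass(frozen=True)
class ResonanceSpec:
    """One metabolite (or macromolecule) as a weighted set of Lorentzians.

    ``components`` are (ppm, weight) pairs; weights are normalised to sum to
    one so a unit concentration contributes unit total signal at t = 0.
    ``base_fwhm`` is *extra* Lorentzian width on top of the global
    (condition-dependent) width, used for broad macromolecule humps.
    """

    metabolite: str
    chemical_shift: float
    relative_amplitude: float = 1.0
    base_fwhm: float = 0.0
    multiplet_offsets: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.relative_amplitude < 0:
            raise ConfigError("relative_amplitude must be >= 0")
        if not (0.0 <= self.chemical_shift <= 10.0):
            raise ConfigError("chemical_shift must lie in [0, 10] ppm")

    @property
    def components(self) -> tuple[tuple[float, float], ...]:
        if self.multiplet_offsets:
            total = sum(w for _, w in self.multiplet_offsets)
            return tuple((p, w / total) for p, w in self.multiplet_offsets)
        return ((self.chemical_shift, 1.0),)


# Simplified panel: literature chemical shifts, weights approximating proton
# numbers.  The split NAA singlet/multiplet mirrors common 7 T practice; the
# tCr singlet components sit at 3.03 ppm and the CH2 resonances 0.017 ppm
# apart, which is what makes Cr/PCr individually ill-determined but their sum
# well determined.  Macromolecules are four broad humps (~40 Hz total width).
_PANEL: tuple[ResonanceSpec, ...] = (
    ResonanceSpec("Glu", 2.35, multiplet_offsets=(
        (3.746, 0.2), (2.042, 0.2), (2.112, 0.2), (2.336, 0.2), (2.352, 0.2))),
    ResonanceSpec("Gln", 2.44, multiplet_offsets=(
        (3.757, 0.2), (2.129, 0.2), (2.432, 0.3), (2.454, 0.3))),
    ResonanceSpec("GABA", 2.28, multiplet_offsets=(
        (3.013, 0.33), (2.284, 0.33), (1.889, 0.34))),
    ResonanceSpec("sNAA", 2.008),
    ResonanceSpec("mNAA", 2.49, multiplet_offsets=(
        (2.490, 0.4), (2.672, 0.4), (4.382, 0.2))),
    ResonanceSpec("Cr", 3.027, multiplet_offsets=((3.027, 0.6), (3.913, 0.4))),
    ResonanceSpec("PCr", 3.029, multiplet_offsets=((3.029, 0.6), (3.930, 0.4))),
    ResonanceSpec("GPC", 3.212),
    ResonanceSpec("PCho", 3.209),
    ResonanceSpec("Ins", 3.52, multiplet_offsets=(
        (3.522, 0.4), (3.614, 0.4), (4.054, 0.2))),
    ResonanceSpec("GSH", 2.95, multiplet_offsets=(
        (2.951, 0.4), (2.157, 0.2), (2.546, 0.2), (3.769, 0.2))),
    ResonanceSpec("Lac", 1.31, multiplet_offsets=((1.313, 0.75), (4.097, 0.25))),
    ResonanceSpec("MM09", 0.91, base_fwhm=30.0),
    ResonanceSpec("MM12", 1.21, base_fwhm=30.0),
    ResonanceSpec("MM14", 1.43, base_fwhm=30.0),
    ResonanceSpec("MM20", 2.05, base_fwhm=30.0),
)

#: Default baseline concentrations (institutional units).  Baseline glutamate
#: is 7.8125 I.U. so that a 1.92 % stimulation increase equals 0.15 I.U.
DEFAULT_CONCENTRATIONS: dict[str, float] = {
    "Glu": 7.8125, "Gln": 2.5, "GABA": 1.2, "sNAA": 9.0, "mNAA": 3.0,
    "Cr": 4.0, "PCr": 4.0, "GPC": 0.6, "PCho": 0.7, "Ins": 6.0,
    "GSH": 1.4, "Lac": 0.8, "MM09": 3.0, "MM12": 2.0, "MM14": 2.5,
    "MM20": 3.0,
}


@dataclass(frozen=True)
class BasisSet:
    """Metabolite panel used both to synthesise data and as fit dictionary."""

    resonances: tuple[ResonanceSpec, ...]

    def __post_init__(self) -> None:
        if not self.resonances:
            raise ConfigError("basis must contain at least one resonance")
        names = [r.metabolite for r in self.resonances]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate metabolite names in basis")

    @property
    def names(self) -> list[str]:
        return [r.metabolite for r in self.resonances]

    def __getitem__(self, name: str) -> ResonanceSpec:
        for r in self.resonances:
            if r.metabolite == name:
                return r
        raise KeyError(name)

    def subset(self, names: list[str]) -> "BasisSet":
        return BasisSet(tuple(self[n] for n in names))


def build_default_basis() -> BasisSet:
    """The default reduced metabolite panel (12 metabolites + 4 MM humps)."""
    return BasisSet(_PANEL)


def synthesize_fid(resonances, concentrations: dict[str, float], fwhm: float,
                   params: AcquisitionParams) -> np.ndarray:
    """Noiseless complex FID for a set of Lorentzian resonances.

    Each component contributes ``c * a * w * exp(i*2*pi*f*t - pi*width*t)``
    with ``width = fwhm + base_fwhm``; its Fourier transform is a Lorentzian
    of that FWHM (Hz) at the component's chemical shift.
    """
    if fwhm <= 0:
        raise ConfigError("fwhm must be positive")
    if isinstance(resonances, BasisSet):
        resonances = resonances.resonances
    t = params.time_axis()
    fid = np.zeros(params.n_points, dtype=complex)
    for res in resonances:
        c = concentrations.get(res.metabolite, 0.0)
        if c < 0:
            raise DataError(f"negative concentration for {res.metabolite}")
        if c == 0:
            continue
        width = fwhm + res.base_fwhm
        for ppm, w in res.components:
            f = params.ppm_to_hz(ppm)
            fid += (c * res.relative_amplitude * w
                    * np.exp((2j * np.pi * f - np.pi * width) * t))
    return fid


def eddy_phase(t: np.ndarray, amplitude: float = 0.5, tau: float = 0.05,
               freq: float = 20.0) -> np.ndarray:
    """Decaying oscillatory eddy-current phase (rad): A*exp(-t/tau)*sin(2*pi*f*t)."""
    return amplitude * np.exp(-t / tau) * np.sin(2 * np.pi * freq * t)


def water_reference_fid(params: AcquisitionParams, fwhm: float,
                        eddy: tuple[float, float, float] | None) -> np.ndarray:
    """Unsuppressed-water FID (noiseless, on-carrier) carrying the eddy phase."""
    t = params.time_axis()
    fid = WATER_AMPLITUDE * np.exp(-np.pi * fwhm * t).astype(complex)
    if eddy is not None:
        fid = fid * np.exp(1j * eddy_phase(t, *eddy))
    return fid


def calibrated_noise_sd(params: AcquisitionParams, basis: BasisSet,
                        concentrations: dict[str, float], fwhm: float,
                        csf_fraction: float = 0.0,
                        target_snr: float = 10.0) -> float:
    """Time-domain noise SD giving a single-TR sNAA peak SNR of ``target_snr``.

    SNR is the real-spectrum peak height of the NAA singlet divided by the
    spectral noise SD (= time-domain SD * sqrt(n_points)).
    """
    conc = {k: v * (1.0 - csf_fraction) for k, v in concentrations.items()}
    fid = synthesize_fid(basis, conc, fwhm, params)
    spec = spectrum(fid).real
    ppm = params.ppm_axis()
    i = np.argmin(np.abs(ppm - 2.008))
    peak = spec[max(0, i - 3): i + 4].max()
    return float(peak / (target_snr * np.sqrt(params.n_points)))


@dataclass
class GroundTruth:
    """Simulation ground truth for one subject (or the group mean).

    Units: concentrations in I.U., widths in Hz, BOLD amplitude and glutamate
    increase in percent, drift in Hz per TR, jitter in degrees.
    """

    baseline_concentrations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    stim_glu_increase: float = 1.92          # % of baseline during stimulation
    baseline_tcr_fwhm: float = 9.72          # Hz
    stim_tcr_fwhm: float = 9.51              # Hz (narrowing during activation)
    bold_amplitude: float = 1.43             # % signal change
    bold_noise_sd: float = 0.3               # % per TR
    drift_rate: float = 0.02                 # Hz per TR, cumulative
    phase_jitter_sd: float = 5.0             # degrees
    eddy_params: tuple[float, float, float] | None = (0.5, 0.05, 20.0)
    noise_sd: float | None = None            # time-domain; None -> SNR-10 calibration
    csf_fraction: float = 0.0816

    def __post_init__(self) -> None:
        if self.stim_tcr_fwhm > self.baseline_tcr_fwhm:
            raise ConfigError("stimulation width must not exceed baseline width "
                              "(BOLD narrows, it does not broaden)")
        if any(v < 0 for v in self.baseline_concentrations.values()):
            raise ConfigError("concentrations must be >= 0")
        if not (0.0 <= self.csf_fraction < 1.0):
            raise ConfigError("csf_fraction must be in [0, 1)")

    def resolved_noise_sd(self, params: AcquisitionParams,
                          basis: BasisSet) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return calibrated_noise_sd(params, basis, self.baseline_concentrations,
                                   self.baseline_tcr_fwhm, self.csf_fraction)


@dataclass
class SubjectDataset:
    """Everything acquired for one simulated subject plus the carried truth."""

    fids: FidSeries
    water_reference: np.ndarray
    bold: np.ndarray
    design: BlockDesign
    csf_fraction: float
    truth: GroundTruth
    seed: int


def _hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR resolution."""
    from scipy.special import gamma as G
    t = np.arange(0.0, duration + 1e-9, tr)
    h = (t ** 5 * np.exp(-t) / G(6.0)) - (t ** 15 * np.exp(-t) / (6.0 * G(16.0)))
    return h


def simulate_bold(design: BlockDesign, amplitude_pct: float, tr: float,
                  noise_sd: float, seed: int | np.random.Generator) -> np.ndarray:
    """ROI-mean BOLD series: HRF-convolved block regressor on a 100 baseline.

    The regressor is scaled so the plateau percent-signal-change during long
    stimulation blocks equals ``amplitude_pct``; ``noise_sd`` is white noise
    in percent of baseline.
    """
    if amplitude_pct < 0:
        raise ConfigError("amplitude_pct must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    box = (design.labels(tr) == STIMULATION).astype(float)
    h = _hrf(tr)
    reg = np.convolve(box, h)[: len(box)]
    total = h.sum()
    if total > 0:
        reg = reg / total
    signal = 100.0 + amplitude_pct * reg
    return signal + noise_sd * rng.standard_normal(len(box))


def estimate_bold_psc(bold: np.ndarray, design: BlockDesign, tr: float) -> float:
    """Percent signal change: plateau (final half of stimulation blocks)
    versus the final half of baseline blocks, where the HRF has settled."""
    labels = design.labels(tr)
    per = design.trs_per_block(tr)
    within = np.arange(len(labels)) % per
    plateau = within >= per // 2
    stim = bold[(labels == STIMULATION) & plateau].mean()
    base = bold[(labels == BASELINE) & plateau].mean()
    return 100.0 * (stim - base) / base


def simulate_subject(params: AcquisitionParams, design: BlockDesign,
                     truth: GroundTruth, seed: int,
                     basis: BasisSet | None = None,
                     subject_id: str = "sim") -> SubjectDataset:
    """Simulate one subject's interleaved fMRI-MRS acquisition.

    Per-TR FIDs carry the condition-dependent glutamate level and global
    (T2*-type) linewidth, cumulative frequency drift, per-TR phase jitter,
    the eddy-current phase (shared with the water reference), and complex
    Gaussian noise.  Bit-reproducible for a fixed seed.
    """
    if seed is None:
        raise ConfigError("a seed is required; simulations must be reproducible")
    basis = basis or build_default_basis()
    labels = design.labels(params.tr)
    n_trs = design.n_trs(params.tr)
    if n_trs != params.n_averages:
        raise ConfigError(
            f"design implies {n_trs} TRs but params.n_averages={params.n_averages}")
    rng = np.random.default_rng(seed)
    t = params.time_axis()
    tissue = 1.0 - truth.csf_fraction
    sigma = truth.resolved_noise_sd(params, basis)

    conc_base = {k: v * tissue for k, v in truth.baseline_concentrations.items()}
    conc_stim = dict(conc_base)
    conc_stim["Glu"] = conc_stim.get("Glu", 0.0) * (1 + truth.stim_glu_increase / 100.0)

    pure = {
        BASELINE: synthesize_fid(basis, conc_base, truth.baseline_tcr_fwhm, params),
        STIMULATION: synthesize_fid(basis, conc_stim, truth.stim_tcr_fwhm, params),
    }
    ec = (np.exp(1j * eddy_phase(t, *truth.eddy_params))
          if truth.eddy_params is not None else 1.0)

    fids = np.empty((n_trs, params.n_points), dtype=complex)
    for i, lab in enumerate(labels):
        fid = pure[lab]
        df = truth.drift_rate * i
        phi = np.deg2rad(truth.phase_jitter_sd) * rng.standard_normal()
        fid = fid * np.exp(1j * (2 * np.pi * df * t + phi)) * ec
        noise = sigma * (rng.standard_normal(params.n_points)
                         + 1j * rng.standard_normal(params.n_points))
        fids[i] = fid + noise

    water = water_reference_fid(params, truth.baseline_tcr_fwhm, truth.eddy_params)
    bold = simulate_bold(design, truth.bold_amplitude, params.tr,
                         truth.bold_noise_sd, rng)
    series = FidSeries(fids=fids, condition_labels=labels, params=params,
                       subject_id=subject_id)
    return SubjectDataset(fids=series, water_reference=water, bold=bold,
                          design=design, csf_fraction=truth.csf_fraction,
                          truth=truth, seed=seed)


@dataclass(frozen=True)
class TruthDistribution:
    """Between-subject SDs around the group-mean ground truth.

    Width SDs follow the reported across-subject spread (which is essentially
    all biological at condition-level measurement precision); the glutamate
    effect SD is small because the observed across-subject spread of the
    percent change is nearly saturated by spectral measurement noise.
    """

    glu_increase_sd: float = 0.6          # percentage points
    baseline_fwhm_sd: float = 0.85        # Hz
    narrowing_sd: float = 0.05            # Hz, SD of the 0.21 Hz narrowing
    bold_amplitude_sd: float = 0.61       # % (0.17 s.e.m. * sqrt(13))
    csf_sd: float = 0.0358
    concentration_scale_sd: float = 0.05  # multiplicative, all metabolites

    @classmethod
    def none(cls) -> "TruthDistribution":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def perturb_truth(truth: GroundTruth, dist: TruthDistribution,
                  rng: np.random.Generator) -> GroundTruth:
    """Draw one subject's truth around the group means."""
    scale = max(0.2, 1.0 + dist.concentration_scale_sd * rng.standard_normal())
    base_fwhm = float(np.clip(
        truth.baseline_tcr_fwhm + dist.baseline_fwhm_sd * rng.standard_normal(),
        5.0, 16.0))
    narrow = truth.baseline_tcr_fwhm - truth.stim_tcr_fwhm
    narrow = float(max(0.0, narrow + dist.narrowing_sd * rng.standard_normal()))
    out = copy.deepcopy(truth)
    out.baseline_concentrations = {
        k: v * scale for k, v in truth.baseline_concentrations.items()}
    out.stim_glu_increase = truth.stim_glu_increase + \
        dist.glu_increase_sd * rng.standard_normal()
    out.baseline_tcr_fwhm = base_fwhm
    out.stim_tcr_fwhm = base_fwhm - narrow
    out.bold_amplitude = float(max(
        0.0, truth.bold_amplitude + dist.bold_amplitude_sd * rng.standard_normal()))
    out.csf_fraction = float(np.clip(
        truth.csf_fraction + dist.csf_sd * rng.standard_normal(), 0.0, 0.35))
    return out


def simulate_group(n_subjects: int = 13,
                   params: AcquisitionParams | None = None,
                   design: BlockDesign | None = None,
                   truth: GroundTruth | None = None,
                   dist: TruthDistribution | None = None,
                   seed: int = 0,
                   basis: BasisSet | None = None) -> list[SubjectDataset]:
    """Simulate an independent cohort; subject seeds derive from the master seed."""
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    params = params or AcquisitionParams()
    design = design or BlockDesign()
    truth = truth or GroundTruth()
    dist = dist or TruthDistribution()
    basis = basis or build_default_basis()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_truth = perturb_truth(truth, dist, rng)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        out.append(simulate_subject(params, design, sub_truth, sub_seed,
                                    basis=basis, subject_id=f"sub-{i + 1:02d}"))
    return out
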