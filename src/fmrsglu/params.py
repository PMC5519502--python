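"""Acquisition metadata, block designs, and spectral axis conventions.

Conventions used throughout the package:

* FIDs are complex time-domain arrays sampled at ``dwell = 1/spectral_width``.
* Spectra are obtained by FFT with the first FID point halved (so a pure
  Lorentzian gives a flat baseline) and ``fftshift`` applied, i.e. the
  frequency axis ascends from ``-sw/2`` to ``+sw/2``.
* The carrier sits on the water resonance at ``reference_ppm`` (default
  4.7 ppm), so a resonance at chemical shift ``delta`` ppm has frequency
  offset ``(delta - reference_ppm) * spectrometer_freq`` Hz.  Plots follow
  the NMR convention (ppm decreasing left to right); arrays are stored with
  ascending ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when input data violate a documented contract."""


class ConfigError(ValueError):
    """Raised when configuration values are inconsistent."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectral acquisition metadata for a semi-LASER-like 7 T protocol.

    Defaults mirror the interleaved fMRI-MRS protocol this package
    emulates: TE 36 ms, TR 4 s, 128 averages.  Spectrometer frequency is
    fixed at 297.2 MHz (7 T proton frequency) and digitization at
    6000 Hz / 2048 complex points, enough to resolve 0.1-ppm-spaced peaks.
    """

    spectrometer_freq: float = 297.2  # MHz, i.e. Hz per ppm
    spectral_width: float = 6000.0    # Hz
    n_points: int = 2048
    tr: float = 4.0                   # s
    te: float = 0.036                 # s, metadata only
    n_averages: int = 128
    reference_ppm: float = 4.7        # carrier position (water)

    def __post_init__(self) -> None:
        if self.spectral_width <= 0:
            raise ConfigError("spectral_width must be positive")
        if self.n_points < 512:
            raise ConfigError("n_points must be >= 512")
        if self.tr <= 0 or self.n_averages < 1:
            raise ConfigError("tr and n_averages must be positive")

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width

    @property
    def hz_per_ppm(self) -> float:
        return self.spectrometer_freq

    def time_axis(self, n: int | None = None) -> np.ndarray:
        """Sampling times (s) of the FID."""
        n = self.n_points if n is None else n
        return np.arange(n) * self.dwell

    def freq_axis(self, n: int | None = None) -> np.ndarray:
        """Frequency offsets from the carrier (Hz), ascending."""
        n = self.n_points if n is None else n
        return np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell))

    def ppm_axis(self, n: int | None = None) -> np.ndarray:
        """Chemical-shift axis (ppm), ascending with frequency."""
        return self.reference_ppm + self.freq_axis(n) / self.hz_per_ppm

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ppm) - self.reference_ppm) * self.hz_per_ppm

    @property
    def spectral_resolution(self) -> float:
        """Hz per spectral point at the native grid."""
        return self.spectral_width / self.n_points


def spectrum(fid: np.ndarray, params: AcquisitionParams | None = None,
             zero_fill: int = 1) -> np.ndarray:
    """Complex spectrum of a FID on the fftshifted (ascending) grid.

    The first point is halved before the FFT, the standard discrete
    correction that keeps the baseline of a Lorentzian flat.  ``zero_fill``
    multiplies the transform length (2 doubles the grid density).
    """
    fid = np.asarray(fid, dtype=complex)
    x = fid.copy()
    x[..., 0] *= 0.5
    n = fid.shape[-1] * int(zero_fill)
    return np.fft.fftshift(np.fft.fft(x, n=n, axis=-1), axes=-1)


BASELINE = "baseline"
STIMULATION = "stimulation"


@dataclass(frozen=True)
class BlockDesign:
    """Alternating baseline/stimulation block design.

    Defaults: 64-s blocks, 4 cycles, baseline first, and the first two TRs
    of every block discarded in the condition-contrast path (the period
    where the hemodynamic response is still settling).
    """

    block_length: float = 64.0       # s
    n_cycles: int = 4
    first_condition: str = BASELINE
    discard_per_block: int = 2       # TRs dropped at each block start

    def __post_init__(self) -> None:
        if self.first_condition not in (BASELINE, STIMULATION):
            raise ConfigError(f"unknown condition {self.first_condition!r}")
        if self.n_cycles < 1 or self.block_length <= 0:
            raise ConfigError("n_cycles and block_length must be positive")

    def trs_per_block(self, tr: float) -> int:
        n = self.block_length / tr
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("block_length must be divisible by tr")
        n = int(round(n))
        if self.discard_per_block >= n:
            raise ConfigError("discard_per_block must be < TRs per block")
        return n

    def n_blocks(self) -> int:
        return 2 * self.n_cycles

    def n_trs(self, tr: float) -> int:
        return self.n_blocks() * self.trs_per_block(tr)

    def labels(self, tr: float) -> np.ndarray:
        """Per-TR condition labels for the full run."""
        per = self.trs_per_block(tr)
        order = [self.first_condition,
                 STIMULATION if self.first_condition == BASELINE else BASELINE]
        return np.array([order[b % 2] for b in range(self.n_blocks())
                         for _ in range(per)])

    def block_index(self, tr: float) -> np.ndarray:
        per = self.trs_per_block(tr)
        return np.repeat(np.arange(self.n_blocks()), per)


@dataclass
class FidSeries:
    """Ordered per-TR complex FIDs with condition labels and provenance.

    ``n_summed`` tracks how many raw averages each entry contains (1 for raw
    TRs, 4 after binning, 56 after condition summation) so that
    water-referenced scaling can normalise per average.
    """

    fids: np.ndarray                  # (n_tr, n_points) complex
    condition_labels: np.ndarray      # (n_tr,) str
    params: AcquisitionParams
    subject_id: str = "sim"
    times: np.ndarray | None = None   # s, acquisition (or bin-centre) times
    n_summed: np.ndarray | None = None
    provenance_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids, dtype=complex)
        if self.fids.ndim != 2:
            raise DataError("fids must be a 2-D (n_tr, n_points) array")
        self.condition_labels = np.asarray(self.condition_labels)
        if len(self.condition_labels) != len(self.fids):
            raise DataError("labels length must equal number of FIDs")
        if self.times is None:
            self.times = np.arange(len(self.fids)) * self.params.tr
        if self.n_summed is None:
            self.n_summed = np.ones(len(self.fids), dtype=int)

    def __len__(self) -> int:
        return len(self.fids)

    def require_absent(self, flag: str) -> None:
        if flag in self.provenance_flags:
            raise DataError(f"correction {flag!r} already applied")

    def replaced(self, fids: np.ndarray, flag: str, **kw) -> "FidSeries":
        out = FidSeries(
            fids=fids,
            condition_labels=kw.get("condition_labels", self.condition_labels).copy(),
            params=self.params,
            subject_id=self.subject_id,
            times=kw.get("times", self.times).copy(),
            n_summed=kw.get("n_summed", self.n_summed).copy(),
            provenance_flags=self.provenance_flags + [flag],
        )
        return out
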