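"""Shared fixtures: default acquisition objects and cached simulations.

Expensive simulations are session-scoped so several tests can share one
realization; anything mutating a series works on fresh copies.
"""

from __future__ import annotations

import numpy as np
import pytest

from fmrsglu import (
    AcquisitionParams,
    BlockDesign,
    GroundTruth,
    build_default_basis,
    simulate_subject,
)


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def design() -> BlockDesign:
    return BlockDesign()


@pytest.fixture(scope="session")
def basis():
    return build_default_basis()


@pytest.fixture(scope="session")
def clean_truth() -> GroundTruth:
    """No noise, no drift, no jitter, no eddy currents."""
    return GroundTruth(noise_sd=0.0, drift_rate=0.0, phase_jitter_sd=0.0,
                       eddy_params=None)


@pytest.fixture(scope="session")
def default_subject(params, design):
    """One subject at the default study conditions."""
    return simulate_subject(params, design, GroundTruth(), seed=20_001)


@pytest.fixture(scope="session")
def clean_subject(params, design, clean_truth):
    return simulate_subject(params, design, clean_truth, seed=20_002)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def measure_fwhm(spec_real: np.ndarray, freqs: np.ndarray) -> float:
    """Interpolated full width at half maximum of a single peak."""
    pk = spec_real.max()
    i = int(np.argmax(spec_real))
    half = pk / 2.0

    def cross(j, step):
        while 0 < j < len(spec_real) - 1 and spec_real[j + step] > half:
            j += step
        a, b = spec_real[j], spec_real[j + step]
        frac = (a - half) / (a - b)
        return freqs[j] + frac * (freqs[j + step] - freqs[j])

    return abs(cross(i, 1) - cross(i, -1))
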