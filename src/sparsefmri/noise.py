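"""Temporal noise synthesis at a controlled temporal SNR.

Measurement noise is modeled as white Gaussian noise (an AR(1) option exists
for exploring serially correlated noise, off by default).  A unit-variance
draw is rescaled so that

    RMS(noise) = RMS(signal) / 10**(tSNR_dB / 20)

where the signal RMS is taken over the *demeaned* ideal per-TA response: tSNR
here is a signal-fluctuation-to-noise ratio in decibels, matching the −20..10
dB regime of typical voxel time series.  The rescaling uses the sample RMS of
the unit draw, so the requested tSNR is realized exactly on every draw, not
just in expectation.

Within one simulated session the same unit draw is reused across all tSNR
levels (pass the same ``seed``): tSNR is a within-iteration parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateNoiseError, DegenerateSignalError

__all__ = [
    "NOISELESS",
    "SimulatedSeries",
    "unit_noise",
    "scale_noise_to_tsnr",
    "simulate_series",
    "measured_tsnr_db",
]

#: Sentinel tSNR for a noise-free series (y = ideal exactly).
NOISELESS = math.inf


def _rms(v: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(v))))


@dataclass(frozen=True)
class SimulatedSeries:
    """Ideal response, scaled noise, and their sum at a stated tSNR."""

    ideal: np.ndarray
    noise: np.ndarray
    tsnr_db: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "ideal", np.asarray(self.ideal, dtype=float))
        object.__setattr__(self, "noise", np.asarray(self.noise, dtype=float))

    @property
    def y(self) -> np.ndarray:
        return self.ideal + self.noise

    def write(self, path) -> None:
        data = np.column_stack(
            [np.arange(self.ideal.size), self.ideal, self.noise, self.y]
        )
        np.savetxt(path, data, fmt="%d\t%.9g\t%.9g\t%.9g",
                   header="ta_index\tideal\tnoise\ty", comments="")


def unit_noise(n: int, seed: int, rho: float = 0.0) -> np.ndarray:
    """n standard-normal draws; with rho != 0, an AR(1) process instead.

    The AR(1) variant x_t = rho*x_{t-1} + sqrt(1-rho^2)*e_t has unit marginal
    variance, so downstream tSNR scaling is unaffected.
    """
    if n < 1:
        raise ValueError(f"need at least one sample, got n={n}")
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    if rho == 0.0:
        return e
    x = np.empty(n)
    x[0] = e[0]
    c = math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + c * e[t]
    return x


def scale_noise_to_tsnr(
    ideal: np.ndarray, unit: np.ndarray, tsnr_db: float
) -> np.ndarray:
    """Rescale a unit draw so the series hits the requested tSNR exactly."""
    ideal = np.asarray(ideal, dtype=float)
    unit = np.asarray(unit, dtype=float)
    if ideal.shape != unit.shape:
        raise ValueError("ideal and unit noise vectors must have equal length")
    signal_rms = _rms(ideal - ideal.mean())
    if signal_rms <= 1e-15:
        raise DegenerateSignalError("ideal response is constant; tSNR undefined")
    if tsnr_db == NOISELESS:
        return np.zeros_like(unit)
    unit_rms = _rms(unit)
    if unit_rms <= 1e-15:
        raise DegenerateNoiseError("unit noise vector is identically zero")
    return unit * (signal_rms / (10.0 ** (tsnr_db / 20.0) * unit_rms))


def simulate_series(
    ideal: np.ndarray, tsnr_db: float, seed: int, rho: float = 0.0
) -> SimulatedSeries:
    """Ideal response plus tSNR-calibrated noise.

    The same seed yields the same unit draw at every tSNR level, so series at
    different tSNR within one simulated session differ only by a scalar
    rescaling of their noise.
    """
    ideal = np.asarray(ideal, dtype=float)
    unit = unit_noise(ideal.size, seed, rho=rho)
    noise = scale_noise_to_tsnr(ideal, unit, tsnr_db)
    return SimulatedSeries(ideal=ideal, noise=noise, tsnr_db=tsnr_db, seed=seed)


def measured_tsnr_db(series: SimulatedSeries) -> float:
    """Recover 20*log10(RMS(demeaned ideal) / RMS(noise)) from a series."""
    signal_rms = _rms(series.ideal - series.ideal.mean())
    noise_rms = _rms(series.noise)
    if noise_rms == 0.0:
        return NOISELESS
    return 20.0 * math.log10(signal_rms / noise_rms)
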