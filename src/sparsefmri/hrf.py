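"""Canonical hemodynamic response kernel.

The BOLD response to a brief neural event is modeled with the field-standard
"canonical" double-gamma shape: a positive gamma peaking ~6 s after onset
minus a smaller gamma (the post-stimulus undershoot) peaking ~16 s, with unit
dispersions and a 6:1 peak-to-undershoot ratio, supported on [0, 32] s.

Absolute kernel amplitude is irrelevant to the model: :func:`calibrate`
rescales the kernel so that its convolution with a solitary 1.0 s unit event
peaks at exactly 1.0.  Under this convention an effect size (GLM beta) of 1.0
corresponds to a 1% BOLD signal change for a 1 s stimulus, and all simulated
amplitudes downstream are in percent-signal-change units.

Convolution uses rectangular (sample-and-hold) integration on the kernel's dt
grid: ``response = numpy.convolve(timeline, samples)[:n] * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import DegenerateKernelError, InvalidResolutionError

__all__ = ["HRFKernel", "make_canonical_hrf", "calibrate", "write_kernel"]

#: Double-gamma shape parameters (seconds).  Delay / dispersion give the gamma
#: shape parameter; the undershoot is divided by the peak:undershoot ratio.
PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
PEAK_DISPERSION = 1.0
UNDERSHOOT_DISPERSION = 1.0
PEAK_UNDERSHOOT_RATIO = 6.0
SUPPORT = 32.0


@dataclass(frozen=True)
class HRFKernel:
    """Sampled HRF kernel at resolution ``dt`` on [0, duration] seconds."""

    dt: float
    samples: np.ndarray
    scale_factor: float = 1.0
    calibrated: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidResolutionError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        """Kernel support in seconds."""
        return (self.samples.size - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def response_to(self, timeline: np.ndarray) -> np.ndarray:
        """Causal convolution with a stimulation timeline at the same dt.

        The result is truncated to the timeline's length (the analysis
        window); rectangular integration contributes the factor ``dt``.
        """
        timeline = np.asarray(timeline, dtype=float)
        return np.convolve(timeline, self.samples)[: timeline.size] * self.dt


def make_canonical_hrf(dt: float = 0.1) -> HRFKernel:
    """Sample the canonical double-gamma HRF every ``dt`` seconds on [0, 32] s.

    Parameters
    ----------
    dt:
        Temporal resolution in seconds; must satisfy 0 < dt <= 0.5 so the
        ~1 s-scale dynamics of the response are resolved.

    Returns
    -------
    HRFKernel
        Uncalibrated kernel (``calibrated`` is False); at dt = 0.1 s it has
        321 samples with a single positive peak near 5 s followed by a smaller
        negative undershoot.
    """
    if dt <= 0 or dt > 0.5:
        raise InvalidResolutionError(
            f"dt must lie in (0, 0.5] seconds, got {dt}"
        )
    t = np.arange(round(SUPPORT / dt) + 1) * dt
    peak = stats.gamma.pdf(t, PEAK_DELAY / PEAK_DISPERSION, scale=PEAK_DISPERSION)
    undershoot = stats.gamma.pdf(
        t, UNDERSHOOT_DELAY / UNDERSHOOT_DISPERSION, scale=UNDERSHOOT_DISPERSION
    )
    return HRFKernel(dt=dt, samples=peak - undershoot / PEAK_UNDERSHOOT_RATIO)


def calibrate(kernel: HRFKernel) -> HRFKernel:
    """Scale the kernel so a solitary 1.0 s event evokes a peak of exactly 1.0.

    The calibration is computed numerically on the kernel's own dt grid with
    the same convolution contract as :meth:`HRFKernel.response_to`, so the
    invariant ``max(response to 1 s event) == 1.0`` holds exactly as
    implemented.  Calibrating an already-calibrated kernel is a no-op up to
    floating-point roundoff.
    """
    n_event = round(1.0 / kernel.dt)
    event = np.ones(n_event)
    response = np.convolve(event, kernel.samples) * kernel.dt
    peak = response.max() if response.size else 0.0
    if peak <= 0.0:
        raise DegenerateKernelError("kernel has no positive peak to calibrate")
    s = 1.0 / peak
    return replace(
        kernel,
        samples=kernel.samples * s,
        scale_factor=kernel.scale_factor * s,
        calibrated=True,
    )


def write_kernel(kernel: HRFKernel, path) -> None:
    """Export the kernel as two-column plain text (time_s, amplitude)."""
    data = np.column_stack([kernel.times, kernel.samples])
    np.savetxt(path, data, fmt="%.6f\t%.9g", header="time_s\tamplitude")
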