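"""Model regressors for sparsely sampled fMRI time series.

Two competing encodings of the task are built for each condition:

* ``x_hrf`` — the physiologically informed regressor: the 0/1 stimulation
  timeline is convolved with the calibrated canonical HRF, the resulting ideal
  response is averaged over each acquisition window (TA), and the per-TA
  vector is demeaned and scaled to peak-to-peak height 1.0, so that a GLM
  parameter estimate of 1.0 signifies a 1% signal change.
* ``x_box`` — the classical boxcar (FIR) regressor: each acquisition in whose
  preceding period an event occurred is coded 1, others 0, then demeaned (no
  peak-to-peak rescaling; it is already 1).  For TRs of 4 s or less the coded
  acquisition is delayed by one additional TR so the sample near the
  hemodynamic peak (~6 s post stimulus) carries the event.

Design matrices assemble these columns with an intercept and optional
Legendre-polynomial drift columns, and report collinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre

from .exceptions import (
    DegenerateRegressorError,
    InvalidResolutionError,
    OverlapError,
)
from .hrf import HRFKernel
from .schedule import AcquisitionDesign, EventSchedule

__all__ = [
    "Timeline",
    "Regressor",
    "DesignMatrix",
    "stimulation_timeline",
    "ideal_response",
    "resample_at_TA",
    "scale_hrf_regressor",
    "hrf_regressor",
    "boxcar_regressor",
    "assemble_design",
]

#: Boxcar events are shifted one TR later for repetition times at or below
#: this, so the coded acquisition falls near the response peak.
BOXCAR_SHIFT_MAX_TR = 4.0

#: Column-pair correlation magnitude above which a design is flagged.
COLLINEARITY_CORR = 0.99


@dataclass(frozen=True)
class Timeline:
    """A vector sampled every ``dt`` seconds over the whole run."""

    dt: float
    values: np.ndarray
    kind: str  # "stimulation" | "response"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass(frozen=True)
class Regressor:
    """One design-matrix column, one entry per acquisition (TA)."""

    values: np.ndarray
    kind: str  # "hrf" | "boxcar"
    condition: str
    mean_removed: float = 0.0
    peak_to_peak_divisor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.kind}"

    def write(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.9g")


@dataclass(frozen=True)
class DesignMatrix:
    names: tuple
    matrix: np.ndarray
    condition_number: float
    collinear_pairs: tuple

    @property
    def n_TA(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def write(self, path) -> None:
        header = "\t".join(self.names)
        np.savetxt(path, self.matrix, fmt="%.9g", delimiter="\t",
                   header=header, comments="")


def stimulation_timeline(
    schedule: EventSchedule, condition: str, dt: float
) -> Timeline:
    """0/1 indicator of stimulation for one condition at resolution dt."""
    n = round(schedule.design.run_length / dt)
    values = np.zeros(n)
    for e in schedule.events:
        if e.condition != condition:
            continue
        i0 = round(e.onset / dt)
        i1 = round((e.onset + e.duration) / dt)
        if abs(e.onset / dt - i0) > 1e-6:
            raise InvalidResolutionError(
                f"onset {e.onset}s does not align with dt={dt}s"
            )
        if values[i0:i1].any():
            raise OverlapError(
                f"events of condition {condition!r} overlap near {e.onset:g}s"
            )
        values[i0: min(i1, n)] = 1.0
    return Timeline(dt=dt, values=values, kind="stimulation")


def ideal_response(stim: Timeline, kernel: HRFKernel) -> Timeline:
    """Convolve a stimulation timeline with the calibrated HRF.

    The response to a solitary 1 s event peaks at 1.0 (the kernel calibration
    contract); overlapping responses add linearly.
    """
    if stim.kind != "stimulation":
        raise ValueError(f"expected a stimulation timeline, got {stim.kind!r}")
    if not kernel.calibrated:
        raise ValueError("kernel must be calibrated before convolution")
    if abs(stim.dt - kernel.dt) > 1e-12:
        raise InvalidResolutionError(
            f"timeline dt={stim.dt}s does not match kernel dt={kernel.dt}s"
        )
    return Timeline(dt=stim.dt, values=kernel.response_to(stim.values),
                    kind="response")


def resample_at_TA(response: Timeline, design: AcquisitionDesign) -> np.ndarray:
    """Average the response over each acquisition window [k·TR, k·TR + TA).

    This is the sparse sampling step: signal evolving between acquisitions is
    invisible to the resulting per-TA vector.
    """
    dt = response.dt
    n_needed = round((design.n_TR - 1) * design.TR / dt) + round(design.TA / dt)
    if response.values.size < n_needed:
        raise ValueError("response timeline does not cover all TA windows")
    w = round(design.TA / dt)
    out = np.empty(design.n_TR)
    for k in range(design.n_TR):
        i0 = round(k * design.TR / dt)
        out[k] = response.values[i0: i0 + w].mean()
    return out


def scale_hrf_regressor(raw: np.ndarray, condition: str = "task") -> Regressor:
    """Demean and peak-to-peak normalize a resampled response vector."""
    raw = np.asarray(raw, dtype=float)
    ptp = raw.max() - raw.min()
    if ptp <= 1e-12:
        raise DegenerateRegressorError(
            "resampled response is constant: no events, or the response is "
            "invisible to the sampling scheme"
        )
    mean = raw.mean()
    return Regressor(
        values=(raw - mean) / ptp,
        kind="hrf",
        condition=condition,
        mean_removed=mean,
        peak_to_peak_divisor=ptp,
    )


def hrf_regressor(
    schedule: EventSchedule, condition: str, kernel: HRFKernel
) -> Regressor:
    """Full pipeline: stimulation timeline → HRF response → TA means → scaling."""
    stim = stimulation_timeline(schedule, condition, kernel.dt)
    raw = resample_at_TA(ideal_response(stim, kernel), schedule.design)
    return scale_hrf_regressor(raw, condition)


def boxcar_regressor(
    schedule: EventSchedule, condition: str, design: AcquisitionDesign | None = None
) -> Regressor:
    """Classical boxcar column: 1 at the acquisition carrying each event.

    Events occur in the silent delay after acquisition k, so the first
    acquisition that samples their response is TA k+1 (the one immediately
    following the event); for TR <= 4 s the event is delayed one further TR
    (TA k+2) so the coded acquisition falls ~6 s after stimulation, near the
    response peak.  Events shifted past the final acquisition are dropped.
    The vector is demeaned only (its height is already 1).
    """
    design = design or schedule.design
    shift = 2 if design.TR <= BOXCAR_SHIFT_MAX_TR else 1
    values = np.zeros(design.n_TR)
    for e in schedule.events:
        if e.condition != condition:
            continue
        k = schedule.tr_index(e.onset) + shift
        if k < design.n_TR:
            values[k] = 1.0
    mean = values.mean()
    return Regressor(
        values=values - mean,
        kind="boxcar",
        condition=condition,
        mean_removed=mean,
        peak_to_peak_divisor=1.0,
    )


def assemble_design(
    regressors: list,
    n_TA: int,
    drift_order: int = 0,
) -> DesignMatrix:
    """Stack intercept, task columns, and Legendre drift columns.

    Drift columns are the Legendre polynomials of orders 1..drift_order
    evaluated on [-1, 1] over the acquisitions and demeaned, so every drift
    column is exactly orthogonal to the intercept.  The condition number of
    the assembled matrix is reported, and column pairs with |correlation|
    above 0.99 are flagged as near-collinear.
    """
    if drift_order < 0:
        raise ValueError("drift_order must be non-negative")
    names = ["intercept"]
    cols = [np.ones(n_TA)]
    for r in regressors:
        if r.values.size != n_TA:
            raise ValueError(
                f"regressor {r.name!r} has length {r.values.size}, "
                f"expected {n_TA}"
            )
        names.append(r.name)
        cols.append(r.values)
    x = np.linspace(-1.0, 1.0, n_TA)
    for order in range(1, drift_order + 1):
        c = np.zeros(order + 1)
        c[order] = 1.0
        col = legendre.legval(x, c)
        names.append(f"drift_{order}")
        cols.append(col - col.mean())
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column names: {', '.join(dupes)}")
    matrix = np.column_stack(cols)
    return DesignMatrix(
        names=tuple(names),
        matrix=matrix,
        condition_number=float(np.linalg.cond(matrix)),
        collinear_pairs=_collinear_pairs(tuple(names), matrix),
    )


def _collinear_pairs(names, matrix):
    pairs = []
    p = matrix.shape[1]
    sd = matrix.std(axis=0)
    centered = matrix - matrix.mean(axis=0)
    for i in range(p):
        for j in range(i + 1, p):
            if sd[i] < 1e-12 or sd[j] < 1e-12:
                # a second constant column duplicates the intercept
                if sd[i] < 1e-12 and sd[j] < 1e-12:
                    pairs.append((names[i], names[j]))
                continue
            r = float(
                centered[:, i] @ centered[:, j]
                / (sd[i] * sd[j] * matrix.shape[0])
            )
            if abs(r) > COLLINEARITY_CORR:
                pairs.append((names[i], names[j]))
    return tuple(pairs)
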