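"""Monte-Carlo sweep over the TR × ISI × tSNR × model grid.

Each replicate emulates one fMRI session: a fresh randomized schedule and a
fresh unit-noise draw (the across-iteration parameters), while tSNR level and
model type vary within the replicate on the identical noisy series.  The
simulated series is

    y = true_amplitude * (demeaned resampled ideal response) + noise

so the HRF-model parameter estimate measures the peak-to-peak amplitude of the
generated response in percent-signal-change units.  More frequent stimulation
yields a larger response amplitude (BOLD additivity) and hence a larger
estimate; the boxcar model, blind to response dynamics, systematically
underestimates it.

Per-replicate results are aggregated into per-cell summaries (mean and normal
95% CI of beta, t, and residual sum of squares over replicates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IncompatibleDesignError
from .glm import GLMResult, fit_ols
from .hrf import HRFKernel, calibrate, make_canonical_hrf
from .noise import NOISELESS, scale_noise_to_tsnr, unit_noise
from .regressors import assemble_design, boxcar_regressor, hrf_regressor
from .schedule import (
    AcquisitionDesign,
    StimulationPlan,
    check_compatibility,
    generate_schedule,
)

__all__ = [
    "DEFAULT_CELLS",
    "DEFAULT_TSNR_GRID",
    "SweepConfig",
    "ReplicateResult",
    "run_replicate",
    "run_sweep",
    "summarize",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: The ten TR × ISI permutations reported by the simulation study (seconds).
DEFAULT_CELLS = (
    (4, 4), (8, 4), (12, 4), (4, 8), (8, 8),
    (3, 3), (6, 3), (9, 3), (6, 6), (9, 9),
)

#: tSNR levels in dB, integer steps from -20 to 10.
DEFAULT_TSNR_GRID = tuple(range(-20, 11))

_MODELS = ("hrf", "boxcar")


@dataclass(frozen=True)
class SweepConfig:
    """Full specification of a Monte-Carlo design sweep."""

    cells: tuple = DEFAULT_CELLS
    tsnr_grid: tuple = DEFAULT_TSNR_GRID
    n_replicates: int = 100
    true_amplitude: float = 1.0
    master_seed: int = 0
    models: tuple = _MODELS
    TA: float = 2.0
    run_length: float = 360.0
    dt: float = 0.1
    post_TA_gap: float = 0.5
    rest_fraction: float = 1.0 / 3.0
    event_duration: float = 1.0
    drift_order: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        unknown = set(self.models) - set(_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        bad = []
        for tr, isi in self.cells:
            report = check_compatibility(self.design(tr), self.plan(isi))
            if not report:
                bad.append(f"TR={tr} x ISI={isi}: {report.reason}")
        if bad:
            raise IncompatibleDesignError(
                "invalid sweep cells:\n" + "\n".join(bad)
            )

    def design(self, TR: float) -> AcquisitionDesign:
        return AcquisitionDesign(
            TR=TR,
            TA=self.TA,
            run_length=self.run_length,
            dt=self.dt,
            post_TA_gap=self.post_TA_gap,
            rest_fraction=self.rest_fraction,
        )

    def plan(self, ISI: float, condition_labels=("task",)) -> StimulationPlan:
        return StimulationPlan(
            ISI=ISI,
            event_duration=self.event_duration,
            condition_labels=condition_labels,
        )


@dataclass(frozen=True)
class ReplicateResult:
    """Everything one simulated session produced."""

    schedule: object
    ideal: np.ndarray
    y: np.ndarray
    tsnr_db: float
    results: dict  # model -> GLMResult
    noiseless_beta: dict  # model -> {condition: beta on the noise-free series}


def _seed_pair(seed_seq: np.random.SeedSequence) -> tuple:
    """Two independent sub-seeds (< 2**31): schedule placement, noise draw."""
    state = seed_seq.generate_state(2)
    return int(state[0]) % 2**31, int(state[1]) % 2**31


def _replicate_parts(design, plan, kernel, schedule_seed, amplitudes,
                     assignment, drift_order):
    """Schedule, per-model design matrices, and the noise-free ideal series."""
    schedule = generate_schedule(design, plan, schedule_seed,
                                 assignment=assignment)
    x_hrf = {c: hrf_regressor(schedule, c, kernel)
             for c in plan.condition_labels}
    x_box = {c: boxcar_regressor(schedule, c)
             for c in plan.condition_labels}
    # The generating response: sum over conditions of amplitude times the
    # demeaned (but not peak-to-peak-normalized) resampled response.
    ideal = np.zeros(design.n_TR)
    for c in plan.condition_labels:
        r = x_hrf[c]
        ideal += amplitudes[c] * r.values * r.peak_to_peak_divisor
    designs = {
        "hrf": assemble_design(
            [x_hrf[c] for c in plan.condition_labels], design.n_TR,
            drift_order=drift_order),
        "boxcar": assemble_design(
            [x_box[c] for c in plan.condition_labels], design.n_TR,
            drift_order=drift_order),
    }
    noiseless_beta = {
        "hrf": {
            c: amplitudes[c] * x_hrf[c].peak_to_peak_divisor
            for c in plan.condition_labels
        }
    }
    return schedule, designs, ideal, noiseless_beta


def run_replicate(
    design: AcquisitionDesign,
    plan: StimulationPlan,
    tsnr_db: float,
    seed: int,
    *,
    models: tuple = _MODELS,
    amplitudes: dict | None = None,
    true_amplitude: float = 1.0,
    kernel: HRFKernel | None = None,
    assignment: str = "balanced",
    drift_order: int = 0,
) -> ReplicateResult:
    """One simulated session: one schedule, one noise draw, all models on one y.

    ``amplitudes`` maps condition label to generating amplitude (percent
    signal change for a 1 s event); by default every condition gets
    ``true_amplitude``.
    """
    report = check_compatibility(design, plan)
    if not report:
        raise IncompatibleDesignError(report.reason)
    if kernel is None:
        kernel = calibrate(make_canonical_hrf(design.dt))
    if amplitudes is None:
        amplitudes = {c: true_amplitude for c in plan.condition_labels}
    schedule_seed, noise_seed = _seed_pair(np.random.SeedSequence(seed))
    schedule, designs, ideal, noiseless_beta = _replicate_parts(
        design, plan, kernel, schedule_seed, amplitudes, assignment,
        drift_order)
    if tsnr_db == NOISELESS:
        noise = np.zeros_like(ideal)
    else:
        unit = unit_noise(ideal.size, noise_seed)
        noise = scale_noise_to_tsnr(ideal, unit, tsnr_db)
    y = ideal + noise
    results = {m: fit_ols(y, designs[m]) for m in models}
    if "boxcar" in models:
        box_fit = fit_ols(ideal, designs["boxcar"])
        noiseless_beta["boxcar"] = {
            c: box_fit[f"{c}_boxcar"][0] for c in plan.condition_labels
        }
    return ReplicateResult(
        schedule=schedule,
        ideal=ideal,
        y=y,
        tsnr_db=tsnr_db,
        results=results,
        noiseless_beta=noiseless_beta,
    )


def run_sweep(config: SweepConfig) -> tuple:
    """Run the full grid; returns ``(summary, raw)`` DataFrames.

    ``raw`` has one row per (cell, replicate, tSNR, model) with the fitted
    task beta, its standard error, t, dof, and the model rss.  ``summary``
    aggregates replicates per (cell, tSNR, model).  Identical configs
    (including master_seed) give bit-identical tables; per-replicate seeds are
    pre-assigned, so results do not depend on execution order.
    """
    kernel = calibrate(make_canonical_hrf(config.dt))
    cell_seqs = np.random.SeedSequence(config.master_seed).spawn(
        len(config.cells))
    amplitudes = {"task": config.true_amplitude}
    rows = []
    for (tr, isi), cell_seq in zip(config.cells, cell_seqs):
        design = config.design(tr)
        plan = config.plan(isi)
        rep_seqs = cell_seq.spawn(config.n_replicates)
        logger.info("cell TR=%g ISI=%g: %d replicates x %d tSNR levels",
                    tr, isi, config.n_replicates, len(config.tsnr_grid))
        for rep, rep_seq in enumerate(rep_seqs):
            schedule_seed, noise_seed = _seed_pair(rep_seq)
            _, designs, ideal, _ = _replicate_parts(
                design, plan, kernel, schedule_seed, amplitudes,
                "balanced", config.drift_order)
            unit = unit_noise(ideal.size, noise_seed)
            for tsnr in config.tsnr_grid:
                noise = scale_noise_to_tsnr(ideal, unit, tsnr)
                y = ideal + noise
                for model in config.models:
                    fit = fit_ols(y, designs[model])
                    beta, se, tstat, _ = fit[f"task_{model}"]
                    rows.append((tr, isi, float(tsnr), model, rep,
                                 beta, se, tstat, fit.dof, fit.rss))
    raw = pd.DataFrame(
        rows,
        columns=["TR", "ISI", "tsnr_db", "model", "replicate",
                 "beta", "se", "t", "dof", "rss"],
    )
    return summarize(raw), raw


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell, tSNR, model) means with normal-approximation 95% CIs."""
    def agg(g):
        n = len(g)
        out = {"n_replicates": n}
        for col, label in (("beta", "beta"), ("t", "t")):
            m = g[col].mean()
            half = 1.96 * g[col].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
            out[f"mean_{label}"] = m
            out[f"ci_{label}_low"] = m - half
            out[f"ci_{label}_high"] = m + half
        out["mean_rss"] = g["rss"].mean()
        return pd.Series(out)

    summary = (
        raw.groupby(["TR", "ISI", "tsnr_db", "model"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    summary["n_replicates"] = summary["n_replicates"].astype(int)
    return summary


def compare_models(summary: pd.DataFrame) -> pd.DataFrame:
    """HRF-minus-boxcar differences per (cell, tSNR).

    Columns: delta_beta, delta_t, and the HRF/boxcar rss ratio.
    """
    keys = ["TR", "ISI", "tsnr_db"]
    hrf = summary[summary["model"] == "hrf"].set_index(keys)
    box = summary[summary["model"] == "boxcar"].set_index(keys)
    if not hrf.index.equals(box.index):
        raise ValueError(
            "summary must contain both models for every (TR, ISI, tSNR) cell"
        )
    out = pd.DataFrame(index=hrf.index)
    out["delta_beta"] = hrf["mean_beta"] - box["mean_beta"]
    out["delta_t"] = hrf["mean_t"] - box["mean_t"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rss_ratio"] = hrf["mean_rss"] / box["mean_rss"]
    return out.reset_index()
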