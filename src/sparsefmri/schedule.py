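"""Sparse-sampling acquisition geometry and constrained event schedules.

A sparse acquisition alternates a short acquisition window (TA, scanner
gradients on) with a silent delay (TR − TA) during which auditory stimuli can
be presented cleanly.  An experiment run is a sequence of n_TR = run_length/TR
repetition periods; a fraction of them are "rest" (no stimulation, implicit
baseline), the remainder carry stimulation events on a fixed lattice: the
first event of a period starts ``post_TA_gap`` seconds after the acquisition
offset, and successive event onsets are separated by exactly the
inter-stimulus interval (ISI).

A (TR, ISI) pair is *compatible* when that lattice repeats identically in
every stimulation period, which requires ISI to divide TR (several events per
period) or TR to divide ISI (one event every ISI/TR periods).  TR = 12 s with
ISI = 8 s, for example, is rejected: stimulation would not occur consistently
with respect to acquisition in every TR.

When the silent delay is long enough, every event (onset to offset) lies
wholly within it.  For very short delays (silent delay < gap + duration, or a
multi-event train overrunning the period) the onset lattice is preserved and
the event tail is allowed to spill into the following acquisition; the
compatibility report exposes this through ``fully_contained``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IncompatibleDesignError, ScheduleFormatError

__all__ = [
    "AcquisitionDesign",
    "StimulationPlan",
    "Event",
    "EventSchedule",
    "CompatibilityReport",
    "check_compatibility",
    "events_per_TR",
    "generate_schedule",
    "read_events_tsv",
    "write_events_tsv",
]

_TOL = 1e-9


def _is_multiple(a: float, b: float) -> bool:
    """True if a is an integer multiple of b (within floating tolerance)."""
    r = a / b
    return abs(r - round(r)) < 1e-6


@dataclass(frozen=True)
class AcquisitionDesign:
    """Sparse sampling geometry.

    Parameters
    ----------
    TR:
        Volume-to-volume repetition time, seconds.
    TA:
        Acquisition (readout) time, seconds; the silent delay is TR − TA.
    run_length:
        Total run duration in seconds; must be an integer multiple of TR.
    dt:
        Resolution of the simulated timelines, seconds.
    post_TA_gap:
        Delay from the previous acquisition offset to the first event onset.
    rest_fraction:
        Proportion of repetition periods that are rest.
    """

    TR: float
    TA: float = 2.0
    run_length: float = 360.0
    dt: float = 0.1
    post_TA_gap: float = 0.5
    rest_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        if self.TA <= 0:
            raise ValueError(f"TA must be positive, got {self.TA}")
        if self.TR <= self.TA:
            raise ValueError(f"TR ({self.TR}) must exceed TA ({self.TA})")
        if not _is_multiple(self.run_length, self.TR):
            raise ValueError(
                f"run_length ({self.run_length}) must be an integer multiple "
                f"of TR ({self.TR})"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.post_TA_gap < 0:
            raise ValueError("post_TA_gap must be non-negative")
        if not 0 <= self.rest_fraction < 1:
            raise ValueError("rest_fraction must lie in [0, 1)")

    @property
    def silent_delay(self) -> float:
        return self.TR - self.TA

    @property
    def n_TR(self) -> int:
        return round(self.run_length / self.TR)


@dataclass(frozen=True)
class StimulationPlan:
    """Stimulation timing and event typing."""

    ISI: float
    event_duration: float = 1.0
    condition_labels: tuple = ("task",)

    def __post_init__(self):
        if self.event_duration <= 0:
            raise ValueError("event_duration must be positive")
        if self.ISI < self.event_duration:
            raise ValueError(
                f"ISI ({self.ISI}) must be at least the event duration "
                f"({self.event_duration})"
            )
        if len(self.condition_labels) < 1:
            raise ValueError("at least one condition label is required")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise ValueError("condition labels must be unique")
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    condition: str


@dataclass(frozen=True)
class CompatibilityReport:
    compatible: bool
    reason: str
    events_per_slot: int = 0
    trs_per_slot: int = 0
    fully_contained: bool = False

    def __bool__(self) -> bool:
        return self.compatible


@dataclass(frozen=True)
class EventSchedule:
    """Timed, typed stimulation events plus rest-TR bookkeeping."""

    events: tuple
    rest_TRs: frozenset
    n_TR: int
    design: AcquisitionDesign
    plan: StimulationPlan | None = None

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "rest_TRs", frozenset(self.rest_TRs))

    @property
    def n_events(self) -> int:
        return len(self.events)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array(
            [e.onset for e in self.events if condition is None or e.condition == condition]
        )

    def conditions(self) -> tuple:
        if self.plan is not None:
            return self.plan.condition_labels
        seen = []
        for e in self.events:
            if e.condition not in seen:
                seen.append(e.condition)
        return tuple(seen)

    def tr_index(self, onset: float) -> int:
        return int(math.floor(onset / self.design.TR + _TOL))

    def validate(self) -> list:
        """Self-check against the schedule invariants; returns violations.

        Full-duration containment in the silent delay is checked only when the
        geometry admits it (silent delay >= gap + duration); for shorter
        delays only the onset is required to fall inside the delay.
        """
        d = self.design
        problems = []
        if self.plan is not None:
            # containment expected only when the full event train fits
            containable = check_compatibility(d, self.plan).fully_contained
        else:
            containable = d.silent_delay >= d.post_TA_gap + (
                self.events[0].duration if self.events else 0.0
            )
        for e in self.events:
            k = self.tr_index(e.onset)
            start = k * d.TR + d.TA + d.post_TA_gap
            if e.onset < start - _TOL:
                problems.append(
                    f"event at {e.onset:g}s begins before the allowed onset "
                    f"{start:g}s of TR {k}"
                )
            if containable and e.onset + e.duration > (k + 1) * d.TR + _TOL:
                problems.append(
                    f"event at {e.onset:g}s extends past the end of TR {k}"
                )
            if k in self.rest_TRs:
                problems.append(f"event at {e.onset:g}s falls in rest TR {k}")
        if self.plan is not None:
            isi = self.plan.ISI
            stim_trs = {self.tr_index(e.onset) for e in self.events}
            onsets = sorted(e.onset for e in self.events)
            for a, b in zip(onsets, onsets[1:]):
                ka, kb = self.tr_index(a), self.tr_index(b)
                adjacent = all(
                    k in self.rest_TRs or k in stim_trs
                    for k in range(ka, kb + 1)
                )
                consecutive_stim = kb == ka or all(
                    k in stim_trs for k in range(ka, kb + 1)
                )
                if consecutive_stim and abs((b - a) - isi) > 1e-6 and adjacent:
                    problems.append(
                        f"onsets {a:g}s and {b:g}s in stimulation TRs are "
                        f"separated by {b - a:g}s, not ISI={isi:g}s"
                    )
        expected_rest = round(d.rest_fraction * self.n_TR)
        if len(self.rest_TRs) != expected_rest:
            problems.append(
                f"{len(self.rest_TRs)} rest TRs, expected {expected_rest}"
            )
        return problems


def check_compatibility(
    design: AcquisitionDesign, plan: StimulationPlan
) -> CompatibilityReport:
    """Decide whether an ISI-spaced event train tiles the TR grid consistently.

    Compatible iff the within-TR onset offsets repeat identically in every
    stimulation period: ISI divides TR (a train of TR/ISI events per period)
    or TR divides ISI (one event every ISI/TR periods), and the first onset
    (TA + post_TA_gap after the period start) falls inside the silent delay.
    """
    d, p = design, plan
    first_offset = d.TA + d.post_TA_gap
    if _is_multiple(d.TR, p.ISI):
        m = round(d.TR / p.ISI)
        trs_per_slot = 1
    elif _is_multiple(p.ISI, d.TR):
        m = 1
        trs_per_slot = round(p.ISI / d.TR)
        if not _is_multiple(d.run_length, p.ISI):
            return CompatibilityReport(
                False,
                f"run length {d.run_length}s is not a whole number of "
                f"ISI={p.ISI}s stimulation slots",
            )
    else:
        return CompatibilityReport(
            False,
            f"ISI={p.ISI}s does not tile TR={d.TR}s: stimulation would not "
            "occur consistently with respect to acquisition in every TR",
        )
    last_onset_offset = first_offset + (m - 1) * p.ISI
    if last_onset_offset >= d.TR - _TOL:
        return CompatibilityReport(
            False,
            f"no event onset fits in the {d.silent_delay:g}s silent delay "
            f"(first onset {first_offset:g}s after period start, "
            f"last {last_onset_offset:g}s, TR {d.TR:g}s)",
        )
    contained = (
        d.post_TA_gap + (m - 1) * p.ISI + p.event_duration
        <= d.silent_delay + _TOL
    )
    return CompatibilityReport(True, "compatible", m, trs_per_slot, contained)


def events_per_TR(design: AcquisitionDesign, plan: StimulationPlan) -> int:
    """Number of events hosted by each stimulation slot.

    For ISI <= TR this is TR/ISI events per stimulation TR; for ISI > TR it is
    one event per slot of ISI/TR consecutive TRs.
    """
    report = check_compatibility(design, plan)
    if not report:
        raise IncompatibleDesignError(report.reason)
    return report.events_per_slot


def generate_schedule(
    design: AcquisitionDesign,
    plan: StimulationPlan,
    seed: int,
    assignment: str = "balanced",
) -> EventSchedule:
    """Generate a randomized schedule satisfying the sparse constraints.

    Event timing is fully determined by the geometry (onsets at
    TA + post_TA_gap + j*ISI within each stimulation slot); randomness enters
    only through the placement of rest slots (uniform without replacement) and
    the assignment of condition labels to events.

    Parameters
    ----------
    assignment:
        "balanced" (default): conditions assigned in random order with counts
        differing by at most one; "alternating": conditions cycle in label
        order over successive events; "uniform": each event's condition drawn
        independently and uniformly.
    """
    report = check_compatibility(design, plan)
    if not report:
        raise IncompatibleDesignError(report.reason)
    if assignment not in ("balanced", "alternating", "uniform"):
        raise ValueError(f"unknown assignment mode {assignment!r}")

    rng = np.random.default_rng(seed)
    d, p = design, plan
    m, q = report.events_per_slot, report.trs_per_slot
    n_slots = d.n_TR // q
    n_rest_slots = round(d.rest_fraction * n_slots)
    rest_slots = set(
        rng.choice(n_slots, size=n_rest_slots, replace=False).tolist()
    )
    rest_trs = {s * q + j for s in rest_slots for j in range(q)}

    onset_list = []
    for s in range(n_slots):
        if s in rest_slots:
            continue
        slot_start = s * q * d.TR
        for j in range(m):
            onset_list.append(slot_start + d.TA + d.post_TA_gap + j * p.ISI)

    n_events = len(onset_list)
    labels = _assign_conditions(rng, p.condition_labels, n_events, assignment)
    events = tuple(
        Event(onset=on, duration=p.event_duration, condition=lab)
        for on, lab in zip(onset_list, labels)
    )
    return EventSchedule(
        events=events,
        rest_TRs=frozenset(rest_trs),
        n_TR=d.n_TR,
        design=d,
        plan=p,
    )


def _assign_conditions(rng, labels, n_events, mode):
    k = len(labels)
    if mode == "alternating":
        return [labels[i % k] for i in range(n_events)]
    if mode == "uniform":
        return [labels[i] for i in rng.integers(0, k, size=n_events)]
    # balanced: counts differ by <= 1, order random
    base, extra = divmod(n_events, k)
    counts = np.full(k, base)
    counts[rng.choice(k, size=extra, replace=False)] += 1
    pool = np.repeat(np.arange(k), counts)
    rng.shuffle(pool)
    return [labels[i] for i in pool]


def write_events_tsv(schedule: EventSchedule, path) -> None:
    """Write a BIDS-style events file (onset, duration, trial_type; tabs)."""
    df = pd.DataFrame(
        {
            "onset": [round(e.onset, 3) for e in schedule.events],
            "duration": [round(e.duration, 3) for e in schedule.events],
            "trial_type": [e.condition for e in schedule.events],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events_tsv(
    path, design: AcquisitionDesign | None = None
) -> EventSchedule:
    """Read a BIDS-style events file into an :class:`EventSchedule`.

    Onsets are kept to 1 ms precision.  If ``design`` is supplied, events are
    checked against the silent-delay constraint; violations are reported as
    warnings rather than errors, since real acquisitions may legitimately
    break the simulation's constraints.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise ScheduleFormatError(f"cannot parse events file {path}: {exc}")
    required = ("onset", "duration", "trial_type")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScheduleFormatError(
            f"events file {path} is missing column(s): {', '.join(missing)}"
        )
    events = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError):
            raise ScheduleFormatError(
                f"non-numeric onset/duration on line {line} of {path}"
            )
        if not (np.isfinite(onset) and np.isfinite(duration)):
            raise ScheduleFormatError(
                f"non-numeric onset/duration on line {line} of {path}"
            )
        if duration < 0:
            raise ScheduleFormatError(
                f"negative duration on line {line} of {path}"
            )
        events.append(
            Event(round(onset, 3), round(duration, 3), str(row["trial_type"]))
        )

    if design is None:
        run_end = max((e.onset + e.duration for e in events), default=0.0)
        tr = max(run_end, 1.0)
        design = AcquisitionDesign(
            TR=tr + 1.0, TA=min(2.0, tr), run_length=tr + 1.0, rest_fraction=0.0
        )
        n_tr = 1
    else:
        n_tr = design.n_TR
        for e in events:
            k = int(math.floor(e.onset / design.TR + _TOL))
            lo = k * design.TR + design.TA + design.post_TA_gap
            if e.onset < lo - _TOL or e.onset + e.duration > (k + 1) * design.TR + _TOL:
                warnings.warn(
                    f"event at {e.onset:g}s violates the silent-delay "
                    f"constraint of TR {k}",
                    stacklevel=2,
                )
    return EventSchedule(
        events=tuple(events),
        rest_TRs=frozenset(),
        n_TR=n_tr,
        design=design,
        plan=None,
    )
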