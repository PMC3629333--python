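"""Unit tests for sparse acquisition geometry and schedule generation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsefmri import (
    AcquisitionDesign,
    StimulationPlan,
    check_compatibility,
    events_per_TR,
    generate_schedule,
    read_events_tsv,
    write_events_tsv,
)
from sparsefmri.exceptions import IncompatibleDesignError, ScheduleFormatError

STUDY_CELLS = [(4, 4), (8, 4), (12, 4), (4, 8), (8, 8),
               (3, 3), (6, 3), (9, 3), (6, 6), (9, 9)]


class TestAcquisitionDesign:
    def test_derived_quantities(self):
        d = AcquisitionDesign(TR=12)
        assert d.silent_delay == 10.0
        assert d.n_TR == 30

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"TR": 2.0, "TA": 2.0},          # TR must exceed TA
            {"TR": 1.0, "TA": 2.0},
            {"TR": 7.0},                      # 360 not a multiple of 7
            {"TR": 8.0, "TA": -1.0},
            {"TR": 8.0, "dt": 0.0},
            {"TR": 8.0, "post_TA_gap": -0.5},
            {"TR": 8.0, "rest_fraction": 1.0},
            {"TR": 8.0, "rest_fraction": -0.1},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionDesign(**kwargs)


class TestStimulationPlan:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ISI": 0.5, "event_duration": 1.0},  # ISI < duration
            {"ISI": 4.0, "event_duration": 0.0},
            {"ISI": 4.0, "condition_labels": ()},
            {"ISI": 4.0, "condition_labels": ("a", "a")},
        ],
    )
    def test_invalid_plan_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StimulationPlan(**kwargs)


class TestCompatibility:
    def test_isi_divides_tr(self):
        r = check_compatibility(AcquisitionDesign(TR=12), StimulationPlan(ISI=4))
        assert r
        assert r.events_per_slot == 3
        assert r.trs_per_slot == 1
        assert r.fully_contained

    def test_tr_divides_isi(self):
        r = check_compatibility(AcquisitionDesign(TR=4), StimulationPlan(ISI=8))
        assert r
        assert r.events_per_slot == 1
        assert r.trs_per_slot == 2

    def test_tr12_isi8_rejected(self):
        r = check_compatibility(AcquisitionDesign(TR=12), StimulationPlan(ISI=8))
        assert not r
        assert "consistently" in r.reason

    def test_tail_spill_allowed_but_reported(self):
        # TR=3, TA=2: 1 s silent delay hosts an onset at 2.5 s but the 1 s
        # event tail runs 0.5 s into the next acquisition.
        r = check_compatibility(AcquisitionDesign(TR=3), StimulationPlan(ISI=3))
        assert r
        assert not r.fully_contained

    def test_first_onset_must_fit(self):
        d = AcquisitionDesign(TR=2.4, TA=2.0, run_length=360.0)
        r = check_compatibility(d, StimulationPlan(ISI=2.4, event_duration=1.0))
        assert not r
        assert "silent delay" in r.reason

    @pytest.mark.parametrize("tr,isi", STUDY_CELLS)
    def test_all_study_cells_compatible(self, tr, isi):
        assert check_compatibility(
            AcquisitionDesign(TR=tr), StimulationPlan(ISI=isi)
        )

    def test_events_per_TR(self):
        assert events_per_TR(AcquisitionDesign(TR=12), StimulationPlan(ISI=4)) == 3
        assert events_per_TR(AcquisitionDesign(TR=8), StimulationPlan(ISI=8)) == 1
        with pytest.raises(IncompatibleDesignError):
            events_per_TR(AcquisitionDesign(TR=12), StimulationPlan(ISI=8))


class TestGenerateSchedule:
    def test_event_count_tr12_isi4(self):
        s = generate_schedule(AcquisitionDesign(TR=12), StimulationPlan(ISI=4), 0)
        assert s.n_events == 60

    def test_event_count_tr8_isi8(self):
        s = generate_schedule(AcquisitionDesign(TR=8), StimulationPlan(ISI=8), 0)
        assert s.n_events == 30

    def test_incompatible_cell_raises(self):
        with pytest.raises(IncompatibleDesignError):
            generate_schedule(AcquisitionDesign(TR=12), StimulationPlan(ISI=8), 0)

    def test_rest_TR_count(self):
        s = generate_schedule(AcquisitionDesign(TR=12), StimulationPlan(ISI=4), 3)
        assert len(s.rest_TRs) == 10  # round(30/3)

    def test_rest_slots_cover_consecutive_TRs_when_isi_exceeds_tr(self):
        s = generate_schedule(AcquisitionDesign(TR=4), StimulationPlan(ISI=8), 3)
        # slots are pairs of TRs; every rest slot contributes both of its TRs
        rest = sorted(s.rest_TRs)
        assert len(rest) == 30  # round(1/3 * 45 slots) * 2 TRs
        for k in rest:
            slot = k // 2
            assert slot * 2 in s.rest_TRs and slot * 2 + 1 in s.rest_TRs

    def test_deterministic_per_seed(self):
        d, p = AcquisitionDesign(TR=8), StimulationPlan(ISI=4)
        a = generate_schedule(d, p, 42)
        b = generate_schedule(d, p, 42)
        assert a.events == b.events
        assert a.rest_TRs == b.rest_TRs

    def test_seed_changes_rest_placement(self):
        d, p = AcquisitionDesign(TR=8), StimulationPlan(ISI=4)
        placements = {
            frozenset(generate_schedule(d, p, s).rest_TRs) for s in range(8)
        }
        assert len(placements) > 1

    def test_onsets_on_lattice(self):
        d = AcquisitionDesign(TR=12)
        s = generate_schedule(d, StimulationPlan(ISI=4), 5)
        for e in s.events:
            k = s.tr_index(e.onset)
            offset = e.onset - k * d.TR
            assert min(abs(offset - v) for v in (2.5, 6.5, 10.5)) < 1e-9

    @pytest.mark.parametrize("tr,isi", STUDY_CELLS)
    def test_validate_clean_for_study_cells(self, tr, isi):
        s = generate_schedule(
            AcquisitionDesign(TR=tr), StimulationPlan(ISI=isi), 11
        )
        assert s.validate() == []

    def test_balanced_assignment_counts(self):
        p = StimulationPlan(ISI=4, condition_labels=("go", "nogo"))
        s = generate_schedule(AcquisitionDesign(TR=12), p, 1)
        counts = [sum(e.condition == c for e in s.events) for c in ("go", "nogo")]
        assert abs(counts[0] - counts[1]) <= 1
        assert sum(counts) == 60

    def test_alternating_assignment(self):
        p = StimulationPlan(ISI=4, condition_labels=("go", "nogo"))
        s = generate_schedule(AcquisitionDesign(TR=12), p, 1,
                              assignment="alternating")
        labels = [e.condition for e in s.events]
        assert labels == ["go", "nogo"] * 30

    def test_uniform_assignment_uses_all_labels(self):
        p = StimulationPlan(ISI=4, condition_labels=("a", "b", "c"))
        s = generate_schedule(AcquisitionDesign(TR=12), p, 1,
                              assignment="uniform")
        assert {e.condition for e in s.events} == {"a", "b", "c"}

    def test_unknown_assignment_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(AcquisitionDesign(TR=12), StimulationPlan(ISI=4),
                              0, assignment="sorted")

    @given(
        st.sampled_from(STUDY_CELLS),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_schedule_invariants_property(self, cell, seed):
        tr, isi = cell
        d = AcquisitionDesign(TR=tr)
        s = generate_schedule(d, StimulationPlan(ISI=isi), seed)
        assert s.validate() == []
        # event-count arithmetic: (1 - rest) fraction of run, one per ISI
        expected = round(d.n_TR * (1 - d.rest_fraction)) * tr // isi \
            if isi <= tr else round((d.n_TR * tr / isi) * (1 - d.rest_fraction))
        assert s.n_events == expected


class TestEventsTsv:
    def test_roundtrip(self, tmp_path):
        d = AcquisitionDesign(TR=12)
        s = generate_schedule(d, StimulationPlan(ISI=4), 9)
        path = tmp_path / "events.tsv"
        write_events_tsv(s, path)
        back = read_events_tsv(path, design=d)
        assert back.n_events == s.n_events
        np.testing.assert_allclose(back.onsets(), s.onsets(), atol=1e-3)
        assert [e.condition for e in back.events] == \
            [e.condition for e in s.events]

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("onset\tduration\n0.5\t1.0\n")
        with pytest.raises(ScheduleFormatError, match="trial_type"):
            read_events_tsv(path)

    def test_non_numeric_onset_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "onset\tduration\ttrial_type\n2.5\t1.0\ttask\nsoon\t1.0\ttask\n"
        )
        with pytest.raises(ScheduleFormatError, match="line 3"):
            read_events_tsv(path)

    def test_negative_duration_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("onset\tduration\ttrial_type\n2.5\t-1.0\ttask\n")
        with pytest.raises(ScheduleFormatError, match="negative duration"):
            read_events_tsv(path)

    def test_constraint_violation_warns_not_errors(self, tmp_path):
        path = tmp_path / "events.tsv"
        # onset 1.0 s falls inside the acquisition window of TR 0
        path.write_text("onset\tduration\ttrial_type\n1.0\t1.0\ttask\n")
        with pytest.warns(UserWarning, match="silent-delay"):
            s = read_events_tsv(path, design=AcquisitionDesign(TR=12))
        assert s.n_events == 1

    def test_read_without_design(self, tmp_path):
        path = tmp_path / "events.tsv"
        path.write_text("onset\tduration\ttrial_type\n2.5\t1.0\tgo\n")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            s = read_events_tsv(path)
        assert s.events[0].condition == "go"
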