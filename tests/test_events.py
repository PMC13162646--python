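"""Independence filtering, RAI, species inclusion, detection histories."""

import numpy as np
import pandas as pd
import pytest

from trapcomm.events import (
    EventTable,
    apply_species_filter,
    build_detection_history,
    compute_rai,
    effective_days,
    filter_independent_events,
    presence_absence,
    read_deployments,
)

from conftest import make_deployments, make_records


class TestIndependenceFilter:
    @pytest.mark.parametrize(
        "minutes, expected",
        [
            ([0, 10, 40], 1),  # gaps 10 and 30: both merge (boundary inclusive)
            ([0, 31, 62], 3),  # both gaps exceed the window
            ([0, 30], 1),  # exactly 30 min still merges
            ([0, 30.5], 2),
            ([0], 1),
        ],
    )
    def test_gap_to_previous_rule(self, minutes, expected):
        rec = make_records([("c1", "sp", m) for m in minutes])
        ev = filter_independent_events(rec, make_deployments(["c1"]))
        assert ev.n_events == expected

    def test_species_are_independent_streams(self):
        rec = make_records([("c1", "A", 0), ("c1", "B", 5)])
        ev = filter_independent_events(rec, make_deployments(["c1"]))
        assert ev.n_events == 2

    def test_cameras_are_independent_streams(self):
        rec = make_records([("c1", "A", 0), ("c2", "A", 5)])
        ev = filter_independent_events(rec, make_deployments(["c1", "c2"]))
        assert ev.n_events == 2

    def test_record_outside_deployment_warned_and_dropped(self):
        rec = make_records([("c1", "A", 0), ("c1", "A", 60 * 24 * 400)])
        dep = make_deployments(["c1"], days=30)
        with pytest.warns(UserWarning, match="outside"):
            ev = filter_independent_events(rec, dep, outside_deployment="drop")
        assert ev.n_events == 1
        with pytest.warns(UserWarning, match="outside"):
            ev = filter_independent_events(rec, dep, outside_deployment="keep")
        assert ev.n_events == 2

    def test_event_count_bounds(self, small_survey):
        _, _, records, deployments = small_survey
        ev = filter_independent_events(records, deployments)
        n_pairs = records.groupby(["camera_id", "species"]).ngroups
        assert len(records) >= ev.n_events >= n_pairs

    def test_duplicate_record_in_merge_chain_leaves_rai_unchanged(self):
        rec = make_records([("c1", "A", 0), ("c1", "A", 20), ("c1", "A", 60)])
        dep = make_deployments(["c1"], days=10)
        base = compute_rai(filter_independent_events(rec, dep))
        dup = pd.concat([rec, make_records([("c1", "A", 10)])], ignore_index=True)
        again = compute_rai(filter_independent_events(dup, dep))
        pd.testing.assert_frame_equal(base.rai, again.rai)


class TestRAI:
    def _events(self, n_events, eff_days):
        ev = make_records([("c1", "A", 60 * i) for i in range(n_events)])
        return EventTable(
            events=ev, effective_days=pd.Series({"c1": eff_days})
        )

    @pytest.mark.parametrize(
        "n_events, days, expected",
        [(5, 250, 2.0), (0, 250, 0.0), (37, 340, 10.8824)],
    )
    def test_rai_arithmetic(self, n_events, days, expected):
        rai = compute_rai(self._events(n_events, days))
        got = rai.rai.loc["c1", "A"] if n_events else 0.0
        assert got == pytest.approx(expected, abs=5e-5)

    def test_zero_effort_camera_excluded(self):
        tab = EventTable(
            events=make_records([("c1", "A", 0)]),
            effective_days=pd.Series({"c1": 100, "c2": 0}),
        )
        with pytest.warns(UserWarning, match="zero-effort"):
            rai = compute_rai(tab)
        assert list(rai.rai.index) == ["c1"]

    def test_zero_entry_iff_zero_events(self, small_survey):
        _, _, records, deployments = small_survey
        ev = filter_independent_events(records, deployments)
        rai = compute_rai(ev)
        counts = ev.counts()
        assert ((rai.rai.to_numpy() == 0) == (counts.to_numpy() == 0)).all()


class TestSpeciesFilter:
    def _table(self, specs):
        """specs: {species: (n_events, n_sites)} with events spread over sites."""
        rows = []
        for sp, (n_ev, n_si) in specs.items():
            for i in range(n_ev):
                rows.append((f"c{i % n_si}", sp, 60 * (i // n_si) + i % n_si))
        cams = sorted({r[0] for r in rows})
        return EventTable(
            events=make_records(rows),
            effective_days=pd.Series({c: 100 for c in cams}),
        )

    def test_strict_fewer_than_boundaries(self):
        tab = self._table({"under_ev": (29, 15), "under_si": (35, 9), "edge": (30, 10)})
        kept = apply_species_filter(tab, min_events=30, min_sites=10)
        assert kept == ["edge"]


class TestDetectionHistory:
    def test_workday_interval_arithmetic(self):
        t0 = pd.Timestamp("2020-01-01")
        dep = pd.DataFrame(
            [{"camera_id": "c1", "start": t0,
              "end": t0 + pd.Timedelta(days=19, hours=12), "camera_type": "A"}]
        )
        ev = EventTable(events=make_records([]), effective_days=effective_days(dep))
        hist = build_detection_history(
            ev, dep, survey_start=t0, survey_end=t0 + pd.Timedelta(days=41)
        )
        assert list(hist.workday.loc["c1"]) == [14, 6, 0]

    def test_event_on_day_16_lands_in_occasion_2(self):
        rec = make_records([("c1", "A", 15 * 24 * 60)])  # day 16 of the survey
        dep = make_deployments(["c1"], days=28)
        ev = filter_independent_events(rec, dep)
        hist = build_detection_history(ev, dep, survey_start="2020-01-01")
        h = hist.histories["A"].loc["c1"]
        assert h[2] == 1.0 and h[1] == 0.0

    def test_zero_effort_occasions_are_missing(self):
        t0 = pd.Timestamp("2020-01-01")
        dep = pd.DataFrame(
            [
                {"camera_id": "c1", "start": t0, "end": t0 + pd.Timedelta(days=27),
                 "camera_type": "A"},
                {"camera_id": "c2", "start": t0 + pd.Timedelta(days=28),
                 "end": t0 + pd.Timedelta(days=41), "camera_type": "A"},
            ]
        )
        ev = filter_independent_events(make_records([("c1", "A", 0)]), dep)
        hist = build_detection_history(ev, dep, survey_start=t0)
        assert np.isnan(hist.histories["A"].loc["c2", 1])
        assert np.isnan(hist.histories["A"].loc["c1", 3])
        assert hist.histories["A"].loc["c1", 1] == 1.0

    def test_event_in_zero_effort_occasion_rejected(self):
        t0 = pd.Timestamp("2020-01-01")
        dep = make_deployments(["c1"], days=14)
        rec = make_records([("c1", "A", 20 * 24 * 60)])  # day 21, camera dead
        ev = filter_independent_events(rec, dep, outside_deployment="keep")
        with pytest.raises(ValueError, match="zero recorded effort"):
            build_detection_history(
                ev, dep, survey_start=t0, survey_end=t0 + pd.Timedelta(days=27)
            )

    def test_workday_sums_to_effective_days(self, small_survey):
        _, _, records, deployments = small_survey
        ev = filter_independent_events(records, deployments)
        hist = build_detection_history(ev, deployments)
        pd.testing.assert_series_equal(
            hist.workday.sum(axis=1).astype(int),
            ev.effective_days.astype(int),
            check_names=False,
        )

    def test_overlapping_deployments_rejected(self):
        t0 = pd.Timestamp("2020-01-01")
        dep = pd.DataFrame(
            [
                {"camera_id": "c1", "start": t0, "end": t0 + pd.Timedelta(days=10),
                 "camera_type": "A"},
                {"camera_id": "c1", "start": t0 + pd.Timedelta(days=5),
                 "end": t0 + pd.Timedelta(days=15), "camera_type": "A"},
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            filter_independent_events(make_records([("c1", "A", 0)]), dep)


def test_presence_absence_is_binary(small_survey):
    _, _, records, deployments = small_survey
    rai = compute_rai(filter_independent_events(records, deployments))
    pa = presence_absence(rai)
    assert set(np.unique(pa.to_numpy())) <= {0, 1}
    assert ((pa == 1) == (rai.rai > 0)).all().all()
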