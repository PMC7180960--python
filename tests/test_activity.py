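import datetime as dt
import io

import pytest

from habitspectrum import (
    ActivityEvent,
    ActivityRegistry,
    DEFAULT_PHASE_WINDOWS,
    PhaseWindows,
    extract_sequences,
    load_registry,
    read_activity_log,
    write_activity_log,
)
from habitspectrum.activity import LogFormatError, RegistryFormatError


class TestRegistry:
    def test_mapping_source_keeps_given_ids(self):
        reg = load_registry({"watching_tv": 1, "sleeping": 2})
        assert len(reg) == 2
        assert reg.id_of("sleeping") == 2
        assert reg.name_of(1) == "watching_tv"

    def test_names_only_get_sequential_ids(self):
        reg = load_registry(["a", "b", "c"])
        assert reg.ids == [1, 2, 3]

    @pytest.mark.parametrize(
        "entries",
        [
            {"a": 1, "b": 1},  # duplicate ID via mapping is caught at build
            (("a", 1), ("a", 2)),  # duplicate name
            (("a", 0),),  # non-positive ID
            (("", 1),),  # empty name
        ],
    )
    def test_invalid_entries_rejected(self, entries):
        with pytest.raises(RegistryFormatError):
            if isinstance(entries, dict):
                ActivityRegistry(tuple((n, i) for n, i in entries.items()))
            else:
                ActivityRegistry(tuple(entries))

    def test_csv_round_trip(self, tmp_path, tv_sleep_registry):
        path = tmp_path / "registry.csv"
        tv_sleep_registry.to_csv(path)
        assert load_registry(path) == tv_sleep_registry

    def test_lookup_round_trips_bidirectionally(self, tv_sleep_registry):
        for name in tv_sleep_registry.names:
            assert tv_sleep_registry.name_of(tv_sleep_registry.id_of(name)) == name


class TestLogIO:
    REGISTRY = ActivityRegistry((("eating_breakfast", 3), ("watching_tv", 1)))

    def _log(self, body: str) -> io.StringIO:
        return io.StringIO("subject,date,clock_time,window,activity,duration_min\n" + body)

    def test_reads_events_in_file_order(self):
        events = read_activity_log(
            self._log("u1,2020-01-06,,,eating_breakfast,30\nu1,2020-01-06,,,watching_tv,60\n"),
            self.REGISTRY,
        )
        assert [e.duration for e in events] == [30.0, 60.0]
        assert [e.activity_id for e in events] == [3, 1]
        assert [e.order_index for e in events] == [0, 1]

    def test_activity_column_accepts_integer_ids(self):
        events = read_activity_log(self._log("u1,2020-01-06,,,3,15\n"), self.REGISTRY)
        assert events[0].activity_id == 3

    def test_empty_body_gives_empty_list(self):
        assert read_activity_log(self._log(""), self.REGISTRY) == []

    def test_non_positive_duration_reports_row(self):
        with pytest.raises(LogFormatError, match="row 3"):
            read_activity_log(
                self._log("u1,2020-01-06,,,watching_tv,60\nu1,2020-01-06,,,watching_tv,-5\n"),
                self.REGISTRY,
            )

    def test_unknown_activity_lists_names(self):
        with pytest.raises(LogFormatError, match="juggling"):
            read_activity_log(self._log("u1,2020-01-06,,,juggling,5\n"), self.REGISTRY)

    def test_write_read_round_trip(self, tmp_path, breakfast_events):
        path = tmp_path / "log.csv"
        write_activity_log(breakfast_events, path, self.REGISTRY)
        assert read_activity_log(path, self.REGISTRY) == breakfast_events

    def test_round_trip_preserves_clock_time_and_window(self, tmp_path):
        events = [
            ActivityEvent(
                subject="u2", date=dt.date(2021, 5, 1), order_index=0, activity_id=1,
                duration=12.5, clock_time=dt.time(8, 30), window="session",
            )
        ]
        path = tmp_path / "log.csv"
        write_activity_log(events, path, self.REGISTRY)
        assert read_activity_log(path, self.REGISTRY) == events


class TestPhaseWindows:
    def test_default_windows_cover_the_day(self):
        assert DEFAULT_PHASE_WINDOWS.labels == ["morning", "afternoon", "night"]

    @pytest.mark.parametrize(
        "time,expected",
        [
            (dt.time(5, 0), "morning"),  # boundary belongs to starting window
            (dt.time(11, 59), "morning"),
            (dt.time(12, 0), "afternoon"),
            (dt.time(18, 0), "night"),
            (dt.time(2, 0), "night"),  # night wraps midnight
            (dt.time(4, 59), "night"),
        ],
    )
    def test_half_open_membership(self, time, expected):
        assert DEFAULT_PHASE_WINDOWS.label_for(time) == expected

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(ValueError):
            PhaseWindows.from_spec([("day", "06:00", "18:00")])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            PhaseWindows.from_spec([("a", "00:00", "12:00"), ("a", "12:00", "00:00")])


class TestExtractSequences:
    def test_session_mode_orders_by_index(self, breakfast_events):
        (seq,) = extract_sequences(breakfast_events, session_mode=True)
        assert seq.ids == (3, 1)
        assert seq.durations == (30.0, 60.0)

    def test_empty_events_give_empty_list(self):
        assert extract_sequences([], session_mode=True) == []

    def test_phase_mode_splits_by_clock_time(self):
        d = dt.date(2020, 1, 6)
        events = [
            ActivityEvent("u1", d, 0, 1, 30.0, clock_time=dt.time(8, 0)),
            ActivityEvent("u1", d, 1, 2, 60.0, clock_time=dt.time(20, 0)),
        ]
        seqs = extract_sequences(events, windows=DEFAULT_PHASE_WINDOWS)
        assert {s.window_label for s in seqs} == {"morning", "night"}

    def test_phase_mode_requires_clock_time(self, breakfast_events):
        with pytest.raises(ValueError, match="clock_time"):
            extract_sequences(breakfast_events, windows=DEFAULT_PHASE_WINDOWS)

    def test_partitions_events_conserving_count(self, rng):
        d0 = dt.date(2020, 1, 6)
        events = []
        for s in range(4):
            for day in range(3):
                for i in range(int(rng.integers(1, 6))):
                    events.append(
                        ActivityEvent(
                            subject=f"s{s}", date=d0 + dt.timedelta(days=day),
                            order_index=i, activity_id=int(rng.integers(1, 7)),
                            duration=float(rng.integers(1, 30)),
                            clock_time=dt.time(int(rng.integers(0, 24)), 0),
                        )
                    )
        seqs = extract_sequences(events, windows=DEFAULT_PHASE_WINDOWS)
        assert sum(len(s) for s in seqs) == len(events)
        # every (subject, date, phase) key is unique -> partition, not overlap
        keys = [s.key for s in seqs]
        assert len(keys) == len(set(keys))
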