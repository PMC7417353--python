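"""Event-log ingestion, bout merging, wave construction and serialization."""

import io
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

import groomnet as gn
from groomnet.data import (
    ActorTable,
    EventLog,
    ValidationError,
    WaveNetwork,
    WavePanel,
    binarize,
    build_panel,
    build_weighted_wave,
    merge_split_bouts,
    normalized_weighted_degrees,
    read_event_log,
)
from groomnet.schedule import ObservationSchedule

SCHED = ObservationSchedule()
T0 = SCHED.total_period_starts(1)[0]


def csv(text):
    return io.StringIO(text)


class TestReadEventLog:
    def test_well_formed(self):
        log = read_event_log(csv(
            "actor,recipient,behavior,timestamp,session\n"
            f"a,b,groom,{T0},s1\n"
            f"b,a,groom,{T0},s1\n"
            f"a,c,headbutt,{T0},s1\n"
        ))
        assert len(log) == 3

    def test_self_interaction_names_line(self):
        with pytest.raises(ValidationError) as exc:
            read_event_log(csv(
                "actor,recipient,behavior,timestamp,session\n"
                f"a,b,groom,{T0},s1\n"
                f"b,b,groom,{T0},s1\n"
            ))
        assert 2 in exc.value.rows

    def test_unknown_behavior_rejected(self):
        with pytest.raises(ValidationError):
            read_event_log(csv(
                "actor,recipient,behavior,timestamp,session\n"
                f"a,b,licking,{T0},s1\n"
            ))

    def test_bad_timestamp_rejected(self):
        with pytest.raises(ValidationError):
            read_event_log(csv(
                "actor,recipient,behavior,timestamp,session\n"
                "a,b,groom,not-a-time,s1\n"
            ))

    def test_empty_file_with_header(self):
        log = read_event_log(csv("actor,recipient,behavior,timestamp,session\n"))
        assert len(log) == 0


class TestBoutRule:
    def raw(self, rows):
        return pd.DataFrame(
            rows, columns=["actor", "recipient", "behavior", "start", "stop",
                           "session"]
        )

    def test_episodes_within_gap_merge(self):
        t = pd.Timestamp(T0)
        raw = self.raw([
            ("a", "b", "groom", t, t + pd.Timedelta(seconds=30), "s"),
            ("a", "b", "groom", t + pd.Timedelta(seconds=45),
             t + pd.Timedelta(seconds=60), "s"),  # 15 s pause
        ])
        assert len(merge_split_bouts(raw).groom_events()) == 1

    def test_episodes_beyond_gap_split(self):
        t = pd.Timestamp(T0)
        raw = self.raw([
            ("a", "b", "groom", t, t + pd.Timedelta(seconds=30), "s"),
            ("a", "b", "groom", t + pd.Timedelta(seconds=55),
             t + pd.Timedelta(seconds=70), "s"),  # 25 s pause
        ])
        assert len(merge_split_bouts(raw).groom_events()) == 2

    def test_interruption_by_other_behavior_splits(self):
        t = pd.Timestamp(T0)
        raw = self.raw([
            ("a", "b", "groom", t, t + pd.Timedelta(seconds=30), "s"),
            ("a", "c", "headbutt", t + pd.Timedelta(seconds=32),
             t + pd.Timedelta(seconds=34), "s"),
            ("a", "b", "groom", t + pd.Timedelta(seconds=40),
             t + pd.Timedelta(seconds=55), "s"),  # resumes within 10 s
        ])
        assert len(merge_split_bouts(raw).groom_events()) == 2

    def test_overlapping_episodes_rejected(self):
        t = pd.Timestamp(T0)
        raw = self.raw([
            ("a", "b", "groom", t, t + pd.Timedelta(seconds=30), "s"),
            ("a", "c", "groom", t + pd.Timedelta(seconds=10),
             t + pd.Timedelta(seconds=40), "s"),
        ])
        with pytest.raises(ValidationError):
            merge_split_bouts(raw)


def tiny_actors(n=3, n_waves=2):
    return ActorTable(
        pd.DataFrame({
            "actor_id": [f"c{i}" for i in range(n)],
            "age": np.linspace(3, 6, n),
            "entry_week": [1] * n,
        }),
        n_waves,
    )


class TestWaveConstruction:
    def test_weighted_counts(self):
        actors = tiny_actors()
        rows = (
            [("c0", "c1", "groom", T0, "s")] * 3
            + [("c1", "c0", "groom", T0, "s")]
        )
        log = EventLog(pd.DataFrame(
            rows, columns=["actor", "recipient", "behavior", "timestamp",
                           "session"]))
        w = build_weighted_wave(log, 1, actors.ids, actors.present(1), SCHED)
        assert w[0, 1] == 3 and w[1, 0] == 1 and w.sum() == 4

    def test_inactive_actor_event_is_error(self):
        actors = ActorTable(
            pd.DataFrame({"actor_id": ["c0", "c1"], "age": [3, 4],
                          "entry_week": [1, 2]}), 2)
        log = EventLog(pd.DataFrame(
            [("c0", "c1", "groom", T0, "s")],
            columns=["actor", "recipient", "behavior", "timestamp", "session"]))
        with pytest.raises(ValidationError):
            build_weighted_wave(log, 1, actors.ids, actors.present(1), SCHED)

    def test_binarize_thresholds(self):
        w = np.array([[0, 3], [1, 0]])
        b = binarize(w)
        assert b[0, 1] == 1 and b[1, 0] == 1 and b[0, 0] == 0
        assert np.array_equal(binarize(b), b)  # idempotent
        with pytest.raises(ValidationError):
            binarize(np.array([[0, -1], [0, 0]]))

    def test_normalized_degrees(self):
        w = np.array([[0, 1], [0, 0]])
        nd = normalized_weighted_degrees(w, np.array([True, True]))
        assert nd.loc[0, "out"] == 1.0 and nd.loc[0, "in"] == 0.0
        # all dyads at max weight -> everyone at 1.0
        full = np.full((4, 4), 5); np.fill_diagonal(full, 0)
        nd = normalized_weighted_degrees(full, np.ones(4, bool))
        assert np.allclose(nd["out"], 1.0) and np.allclose(nd["in"], 1.0)
        # empty -> zeros
        nd = normalized_weighted_degrees(np.zeros((3, 3)), np.ones(3, bool))
        assert np.allclose(nd[["out", "in"]], 0.0)
        with pytest.raises(ValidationError):
            normalized_weighted_degrees(w, np.array([True, False]))


class TestWaveNetworkInvariants:
    def test_no_self_ties(self):
        with pytest.raises(ValidationError):
            WaveNetwork(1, ["a", "b"], np.ones(2, bool), np.eye(2, dtype=int))

    def test_no_inactive_ties(self):
        adj = np.array([[0, 1], [0, 0]], dtype=np.int8)
        with pytest.raises(ValidationError):
            WaveNetwork(1, ["a", "b"], np.array([True, False]), adj)


class TestPanel:
    def test_paper_shaped_node_counts(self, paper_study):
        counts = [w.n_active for w in paper_study.panel.waves]
        assert counts == [25, 32, 33, 38, 38, 38]

    def test_single_actor_single_week(self):
        actors = tiny_actors(1, 1)
        log = EventLog(pd.DataFrame(
            columns=["actor", "recipient", "behavior", "timestamp", "session"]))
        panel = build_panel(log, actors, 1, SCHED)
        assert panel.n_waves == 1 and panel.waves[0].n_ties == 0

    def test_roundtrip_from_generated_log(self, paper_study):
        """binarize . build_weighted_wave reproduces the generator's panel."""
        rebuilt = build_panel(
            paper_study.grooming_log, paper_study.actors,
            paper_study.config.n_waves,
            ObservationSchedule(n_weeks=paper_study.config.n_waves),
        )
        for a, b in zip(rebuilt.waves, paper_study.panel.waves):
            assert np.array_equal(a.adj, b.adj)
            assert np.array_equal(a.active, b.active)

    def test_serialization_lossless(self, paper_study, tmp_path):
        panel = paper_study.panel
        panel.write(tmp_path / "panel")
        back = WavePanel.read(tmp_path / "panel")
        assert back.n_waves == panel.n_waves
        for a, b in zip(back.waves, panel.waves):
            assert np.array_equal(a.adj, b.adj)
            assert np.array_equal(a.active, b.active)
        for a, b in zip(back.weighted, panel.weighted):
            assert np.array_equal(a, b)


class TestSchedule:
    def test_week_assignment(self):
        assert SCHED.week_of(T0) == 1
        t_w2 = SCHED.total_period_starts(2)[0]
        assert SCHED.week_of(t_w2) == 2

    def test_periods_per_week(self):
        # 5 days x 2 blocks x 4 periods
        assert len(list(SCHED.periods(1))) == 40

    def test_contains(self):
        assert SCHED.contains(T0)
        outside = datetime.combine(SCHED.study_start, datetime.min.time())
        assert not SCHED.contains(outside)
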