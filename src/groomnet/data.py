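"""Event logs, actor attributes and weekly wave networks.

This module turns timestamped dyadic behavioural records (grooming and
headbutting events between cows) into the panel of weekly directed networks
that the dynamic model consumes: weighted count matrices, their binary
counterparts (tie = at least one grooming event that week) and the
composition table recording when each animal joined or left the group.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schedule import ObservationSchedule

BEHAVIORS = ("groom", "headbutt")

EVENT_COLUMNS = ["actor", "recipient", "behavior", "timestamp", "session"]


class ValidationError(ValueError):
    """Raised when an input table violates the schema; lists offending rows."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

@dataclass
class EventLog:
    """Validated table of dyadic behavioural events.

    ``df`` has columns ``actor, recipient, behavior, timestamp, session``
    with ``behavior`` in {"groom", "headbutt"} and no self-interactions.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def groom_events(self) -> pd.DataFrame:
        return self.df[self.df["behavior"] == "groom"]

    def headbutt_events(self) -> pd.DataFrame:
        return self.df[self.df["behavior"] == "headbutt"]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table, raising with 1-based row numbers on failure."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df[EVENT_COLUMNS].copy()

    bad_self = df.index[df["actor"] == df["recipient"]]
    if len(bad_self):
        raise ValidationError(
            "self-interaction (actor == recipient)", (bad_self + 1).tolist()
        )
    bad_beh = df.index[~df["behavior"].isin(BEHAVIORS)]
    if len(bad_beh):
        raise ValidationError(
            f"unknown behavior (must be one of {BEHAVIORS})", (bad_beh + 1).tolist()
        )
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad_ts = df.index[ts.isna()]
    if len(bad_ts):
        raise ValidationError("unparseable timestamp", (bad_ts + 1).tolist())
    df["timestamp"] = ts
    return df


def read_event_log(source: str | Path | io.IOBase) -> EventLog:
    """Read and validate a delimited event log.

    The file must have a header row with columns
    ``actor,recipient,behavior,timestamp,session``.
    """
    df = pd.read_csv(source, dtype={"actor": str, "recipient": str, "session": str})
    return EventLog(validate_events(df))


def merge_split_bouts(raw: pd.DataFrame, gap_seconds: float = 20.0) -> EventLog:
    """Apply the bout rule to raw licking episodes.

    A grooming bout that pauses for at most ``gap_seconds`` and is not
    interrupted by another behaviour of the same actor counts as a single
    grooming event; longer pauses or interruptions split it into two events.

    Parameters
    ----------
    raw : DataFrame
        Columns ``actor, recipient, behavior, start, stop, session``; one row
        per continuous episode, with ``start``/``stop`` datetimes.
    """
    for col in ("actor", "recipient", "behavior", "start", "stop", "session"):
        if col not in raw.columns:
            raise ValidationError(f"missing column: {col}")
    raw = raw.copy()
    raw["start"] = pd.to_datetime(raw["start"])
    raw["stop"] = pd.to_datetime(raw["stop"])
    if (raw["stop"] < raw["start"]).any():
        bad = raw.index[raw["stop"] < raw["start"]]
        raise ValidationError("episode stops before it starts", (bad + 1).tolist())

    # one actor cannot perform two behaviours at once
    for actor, grp in raw.groupby("actor"):
        g = grp.sort_values("start")
        overlap = g["start"].values[1:] < g["stop"].values[:-1]
        if overlap.any():
            rows = g.index[1:][overlap]
            raise ValidationError(
                f"overlapping episodes for actor {actor!r}", (rows + 1).tolist()
            )

    events = []
    order = raw.sort_values("start").reset_index(drop=True)
    open_bouts: dict = {}  # actor -> (recipient, stop_time, row)
    for _, row in order.iterrows():
        actor = row["actor"]
        prev = open_bouts.get(actor)
        if row["behavior"] == "groom":
            if (
                prev is not None
                and prev[0] == row["recipient"]
                and (row["start"] - prev[1]).total_seconds() <= gap_seconds
            ):
                # continuation of the open bout: extend, emit nothing new
                open_bouts[actor] = (prev[0], row["stop"], prev[2])
                continue
            rec = {
                "actor": actor,
                "recipient": row["recipient"],
                "behavior": "groom",
                "timestamp": row["start"],
                "session": row["session"],
            }
            events.append(rec)
            open_bouts[actor] = (row["recipient"], row["stop"], rec)
        else:
            # any other behaviour by this actor interrupts her open bout
            open_bouts.pop(actor, None)
            events.append(
                {
                    "actor": actor,
                    "recipient": row["recipient"],
                    "behavior": row["behavior"],
                    "timestamp": row["start"],
                    "session": row["session"],
                }
            )
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return EventLog(validate_events(df)) if len(df) else EventLog(
        pd.DataFrame(columns=EVENT_COLUMNS)
    )


# ---------------------------------------------------------------------------
# Actor attributes
# ---------------------------------------------------------------------------

@dataclass
class ActorTable:
    """Per-cow attributes: age, entry week, weekly oestrus state.

    ``df`` columns: ``actor_id, age, entry_week`` plus optional
    ``leave_week`` (NaN = never leaves) and ``oestrus_w<k>`` indicator
    columns for k = 1..n_waves.  ``di`` (mean dominance index) is appended
    by :mod:`groomnet.dominance`.
    """

    df: pd.DataFrame
    n_waves: int

    def __post_init__(self) -> None:
        req = {"actor_id", "age", "entry_week"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValidationError(f"actor table missing columns: {sorted(missing)}")
        if self.df["actor_id"].duplicated().any():
            raise ValidationError("duplicate actor_id")
        self.df = self.df.reset_index(drop=True)
        if "leave_week" not in self.df.columns:
            self.df["leave_week"] = np.nan

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list:
        return self.df["actor_id"].tolist()

    def entry_week(self, actor_id) -> int:
        row = self.df.loc[self.df["actor_id"] == actor_id]
        return int(row["entry_week"].iloc[0])

    def present(self, week: int) -> np.ndarray:
        """Boolean mask over actors present (active) in a given week."""
        entry = self.df["entry_week"].to_numpy()
        leave = self.df["leave_week"].to_numpy(dtype=float)
        return (entry <= week) & (np.isnan(leave) | (week <= leave))

    def present_weeks(self, actor_id) -> set[int]:
        mask = [w for w in range(1, self.n_waves + 1)
                if self.present(w)[self.ids.index(actor_id)]]
        return set(mask)

    def newly_entered(self, week: int) -> np.ndarray:
        """Entry coding: True where the actor joined the group this week."""
        return self.df["entry_week"].to_numpy() == week

    def oestrus(self, week: int) -> np.ndarray:
        col = f"oestrus_w{week}"
        if col not in self.df.columns:
            return np.zeros(len(self.df), dtype=bool)
        return self.df[col].to_numpy().astype(bool)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_waves: int) -> "ActorTable":
        return cls(pd.read_csv(path, dtype={"actor_id": str}), n_waves)


# ---------------------------------------------------------------------------
# Waves and panels
# ---------------------------------------------------------------------------

@dataclass
class WaveNetwork:
    """One weekly directed binary network on the global actor index."""

    week: int
    actor_ids: list
    active: np.ndarray  # bool, shape (n,)
    adj: np.ndarray     # int8, shape (n, n), zero diagonal

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        self.adj = np.asarray(self.adj)
        n = len(self.actor_ids)
        if self.adj.shape != (n, n):
            raise ValidationError("adjacency shape does not match actor index")
        if np.diag(self.adj).any():
            raise ValidationError("self-ties on the diagonal")
        inactive = ~self.active
        if self.adj[inactive].any() or self.adj[:, inactive].any():
            raise ValidationError("ties involving inactive actors")

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_ties(self) -> int:
        return int(self.adj.sum())

    def subnetwork(self) -> np.ndarray:
        """Adjacency restricted to active actors."""
        idx = np.flatnonzero(self.active)
        return self.adj[np.ix_(idx, idx)]


@dataclass
class WavePanel:
    """Ordered sequence of weekly waves sharing one global actor index."""

    actor_ids: list
    waves: list[WaveNetwork]
    weighted: list[np.ndarray]            # parallel to waves
    composition: pd.DataFrame             # actor_id, join_wave, leave_wave, frac_w<k>
    actors: ActorTable | None = None

    def __post_init__(self) -> None:
        weeks = [w.week for w in self.waves]
        if weeks != sorted(weeks) or len(set(weeks)) != len(weeks):
            raise ValidationError("wave weeks must be strictly increasing")
        for w in self.waves:
            if w.actor_ids != self.actor_ids:
                raise ValidationError("waves must share the global actor index")

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    def active_matrix(self) -> np.ndarray:
        """Bool array (n_waves, n_actors) of presence."""
        return np.stack([w.active for w in self.waves])

    def presence_fraction(self, wave_idx: int) -> np.ndarray:
        col = f"frac_w{self.waves[wave_idx].week}"
        if col in self.composition.columns:
            return self.composition[col].to_numpy(dtype=float)
        return np.ones(self.n_actors)

    # -- serialization ------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for wave, wmat in zip(self.waves, self.weighted):
            pd.DataFrame(wave.adj, index=self.actor_ids, columns=self.actor_ids
                         ).to_csv(outdir / f"wave_{wave.week}_binary.csv")
            pd.DataFrame(wmat, index=self.actor_ids, columns=self.actor_ids
                         ).to_csv(outdir / f"wave_{wave.week}_weighted.csv")
        self.composition.to_csv(outdir / "composition.csv", index=False)
        manifest = pd.DataFrame(
            {"week": [w.week for w in self.waves],
             "n_active": [w.n_active for w in self.waves]}
        )
        manifest.to_csv(outdir / "manifest.csv", index=False)

    @classmethod
    def read(cls, outdir: str | Path, actors: ActorTable | None = None) -> "WavePanel":
        outdir = Path(outdir)
        manifest = pd.read_csv(outdir / "manifest.csv")
        composition = pd.read_csv(outdir / "composition.csv", dtype={"actor_id": str})
        waves, weighted = [], []
        actor_ids = None
        for week in manifest["week"]:
            wdf = pd.read_csv(outdir / f"wave_{week}_weighted.csv", index_col=0)
            bdf = pd.read_csv(outdir / f"wave_{week}_binary.csv", index_col=0)
            if actor_ids is None:
                actor_ids = [str(i) for i in wdf.index]
            adj = bdf.to_numpy().astype(np.int8)
            active = adj.any(axis=0) | adj.any(axis=1)
            # composition is authoritative for presence (a lone actor has no ties)
            join = composition.set_index("actor_id")["join_wave"]
            leave = composition.set_index("actor_id")["leave_wave"]
            jn = join.reindex(actor_ids).to_numpy(dtype=float)
            lv = leave.reindex(actor_ids).to_numpy(dtype=float)
            active = (jn <= week) & (np.isnan(lv) | (week <= lv))
            waves.append(WaveNetwork(int(week), actor_ids, active, adj))
            weighted.append(wdf.to_numpy().astype(np.int64))
        return cls(actor_ids, waves, weighted, composition, actors)

    def to_graphml(self, outdir: str | Path) -> None:
        import networkx as nx

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for wave, wmat in zip(self.waves, self.weighted):
            g = nx.DiGraph()
            idx = np.flatnonzero(wave.active)
            g.add_nodes_from(self.actor_ids[i] for i in idx)
            for i in idx:
                for j in idx:
                    if wave.adj[i, j]:
                        g.add_edge(self.actor_ids[i], self.actor_ids[j],
                                   weight=int(wmat[i, j]))
            nx.write_graphml(g, outdir / f"wave_{wave.week}.graphml")


# ---------------------------------------------------------------------------
# Wave construction
# ---------------------------------------------------------------------------

def build_weighted_wave(
    log: EventLog,
    week: int,
    actor_ids: Sequence,
    active: np.ndarray,
    schedule: ObservationSchedule | None = None,
    on_inactive: str = "error",
) -> np.ndarray:
    """Count matrix of directed grooming events for one week.

    Entry (i, j) is the number of i->j grooming events that week among
    active actors.  Events involving an actor inactive that week raise a
    :class:`ValidationError` (``on_inactive="drop"`` drops them with a
    warning instead).
    """
    schedule = schedule or ObservationSchedule()
    idx = {a: k for k, a in enumerate(actor_ids)}
    n = len(actor_ids)
    counts = np.zeros((n, n), dtype=np.int64)
    groom = log.groom_events()
    weeks = groom["timestamp"].map(schedule.week_of)
    this_week = groom[weeks == week]
    bad_rows = []
    for row_i, row in this_week.iterrows():
        a, r = idx.get(row["actor"]), idx.get(row["recipient"])
        if a is None or r is None or not (active[a] and active[r]):
            bad_rows.append(row_i + 1)
            continue
        counts[a, r] += 1
    if bad_rows:
        if on_inactive == "error":
            raise ValidationError(
                f"week-{week} events involving inactive/unknown actors", bad_rows
            )
        warnings.warn(
            f"dropped {len(bad_rows)} week-{week} events involving inactive actors"
        )
    return counts


def binarize(weighted: np.ndarray) -> np.ndarray:
    """Binary adjacency: 1 wherever at least one event occurred (weight >= 1)."""
    weighted = np.asarray(weighted)
    if (weighted < 0).any():
        raise ValidationError("negative weights")
    return (weighted >= 1).astype(np.int8)


def normalized_weighted_degrees(
    weighted: np.ndarray, active: np.ndarray, mode: str = "weighted"
) -> pd.DataFrame:
    """Per-actor normalized weighted out/in degree, each in [0, 1].

    Strength (row/column sums of the count matrix over active actors) is
    divided by the maximum attainable value in this network:
    ``(n_active - 1) * max dyadic weight`` for ``mode="weighted"`` or
    plain ``n_active - 1`` for ``mode="binary"``.
    """
    active = np.asarray(active, dtype=bool)
    n_active = int(active.sum())
    if n_active < 2:
        raise ValidationError("normalized degrees undefined for < 2 active actors")
    sub = np.asarray(weighted, dtype=float)[np.ix_(active, active)]
    if mode == "binary":
        sub = (sub >= 1).astype(float)
        denom = n_active - 1
    else:
        wmax = sub.max()
        denom = (n_active - 1) * (wmax if wmax > 0 else 1.0)
    out = sub.sum(axis=1) / denom
    inn = sub.sum(axis=0) / denom
    idx = np.flatnonzero(active)
    return pd.DataFrame({"actor_index": idx, "out": out, "in": inn})


def build_panel(
    log: EventLog,
    actors: ActorTable,
    n_waves: int,
    schedule: ObservationSchedule | None = None,
    on_inactive: str = "error",
) -> WavePanel:
    """Assemble the weekly panel of weighted + binary waves with composition."""
    schedule = schedule or ObservationSchedule(n_weeks=n_waves)
    actor_ids = actors.ids
    waves, weighted = [], []
    comp = {
        "actor_id": actor_ids,
        "join_wave": actors.df["entry_week"].tolist(),
        "leave_wave": actors.df["leave_week"].tolist(),
    }
    for week in range(1, n_waves + 1):
        active = actors.present(week)
        counts = build_weighted_wave(
            log, week, actor_ids, active, schedule, on_inactive
        )
        waves.append(WaveNetwork(week, actor_ids, active, binarize(counts)))
        weighted.append(counts)
        comp[f"frac_w{week}"] = np.where(active, 1.0, 0.0)
    return WavePanel(actor_ids, waves, weighted, pd.DataFrame(comp), actors)
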