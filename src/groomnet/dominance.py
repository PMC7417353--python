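"""Dominance hierarchy from agonistic interactions.

Weekly headbutt records give, per dyad, a dominant (the cow delivering
more headbutts) and a subordinate.  The dominance index (DI) of a cow is
her number of subordinates divided by the number of animals she interacted
with; rank classes follow the conventional cut points (low: DI < 0.40,
medium: 0.40 <= DI < 0.60, high: DI >= 0.60).  Week-to-week stability and
inter-observer reliability are quantified with the intraclass correlation
coefficient ICC(A,k): two-way model, absolute agreement, mean of k
ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data import ActorTable, EventLog, ValidationError
from .schedule import ObservationSchedule

TiePolicy = Literal["partner_only", "half_credit"]


@dataclass
class DominanceMatrix:
    """Weekly headbutt count matrix among active actors."""

    week: int
    actor_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if (c < 0).any() or np.diag(c).any():
            raise ValidationError("headbutt counts must be nonnegative, zero diagonal")


def weekly_dominance_matrices(
    log: EventLog,
    actors: ActorTable,
    schedule: ObservationSchedule | None = None,
) -> list[DominanceMatrix]:
    schedule = schedule or ObservationSchedule(n_weeks=actors.n_waves)
    ids = actors.ids
    idx = {a: k for k, a in enumerate(ids)}
    hb = log.headbutt_events()
    weeks = hb["timestamp"].map(schedule.week_of)
    out = []
    for week in range(1, actors.n_waves + 1):
        counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
        for _, row in hb[weeks == week].iterrows():
            a, r = idx.get(row["actor"]), idx.get(row["recipient"])
            if a is not None and r is not None:
                counts[a, r] += 1
        out.append(DominanceMatrix(week, ids, counts))
    return out


def dyadic_dominance(dm: DominanceMatrix) -> pd.DataFrame:
    """Per-dyad labels: dominant / subordinate / tied for interacting dyads."""
    c = np.asarray(dm.counts)
    rows = []
    n = c.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            total = c[i, j] + c[j, i]
            if total == 0:
                continue
            if c[i, j] > c[j, i]:
                dom, sub = dm.actor_ids[i], dm.actor_ids[j]
            elif c[j, i] > c[i, j]:
                dom, sub = dm.actor_ids[j], dm.actor_ids[i]
            else:
                dom = sub = None
            rows.append(
                {"week": dm.week, "a": dm.actor_ids[i], "b": dm.actor_ids[j],
                 "dominant": dom, "subordinate": sub, "tied": dom is None}
            )
    return pd.DataFrame(rows, columns=["week", "a", "b", "dominant",
                                       "subordinate", "tied"])


def rank_class(di: float) -> str:
    if di < 0.40:
        return "low"
    if di < 0.60:
        return "medium"
    return "high"


def dominance_index(
    labels: pd.DataFrame,
    actor_id,
    tie_policy: TiePolicy = "partner_only",
) -> dict:
    """DI record for one actor from a week's dyadic labels.

    Tied dyads count toward the partner total; under ``partner_only``
    (default) they contribute no subordinates, under ``half_credit`` they
    contribute 0.5.
    """
    mine = labels[(labels["a"] == actor_id) | (labels["b"] == actor_id)]
    n_partners = len(mine)
    n_sub = float((mine["dominant"] == actor_id).sum())
    if tie_policy == "half_credit":
        n_sub += 0.5 * float(mine["tied"].sum())
    week = int(labels["week"].iloc[0]) if len(labels) else None
    if n_partners == 0:
        return {"actor_id": actor_id, "week": week, "n_subordinates": 0,
                "n_partners": 0, "di": float("nan"), "rank_class": None}
    di = n_sub / n_partners
    return {"actor_id": actor_id, "week": week, "n_subordinates": n_sub,
            "n_partners": n_partners, "di": di, "rank_class": rank_class(di)}


def weekly_rank_records(
    log: EventLog,
    actors: ActorTable,
    schedule: ObservationSchedule | None = None,
    tie_policy: TiePolicy = "partner_only",
) -> pd.DataFrame:
    """RankRecord table: one row per present actor-week."""
    rows = []
    for dm in weekly_dominance_matrices(log, actors, schedule):
        labels = dyadic_dominance(dm)
        present = actors.present(dm.week)
        for k, actor in enumerate(actors.ids):
            if not present[k]:
                continue
            rec = dominance_index(labels, actor, tie_policy) if len(labels) else {
                "actor_id": actor, "week": dm.week, "n_subordinates": 0,
                "n_partners": 0, "di": float("nan"), "rank_class": None}
            rec["week"] = dm.week
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc_absolute_agreement(ratings: np.ndarray) -> dict:
    """ICC(A,k): two-way, absolute agreement, mean of k raters.

    ``ratings`` is subjects x raters with no missing cells.  Returns the
    coefficient with its F test and 95% confidence interval.
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValidationError("ICC needs >= 2 subjects and >= 2 raters")
    if np.isnan(ratings).any():
        raise ValidationError("ICC input must have no missing cells")
    n, k = ratings.shape
    if np.isclose(ratings.mean(axis=1).var(), 0.0):
        raise ValidationError("zero between-subject variance: ICC undefined")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # label and CI column names vary across pingouin releases
    label = "ICC(A,k)" if "ICC(A,k)" in table.index else "ICC2k"
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.loc[label]
    return {
        "icc": float(row["ICC"]),
        "F": float(row["F"]),
        "df1": float(row["df1"]),
        "df2": float(row["df2"]),
        "p": float(row["pval"]),
        "ci95": tuple(float(v) for v in row[ci_col]),
    }


def di_stability(rank_records: pd.DataFrame) -> dict:
    """ICC of the dominance index across weeks (complete-case actors)."""
    wide = rank_records.pivot(index="actor_id", columns="week", values="di")
    complete = wide.dropna()
    if len(complete) < 2:
        raise ValidationError("fewer than 2 complete-case actors")
    return icc_absolute_agreement(complete.to_numpy())


def mean_di(rank_records: pd.DataFrame) -> pd.Series:
    """Weekly DIs averaged per actor: the constant social-rank covariate."""
    return rank_records.groupby("actor_id")["di"].mean()
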