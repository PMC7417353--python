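"""Per-wave network summaries and between-wave tie dynamics.

Reproduces the standard descriptive surface for a weekly panel of directed
grooming networks: density, reciprocity, directed diameter and average
path length per wave, and created/dissolved/stable tie counts with the
Jaccard stability index per consecutive wave pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx
import numpy as np
import pandas as pd

from .data import ValidationError, WaveNetwork, WavePanel


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report rounding: half-up at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WaveSummary:
    week: int
    n_nodes: int
    n_ties: int
    density: float
    diameter: float          # nan when no finite path exists
    average_path_length: float
    reciprocity: float       # nan when the wave has no ties


@dataclass
class TieChange:
    from_week: int
    to_week: int
    created: int
    dissolved: int
    stable: int

    @property
    def jaccard(self) -> float:
        denom = self.created + self.dissolved + self.stable
        return self.stable / denom if denom > 0 else float("nan")


def density(wave: WaveNetwork | np.ndarray, n_nodes: int | None = None) -> float:
    """Directed density: ties / (n * (n - 1)) over active actors."""
    if isinstance(wave, WaveNetwork):
        n, ties = wave.n_active, wave.n_ties
    else:
        adj = np.asarray(wave)
        n = adj.shape[0] if n_nodes is None else n_nodes
        ties = int(adj.sum())
    if n < 2:
        raise ValidationError("density undefined for fewer than 2 active nodes")
    return ties / (n * (n - 1))


def density_from_counts(n_nodes: int, n_ties: int) -> float:
    """Density from printed node/tie counts (worked-example surface)."""
    if n_nodes < 2:
        raise ValidationError("density undefined for fewer than 2 nodes")
    return n_ties / (n_nodes * (n_nodes - 1))


def reciprocity(wave: WaveNetwork | np.ndarray) -> float:
    """Proportion of ties i->j whose reverse j->i is also present."""
    adj = wave.subnetwork() if isinstance(wave, WaveNetwork) else np.asarray(wave)
    ties = adj.sum()
    if ties == 0:
        raise ValidationError("reciprocity undefined for a network with no ties")
    return float((adj * adj.T).sum() / ties)


def shortest_path_stats(wave: WaveNetwork | np.ndarray) -> tuple[float, float]:
    """(diameter, average path length) over finite directed geodesics.

    Unreachable ordered pairs are excluded from the average; the diameter
    is the longest finite geodesic.  Both are nan when no finite path
    exists.
    """
    adj = wave.subnetwork() if isinstance(wave, WaveNetwork) else np.asarray(wave)
    if adj.shape[0] < 2:
        raise ValidationError("path statistics need at least 2 active nodes")
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    lengths = [
        dist
        for _, targets in nx.all_pairs_shortest_path_length(g)
        for node, dist in targets.items()
        if dist > 0
    ]
    if not lengths:
        return float("nan"), float("nan")
    return float(max(lengths)), float(np.mean(lengths))


def jaccard_from_counts(created: int, dissolved: int, stable: int) -> float:
    """Jaccard stability index from printed tie-change counts."""
    denom = created + dissolved + stable
    if denom <= 0:
        raise ValidationError("Jaccard undefined without any tie changes or ties")
    return stable / denom


def tie_changes(wave_a: WaveNetwork, wave_b: WaveNetwork) -> TieChange:
    """Created/dissolved/stable ties over dyads jointly active in both waves."""
    joint = wave_a.active & wave_b.active
    if not joint.any():
        raise ValidationError("no jointly active actors between waves")
    mask = joint[:, None] & joint[None, :]
    np.fill_diagonal(mask, False)
    a = wave_a.adj.astype(bool) & mask
    b = wave_b.adj.astype(bool) & mask
    return TieChange(
        from_week=wave_a.week,
        to_week=wave_b.week,
        created=int((~a & b).sum()),
        dissolved=int((a & ~b).sum()),
        stable=int((a & b).sum()),
    )


def summarize_wave(wave: WaveNetwork) -> WaveSummary:
    dens = density(wave)
    try:
        rec = reciprocity(wave)
    except ValidationError:
        rec = float("nan")
    diam, apl = shortest_path_stats(wave)
    return WaveSummary(
        week=wave.week, n_nodes=wave.n_active, n_ties=wave.n_ties,
        density=dens, diameter=diam, average_path_length=apl, reciprocity=rec,
    )


def summarize_panel(panel: WavePanel
                    ) -> tuple[list[WaveSummary], list[TieChange]]:
    """One summary per wave plus tie-change records per consecutive pair."""
    summaries = [summarize_wave(w) for w in panel.waves]
    changes = [
        tie_changes(a, b) for a, b in zip(panel.waves[:-1], panel.waves[1:])
    ]
    return summaries, changes


def summary_frame(summaries: list[WaveSummary]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    for col in ("density", "average_path_length", "reciprocity"):
        df[col] = df[col].map(lambda v: round_half_up(v, 2) if np.isfinite(v) else v)
    return df


def changes_frame(changes: list[TieChange]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {**c.__dict__, "jaccard": round_half_up(c.jaccard, 2)
             if np.isfinite(c.jaccard) else c.jaccard}
            for c in changes
        ]
    )
    return df
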