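"""Goodness of fit by auxiliary network statistics, and forward selection.

A fitted model is judged by whether panels simulated at the estimate
reproduce features of the observed waves that were *not* fitted directly:
the outdegree and indegree distributions, the 16-class directed triad
census, and the geodesic (directed shortest-path) distance distribution,
pooled over the later waves.  Discrepancy is the Mahalanobis distance in
the simulated distribution (variance pooled over simulations,
pseudo-inverse for degenerate components), and the Monte-Carlo p-value is
the proportion of simulated panels at least as discrepant as the observed
one; p > 0.05 indicates the simulated values are close to the observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import WavePanel
from .saom import SAOM

AUXILIARIES = (
    "outdegree_distribution",
    "indegree_distribution",
    "triad_census",
    "geodesic_distribution",
)

#: networkx triad-census keys in canonical order
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

DEGREE_VALUES = np.arange(0, 9)     # cumulative counts at 0..8
GEODESIC_VALUES = np.arange(1, 6)   # pair counts at distances 1..5


def degree_distribution(x: np.ndarray, active: np.ndarray, direction: str
                        ) -> np.ndarray:
    """Cumulative count of active actors with out-/in-degree <= 0..8."""
    sub = np.asarray(x)[np.ix_(active, active)]
    deg = sub.sum(axis=1) if direction == "out" else sub.sum(axis=0)
    return np.array([(deg <= v).sum() for v in DEGREE_VALUES], dtype=float)


def triad_census(x: np.ndarray, active: np.ndarray) -> np.ndarray:
    """16-class directed triad census of the active subgraph."""
    sub = np.asarray(x)[np.ix_(active, active)]
    g = nx.from_numpy_array(sub, create_using=nx.DiGraph)
    census = nx.triadic_census(g)
    return np.array([census[c] for c in TRIAD_CLASSES], dtype=float)


def geodesic_distribution(x: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Counts of ordered active pairs at directed geodesic distance 1..5."""
    sub = np.asarray(x)[np.ix_(active, active)]
    g = nx.from_numpy_array(sub, create_using=nx.DiGraph)
    counts = np.zeros(len(GEODESIC_VALUES))
    for _, lengths in nx.all_pairs_shortest_path_length(g, cutoff=int(GEODESIC_VALUES[-1])):
        for dist in lengths.values():
            if 1 <= dist <= GEODESIC_VALUES[-1]:
                counts[dist - 1] += 1
    return counts


def auxiliary_vector(aux: str, x: np.ndarray, active: np.ndarray) -> np.ndarray:
    if aux == "outdegree_distribution":
        return degree_distribution(x, active, "out")
    if aux == "indegree_distribution":
        return degree_distribution(x, active, "in")
    if aux == "triad_census":
        return triad_census(x, active)
    if aux == "geodesic_distribution":
        return geodesic_distribution(x, active)
    raise ValueError(f"unknown auxiliary statistic {aux!r}")


@dataclass
class GofResult:
    auxiliary: str
    observed: np.ndarray
    simulated: np.ndarray        # (n_sim, n_components)
    kept: np.ndarray             # indices of non-degenerate components
    distance_observed: float
    distances_simulated: np.ndarray
    p_value: float

    def __repr__(self) -> str:
        return (f"GofResult({self.auxiliary}, d_obs={self.distance_observed:.2f}, "
                f"p={self.p_value:.3f})")


def _panel_auxiliary(aux: str, waves, actives) -> np.ndarray:
    """Auxiliary vector pooled (summed) over end waves."""
    return np.sum(
        [auxiliary_vector(aux, x, act) for x, act in zip(waves, actives)], axis=0
    )


def gof(
    model: SAOM,
    panel: WavePanel,
    auxiliary: str = "outdegree_distribution",
    n_sim: int = 200,
    seed: int | None = None,
) -> GofResult:
    """Monte-Carlo Mahalanobis goodness of fit for one auxiliary statistic."""
    actives = [w.active for w in panel.waves[1:]]
    observed_waves = [w.adj for w in panel.waves[1:]]
    obs = _panel_auxiliary(auxiliary, observed_waves, actives)

    sims = model.simulate(n_sim, seed=seed)
    sim_vectors = np.array(
        [_panel_auxiliary(auxiliary, ends, actives) for ends in sims]
    )

    var = sim_vectors.var(axis=0)
    kept = np.flatnonzero(var > 1e-12)
    if len(kept) < len(var):
        warnings.warn(
            f"{auxiliary}: dropped {len(var) - len(kept)} degenerate component(s)"
        )
    if len(kept) == 0:
        return GofResult(auxiliary, obs, sim_vectors, kept, 0.0,
                         np.zeros(n_sim), 1.0)
    V = sim_vectors[:, kept]
    center = V.mean(axis=0)
    prec = np.linalg.pinv(np.atleast_2d(np.cov(V, rowvar=False)))
    d = obs[kept] - center
    d_obs = float(d @ prec @ d)

    # leave-one-out distances keep the simulated panels exchangeable with
    # the held-out observed panel (in-sample Mahalanobis distances are
    # deflated, badly so for the 16-component triad census)
    d_sim = np.empty(n_sim)
    for i in range(n_sim):
        rest = np.delete(V, i, axis=0)
        prec_i = np.linalg.pinv(np.atleast_2d(np.cov(rest, rowvar=False)))
        di = V[i] - rest.mean(axis=0)
        d_sim[i] = di @ prec_i @ di
    p = float((d_sim >= d_obs).mean())
    return GofResult(auxiliary, obs, sim_vectors, kept, d_obs, d_sim, p)


def gof_all(model: SAOM, panel: WavePanel, n_sim: int = 200,
            seed: int | None = None) -> dict[str, GofResult]:
    return {aux: gof(model, panel, aux, n_sim, seed) for aux in AUXILIARIES}


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------

def forward_selection(
    panel: WavePanel,
    base_spec,
    candidates,
    gof_nsim: int = 100,
    gof_threshold: float = 0.05,
    z_threshold: float = 1.96,
    seed: int = 0,
    **fit_options,
) -> tuple[object, list[dict]]:
    """Add candidate effects one at a time, keeping those that earn their place.

    A candidate is retained iff the extended fit converges (all |t-ratios|
    below threshold, max convergence ratio below threshold), its estimate is
    significant (|estimate/SE| >= 1.96), and no auxiliary GOF p-value drops
    below 0.05 — i.e. falls under the threshold while also being worse than
    the current model's p for that auxiliary.  Returns the final spec and a
    ledger of every decision.
    """
    from .effects import ModelSpec

    spec = base_spec
    ledger = []
    current_model = SAOM(spec=spec, seed=seed, **fit_options).fit(panel)
    current_gof = {
        aux: gof(current_model, panel, aux, n_sim=gof_nsim, seed=seed + 1)
        for aux in AUXILIARIES
    }
    for cand in candidates:
        record = {"candidate": cand.key, "retained": False, "reason": ""}
        try:
            trial_spec = ModelSpec(
                spec.effects + [cand], list(spec.rates), dict(spec.covariates)
            )
            model = SAOM(spec=trial_spec, seed=seed, **fit_options).fit(panel)
            fit = model.result_
            idx = fit.names.index(cand.key)
            if not fit.converged:
                record["reason"] = (
                    f"non-convergence (max ratio {fit.max_conv_ratio:.3f})"
                )
            elif fit.se[idx] <= 0 or abs(fit.theta[idx] / fit.se[idx]) < z_threshold:
                record["reason"] = (
                    f"not significant (z = {fit.theta[idx] / max(fit.se[idx], 1e-12):.2f})"
                )
            else:
                gres = gof_all(model, panel, n_sim=gof_nsim, seed=seed + 1)
                bad = [
                    a for a, g in gres.items()
                    if g.p_value < gof_threshold
                    and g.p_value < current_gof[a].p_value
                ]
                if bad:
                    record["reason"] = f"GOF degraded: {bad}"
                else:
                    spec = trial_spec
                    current_model = model
                    current_gof = gres
                    record["retained"] = True
                    record["reason"] = "converged, significant, GOF intact"
                    record["estimate"] = float(fit.theta[idx])
                    record["se"] = float(fit.se[idx])
        except Exception as exc:  # singular D, spec errors, ...
            record["reason"] = f"rejected: {exc}"
        ledger.append(record)
    return spec, ledger
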