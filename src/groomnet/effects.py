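"""Model effects: per-actor statistics, evaluation/rate functions, MoM targets.

An actor-oriented model for directed networks is parametrized by a linear
evaluation function f_i(x) = sum_k beta_k * s_ik(x) built from the per-actor
statistics below, plus a rate function giving the intensity at which each
actor receives change opportunities.  The Method-of-Moments estimator pairs
every free parameter with a target statistic computed on the observed waves.

Statistic formulas (x binary directed, no self-ties, v a centered covariate):

==========================  =================================================
outdegree                   sum_j x_ij
reciprocity                 sum_j x_ij x_ji
transitive_triplets         sum_{j,h} x_ih x_hj x_ij
three_cycles                sum_{j,h} x_ij x_jh x_hi
transitive_recip_triplets   sum_{j,h} x_ij x_ji x_ih x_hj
indegree_popularity         sum_j x_ij indeg(j)
indegree_popularity_sqrt    sum_j x_ij sqrt(indeg(j))
outdegree_popularity_sqrt   sum_j x_ij sqrt(outdeg(j))
outdegree_activity_sqrt     outdeg(i)^(3/2)
out_out_assortativity       sum_j x_ij sqrt(outdeg(i)) sqrt(outdeg(j))
cov_ego                     v_i * outdeg(i)
cov_alter                   sum_j x_ij v_j
cov_same                    sum_j x_ij 1{v_i = v_j}
cov_similarity              sum_j x_ij (sim_ij - mean sim),
                            sim_ij = 1 - |v_i - v_j| / range(v)
same_cov_x_reciprocity      sum_j x_ij x_ji 1{v_i = v_j}
==========================  =================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

EVALUATION_EFFECTS = (
    "outdegree",
    "reciprocity",
    "transitive_triplets",
    "transitive_recip_triplets",
    "three_cycles",
    "indegree_popularity",
    "indegree_popularity_sqrt",
    "outdegree_popularity_sqrt",
    "outdegree_activity_sqrt",
    "out_out_assortativity",
    "cov_ego",
    "cov_alter",
    "cov_same",
    "cov_similarity",
    "same_cov_x_reciprocity",
)
RATE_EFFECTS = ("rate_basic", "rate_outdegree")
COVARIATE_EFFECTS = (
    "cov_ego", "cov_alter", "cov_same", "cov_similarity", "same_cov_x_reciprocity",
)

#: integer codes consumed by the simulation kernel
EFFECT_CODES = {name: k for k, name in enumerate(EVALUATION_EFFECTS)}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """One effect: name, optional covariate, and its parameter value."""

    name: str
    covariate: str | None = None
    parameter: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.name not in EVALUATION_EFFECTS + RATE_EFFECTS:
            raise SpecError(f"unknown effect: {self.name!r}")
        if self.name in COVARIATE_EFFECTS and self.covariate is None:
            raise SpecError(f"effect {self.name!r} requires a covariate")

    @property
    def key(self) -> str:
        return self.name if self.covariate is None else f"{self.name}:{self.covariate}"


@dataclass
class Covariate:
    """Registered actor covariate.

    ``values`` is (n_actors,) for a constant covariate or
    (n_actors, n_periods) for a changing one (value in force during each
    period).  ``categorical`` marks covariates whose equality (not distance)
    is meaningful; they are exempt from centering.
    """

    name: str
    values: np.ndarray
    categorical: bool = False

    @property
    def changing(self) -> bool:
        return np.ndim(self.values) == 2

    def period_values(self, m: int) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return v[:, m] if self.changing else v


@dataclass
class ModelSpec:
    """Effect list, per-period rates, and the covariate registry."""

    effects: list[EffectSpec]
    rates: list[float] = field(default_factory=list)  # rho_m, one per period
    covariates: dict[str, Covariate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.evaluation_effects]
        if len(keys) != len(set(keys)):
            raise SpecError("duplicated effects")
        if "outdegree" not in [e.name for e in self.evaluation_effects]:
            raise SpecError("the outdegree effect must be present")
        for e in self.effects:
            if e.covariate is not None and e.covariate not in self.covariates:
                raise SpecError(
                    f"effect {e.key!r} references unregistered covariate"
                )
        if any(r < 0 for r in self.rates):
            raise SpecError("rates must be nonnegative")

    @property
    def evaluation_effects(self) -> list[EffectSpec]:
        return [e for e in self.effects if e.name in EVALUATION_EFFECTS]

    @property
    def rate_outdegree(self) -> EffectSpec | None:
        for e in self.effects:
            if e.name == "rate_outdegree":
                return e
        return None

    @property
    def beta(self) -> np.ndarray:
        return np.array([e.parameter for e in self.evaluation_effects])

    def with_parameters(
        self, rates: Sequence[float], alpha: float | None, beta: Sequence[float]
    ) -> "ModelSpec":
        effects = []
        k = 0
        for e in self.effects:
            if e.name in EVALUATION_EFFECTS:
                effects.append(replace(e, parameter=float(beta[k])))
                k += 1
            elif e.name == "rate_outdegree":
                effects.append(replace(e, parameter=float(alpha)))
            else:
                effects.append(e)
        return ModelSpec(effects, list(map(float, rates)), dict(self.covariates))

    # -- covariate preparation ---------------------------------------------

    def centered_covariate(self, name: str, period: int, ever_present: np.ndarray
                           ) -> np.ndarray:
        """Covariate values for a period, centered over ever-present actors."""
        cov = self.covariates[name]
        v = cov.period_values(period).astype(float).copy()
        if not cov.categorical:
            v -= v[ever_present].mean()
        return v

    def dyadic_matrix(self, effect: EffectSpec, period: int,
                      ever_present: np.ndarray) -> np.ndarray:
        """Precomputed dyadic contribution M[i, a] for a covariate effect.

        For ego/alter/same/similarity effects the change in actor i's
        statistic from the presence of tie i->a is a function of (i, a)
        alone; the kernel and the target computation both consume these
        matrices.  ``same_cov_x_reciprocity`` additionally multiplies by
        x_ai at evaluation time.
        """
        cov = self.covariates[effect.covariate]
        raw = cov.period_values(period).astype(float)
        n = len(raw)
        if effect.name == "cov_ego":
            v = self.centered_covariate(effect.covariate, period, ever_present)
            return np.repeat(v[:, None], n, axis=1)
        if effect.name == "cov_alter":
            v = self.centered_covariate(effect.covariate, period, ever_present)
            return np.repeat(v[None, :], n, axis=0)
        if effect.name in ("cov_same", "same_cov_x_reciprocity"):
            return (raw[:, None] == raw[None, :]).astype(float)
        if effect.name == "cov_similarity":
            rng = raw[ever_present].max() - raw[ever_present].min()
            rng = rng if rng > 0 else 1.0
            sim = 1.0 - np.abs(raw[:, None] - raw[None, :]) / rng
            mask = ever_present[:, None] & ever_present[None, :] & ~np.eye(n, dtype=bool)
            return sim - sim[mask].mean()
        raise SpecError(f"not a covariate effect: {effect.name}")


# ---------------------------------------------------------------------------
# Per-actor statistics
# ---------------------------------------------------------------------------

def effect_statistic(
    effect: EffectSpec,
    i: int,
    x: np.ndarray,
    covariates: Mapping[str, np.ndarray] | None = None,
    dyadic: np.ndarray | None = None,
) -> float:
    """Statistic s_ik(x) of actor ``i`` for one evaluation effect.

    ``covariates`` maps covariate name -> centered value vector; covariate
    effects may instead be given their precomputed ``dyadic`` matrix
    (as from :meth:`ModelSpec.dyadic_matrix`).
    """
    x = np.asarray(x, dtype=float)
    row = x[i]
    col = x[:, i]
    name = effect.name
    if name == "outdegree":
        return float(row.sum())
    if name == "reciprocity":
        return float((row * col).sum())
    if name == "transitive_triplets":
        # two-path i->h->j closed by i->j
        return float(row @ x @ row)
    if name == "three_cycles":
        return float(row @ x @ col)
    if name == "transitive_recip_triplets":
        # mutual dyad i<->j closed by a two-path i->h->j
        return float((row * col) @ (row @ x))
    if name == "indegree_popularity":
        return float(row @ x.sum(axis=0))
    if name == "indegree_popularity_sqrt":
        return float(row @ np.sqrt(x.sum(axis=0)))
    if name == "outdegree_popularity_sqrt":
        return float(row @ np.sqrt(x.sum(axis=1)))
    if name == "outdegree_activity_sqrt":
        return float(row.sum() ** 1.5)
    if name == "out_out_assortativity":
        return float(np.sqrt(row.sum()) * (row @ np.sqrt(x.sum(axis=1))))
    # covariate effects
    if dyadic is not None:
        if name == "same_cov_x_reciprocity":
            return float((row * col * dyadic[i]).sum())
        # ego/alter/same/similarity: s_i = sum_a x_ia * M[i, a]
        return float((row * dyadic[i]).sum())
    if covariates is None or effect.covariate not in covariates:
        raise SpecError(f"covariate values required for {effect.key!r}")
    v = np.asarray(covariates[effect.covariate], dtype=float)
    if name == "cov_ego":
        return float(v[i] * row.sum())
    if name == "cov_alter":
        return float(row @ v)
    if name == "cov_same":
        return float((row * (v == v[i])).sum())
    if name == "cov_similarity":
        rng = np.ptp(v)
        rng = rng if rng > 0 else 1.0
        n = len(v)
        sim = 1.0 - np.abs(v[:, None] - v[None, :]) / rng
        mean_sim = sim[~np.eye(n, dtype=bool)].mean()
        return float((row * (sim[i] - mean_sim)).sum())
    if name == "same_cov_x_reciprocity":
        return float((row * col * (v == v[i])).sum())
    raise SpecError(f"unknown evaluation effect {name!r}")


def evaluation_fn(
    i: int,
    x: np.ndarray,
    spec: ModelSpec,
    covariates: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Evaluation function f_i(x) = sum_k beta_k s_ik(x)."""
    return float(
        sum(
            e.parameter * effect_statistic(e, i, x, covariates)
            for e in spec.evaluation_effects
        )
    )


def rate_fn(
    i: int,
    x: np.ndarray,
    period: int,
    spec: ModelSpec,
    active: np.ndarray | None = None,
    presence: np.ndarray | None = None,
) -> float:
    """Change-opportunity intensity lambda_i for one actor in one period."""
    rho = spec.rates[period]
    if rho <= 0:
        raise SpecError("rate parameter must be positive")
    if active is not None and not active[i]:
        return 0.0
    alpha = spec.rate_outdegree.parameter if spec.rate_outdegree else 0.0
    pres = 1.0 if presence is None else float(presence[i])
    outdeg = float(np.asarray(x)[i].sum())
    return rho * np.exp(alpha * outdeg) * pres


# ---------------------------------------------------------------------------
# Method-of-Moments targets
# ---------------------------------------------------------------------------

def total_statistics_codes(x: np.ndarray, codes: np.ndarray, covmats: np.ndarray
                           ) -> np.ndarray:
    """sum_i s_ik(x) per evaluation effect, keyed by kernel effect codes."""
    x = np.asarray(x, dtype=float)
    outdeg = x.sum(axis=1)
    indeg = x.sum(axis=0)
    mutual = x * x.T
    names = {v: k for k, v in EFFECT_CODES.items()}
    out = np.empty(len(codes))
    for k, code in enumerate(codes):
        name = names[int(code)]
        if name == "outdegree":
            out[k] = x.sum()
        elif name == "reciprocity":
            out[k] = mutual.sum()
        elif name == "transitive_triplets":
            out[k] = ((x @ x) * x).sum()
        elif name == "three_cycles":
            out[k] = ((x @ x) * x.T).sum()
        elif name == "transitive_recip_triplets":
            out[k] = (mutual * (x @ x)).sum()
        elif name == "indegree_popularity":
            out[k] = (x @ indeg).sum()
        elif name == "indegree_popularity_sqrt":
            out[k] = (x @ np.sqrt(indeg)).sum()
        elif name == "outdegree_popularity_sqrt":
            out[k] = (x @ np.sqrt(outdeg)).sum()
        elif name == "outdegree_activity_sqrt":
            out[k] = (outdeg ** 1.5).sum()
        elif name == "out_out_assortativity":
            out[k] = (np.sqrt(outdeg) * (x @ np.sqrt(outdeg))).sum()
        elif name == "same_cov_x_reciprocity":
            out[k] = (mutual * covmats[k]).sum()
        else:  # ego/alter/same/similarity via the dyadic contribution matrix
            out[k] = (x * covmats[k]).sum()
    return out


def _total_statistics(x: np.ndarray, spec: ModelSpec, dyadics: list[np.ndarray | None]
                      ) -> np.ndarray:
    """sum_i s_ik(x) for every evaluation effect, vectorized over actors."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    effects = spec.evaluation_effects
    codes = np.array([EFFECT_CODES[e.name] for e in effects], dtype=np.int64)
    covmats = np.zeros((len(effects), n, n))
    for k, M in enumerate(dyadics):
        if M is not None:
            covmats[k] = M
    return total_statistics_codes(x, codes, covmats)


def period_dyadics(spec: ModelSpec, period: int, ever_present: np.ndarray
                   ) -> list[np.ndarray | None]:
    """Dyadic contribution matrix per evaluation effect (None for structural)."""
    return [
        spec.dyadic_matrix(e, period, ever_present) if e.covariate else None
        for e in spec.evaluation_effects
    ]


def target_statistics(panel, spec: ModelSpec) -> np.ndarray:
    """Observed MoM target vector, ordered [rates..., rate_outdegree?, betas...].

    Rate targets are Hamming distances between consecutive observed waves
    over jointly active dyads; the rate-outdegree target is the cross-moment
    sum_m sum_i outdeg_i(x_m) * (# row-i changes); evaluation targets are the
    per-effect statistic totals over actors, summed over waves 2..W.
    """
    if panel.n_waves < 2:
        raise SpecError("at least two waves are required")
    W = panel.n_waves
    ever = panel.active_matrix().any(axis=0)
    rate_targets, eval_totals = [], np.zeros(len(spec.evaluation_effects))
    rate_out_target = 0.0
    for m in range(W - 1):
        a, b = panel.waves[m], panel.waves[m + 1]
        joint = a.active & b.active
        d = (a.adj != b.adj) & joint[:, None] & joint[None, :]
        rate_targets.append(float(d.sum()))
        rate_out_target += float(a.adj.sum(axis=1) @ d.sum(axis=1))
        dyads = period_dyadics(spec, m, ever)
        xb = b.adj * (b.active[:, None] & b.active[None, :])
        eval_totals += _total_statistics(xb, spec, dyads)
    parts = [np.array(rate_targets)]
    if spec.rate_outdegree is not None:
        parts.append(np.array([rate_out_target]))
    parts.append(eval_totals)
    return np.concatenate(parts)


def parameter_names(spec: ModelSpec) -> list[str]:
    """Free-parameter labels in the order used by target/estimate vectors."""
    names = [f"rate_period_{m + 1}" for m in range(len(spec.rates))]
    if spec.rate_outdegree is not None:
        names.append("rate_outdegree")
    names += [e.key for e in spec.evaluation_effects]
    return names
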