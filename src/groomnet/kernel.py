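"""Continuous-time micro-step simulator for directed network dynamics.

Between two observation waves the network evolves by a continuous-time
Markov chain: actor i receives change opportunities at rate
lambda_i = rho_m * exp(alpha * outdeg_i) * presence_i, and at each
opportunity chooses among toggling one of her outgoing ties or leaving the
network unchanged, with multinomial-logit probabilities
exp(f_i(x')) / sum exp(f_i(x'')) over the candidate networks x'.

Two implementations coexist:

* :func:`micro_step` / :func:`simulate_period_python` — plain numpy,
  readable, used for probability-level unit tests;
* :func:`simulate_period_kernel` — a numba-compiled loop used by the
  estimator, goodness-of-fit and the synthetic generator, where millions of
  micro-steps are needed.

Both share the same tie-contribution algebra: for each candidate alter
``a`` the quantity g_a = f_i(x with tie i->a) - f_i(x without tie i->a) is
computed in O(n) from a handful of pre-aggregated vectors, so a full choice
set costs O(n^2) rather than O(n^3).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .effects import EFFECT_CODES, ModelSpec, period_dyadics

_C_OUT = EFFECT_CODES["outdegree"]
_C_REC = EFFECT_CODES["reciprocity"]
_C_TT = EFFECT_CODES["transitive_triplets"]
_C_TRT = EFFECT_CODES["transitive_recip_triplets"]
_C_3C = EFFECT_CODES["three_cycles"]
_C_INP = EFFECT_CODES["indegree_popularity"]
_C_INPS = EFFECT_CODES["indegree_popularity_sqrt"]
_C_OPS = EFFECT_CODES["outdegree_popularity_sqrt"]
_C_OAS = EFFECT_CODES["outdegree_activity_sqrt"]
_C_OOA = EFFECT_CODES["out_out_assortativity"]
_C_EGO = EFFECT_CODES["cov_ego"]
_C_ALT = EFFECT_CODES["cov_alter"]
_C_SAME = EFFECT_CODES["cov_same"]
_C_SIM = EFFECT_CODES["cov_similarity"]
_C_SXR = EFFECT_CODES["same_cov_x_reciprocity"]

MAX_EXP = 40.0  # logit clip guarding exp overflow


def spec_arrays(spec: ModelSpec, period: int, ever_present: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, betas, covmats) for one period, as consumed by the kernels."""
    effects = spec.evaluation_effects
    codes = np.array([EFFECT_CODES[e.name] for e in effects], dtype=np.int64)
    betas = np.array([e.parameter for e in effects], dtype=np.float64)
    n = len(ever_present)
    covmats = np.zeros((len(effects), n, n))
    for k, (e, M) in enumerate(zip(effects, period_dyadics(spec, period, ever_present))):
        if M is not None:
            covmats[k] = M
    return codes, betas, covmats


def tie_contributions(
    i: int,
    x: np.ndarray,
    codes: np.ndarray,
    betas: np.ndarray,
    covmats: np.ndarray,
) -> np.ndarray:
    """g_a = f_i(x + tie i->a) - f_i(x - tie i->a) for every alter a.

    The value is the *presence contribution* of the tie: it does not depend
    on whether the tie currently exists, so the evaluation gain of toggling
    is +g_a when creating and -g_a when dissolving.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    row, col = x[i], x[:, i]
    outdeg, indeg = x.sum(axis=1), x.sum(axis=0)
    g = np.zeros(n)
    u = w = z = rc = None
    for k, (code, beta) in enumerate(zip(codes, betas)):
        if code == _C_OUT:
            c = np.ones(n)
        elif code == _C_REC:
            c = col
        elif code == _C_TT:
            if u is None:
                u = row @ x
            if w is None:
                w = x @ row
            c = u + w
        elif code == _C_3C:
            c = x @ col
        elif code == _C_TRT:
            if u is None:
                u = row @ x
            if rc is None:
                rc = x @ (row * col)
            c = col * u + rc
        elif code == _C_INP:
            c = indeg - row + 1.0
        elif code == _C_INPS:
            c = np.sqrt(indeg - row + 1.0)
        elif code == _C_OPS:
            c = np.sqrt(outdeg)
        elif code == _C_OAS:
            d0 = outdeg[i] - row
            c = (d0 + 1.0) ** 1.5 - d0 ** 1.5
        elif code == _C_OOA:
            d0 = outdeg[i] - row
            s_out = row @ np.sqrt(outdeg)
            t0 = s_out - row * np.sqrt(outdeg)
            c = np.sqrt(d0 + 1.0) * (t0 + np.sqrt(outdeg)) - np.sqrt(d0) * t0
        elif code == _C_SXR:
            c = col * covmats[k][i]
        else:  # ego / alter / same / similarity
            c = covmats[k][i]
        g = g + beta * c
    return g


def choice_probabilities(
    i: int,
    x: np.ndarray,
    spec: ModelSpec,
    active: np.ndarray | None = None,
    period: int = 0,
    covmats: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Micro-step choice distribution for actor ``i``.

    Returns ``(targets, probs)`` where ``targets[k]`` is the alter whose tie
    is toggled (-1 for the no-change option) and ``probs`` sums to 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if active is None:
        active = np.ones(n, dtype=bool)
    ever = np.asarray(active, dtype=bool)
    codes, betas, mats = spec_arrays(spec, period, ever)
    if covmats is not None:
        mats = covmats
    g = tie_contributions(i, x, codes, betas, mats)
    sign = 1.0 - 2.0 * x[i]
    delta = np.clip(sign * g, -MAX_EXP, MAX_EXP)
    cand = np.flatnonzero(active & (np.arange(n) != i))
    weights = np.concatenate([[1.0], np.exp(delta[cand])])
    targets = np.concatenate([[-1], cand])
    return targets, weights / weights.sum()


def micro_step(
    x: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
    period: int = 0,
    active: np.ndarray | None = None,
    presence: np.ndarray | None = None,
) -> np.ndarray:
    """One micro-step: draw an actor by rate, then a tie change by logit.

    Returns a new adjacency differing from ``x`` in at most one tie.
    Raises ``RuntimeError`` if all rates are zero (no-step signal).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if active is None:
        active = np.ones(n, dtype=bool)
    if presence is None:
        presence = np.ones(n)
    rho = spec.rates[period]
    alpha = spec.rate_outdegree.parameter if spec.rate_outdegree else 0.0
    lam = np.where(active, rho * np.exp(alpha * x.sum(axis=1)) * presence, 0.0)
    total = lam.sum()
    if total <= 0:
        raise RuntimeError("all change rates are zero: no micro-step possible")
    i = int(rng.choice(n, p=lam / total))
    targets, probs = choice_probabilities(i, x, spec, active, period)
    a = int(targets[rng.choice(len(targets), p=probs)])
    x_new = x.copy()
    if a >= 0:
        x_new[i, a] = 1.0 - x_new[i, a]
    return x_new


# ---------------------------------------------------------------------------
# numba period kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def simulate_period_kernel(
    x: np.ndarray,          # (n, n) float64, modified in place
    active: np.ndarray,     # (n,) bool
    pres: np.ndarray,       # (n,) float64 presence fractions
    rho: float,
    alpha: float,
    codes: np.ndarray,      # (K,) int64 effect codes
    betas: np.ndarray,      # (K,) float64
    covmats: np.ndarray,    # (K, n, n) float64 dyadic contributions
    seed: int,
) -> int:
    """Simulate one period of unit model time; returns the micro-step count."""
    np.random.seed(seed)
    n = x.shape[0]
    K = codes.shape[0]

    outdeg = np.zeros(n)
    indeg = np.zeros(n)
    for i in range(n):
        for j in range(n):
            outdeg[i] += x[i, j]
            indeg[j] += x[i, j]

    need_u = need_w = need_z = need_rc = need_sout = False
    for k in range(K):
        c = codes[k]
        if c == _C_TT:
            need_u = True
            need_w = True
        elif c == _C_3C:
            need_z = True
        elif c == _C_TRT:
            need_u = True
            need_rc = True
        elif c == _C_OOA:
            need_sout = True

    lam = np.zeros(n)
    u = np.zeros(n)
    w = np.zeros(n)
    z = np.zeros(n)
    rc = np.zeros(n)
    wt = np.zeros(n)

    t = 0.0
    steps = 0
    while True:
        total = 0.0
        for i in range(n):
            if active[i] and pres[i] > 0.0:
                lam[i] = rho * np.exp(alpha * outdeg[i]) * pres[i]
            else:
                lam[i] = 0.0
            total += lam[i]
        if total <= 0.0:
            break
        dt = np.random.exponential(1.0 / total)
        if t + dt > 1.0:
            break
        t += dt
        steps += 1

        r = np.random.random() * total
        i = -1
        acc = 0.0
        for k in range(n):
            acc += lam[k]
            if r < acc:
                i = k
                break
        if i < 0:
            for k in range(n - 1, -1, -1):
                if lam[k] > 0.0:
                    i = k
                    break

        # shared aggregates for this ego
        if need_u:
            for a in range(n):
                u[a] = 0.0
            for h in range(n):
                if x[i, h] > 0.0:
                    for a in range(n):
                        u[a] += x[h, a]
        if need_w:
            for a in range(n):
                s = 0.0
                for j in range(n):
                    s += x[a, j] * x[i, j]
                w[a] = s
        if need_z:
            for a in range(n):
                s = 0.0
                for h in range(n):
                    s += x[a, h] * x[h, i]
                z[a] = s
        if need_rc:
            for a in range(n):
                s = 0.0
                for j in range(n):
                    s += x[a, j] * x[i, j] * x[j, i]
                rc[a] = s
        s_out = 0.0
        if need_sout:
            for j in range(n):
                if x[i, j] > 0.0:
                    s_out += np.sqrt(outdeg[j])

        di = outdeg[i]
        total_w = 1.0  # no-change option
        for a in range(n):
            if a == i or not active[a]:
                wt[a] = 0.0
                continue
            g = 0.0
            for k in range(K):
                c = 0.0
                code = codes[k]
                if code == _C_OUT:
                    c = 1.0
                elif code == _C_REC:
                    c = x[a, i]
                elif code == _C_TT:
                    c = u[a] + w[a]
                elif code == _C_3C:
                    c = z[a]
                elif code == _C_TRT:
                    c = x[a, i] * u[a] + rc[a]
                elif code == _C_INP:
                    c = indeg[a] - x[i, a] + 1.0
                elif code == _C_INPS:
                    c = np.sqrt(indeg[a] - x[i, a] + 1.0)
                elif code == _C_OPS:
                    c = np.sqrt(outdeg[a])
                elif code == _C_OAS:
                    d0 = di - x[i, a]
                    c = (d0 + 1.0) ** 1.5 - d0 ** 1.5
                elif code == _C_OOA:
                    d0 = di - x[i, a]
                    t0 = s_out - x[i, a] * np.sqrt(outdeg[a])
                    c = (np.sqrt(d0 + 1.0) * (t0 + np.sqrt(outdeg[a]))
                         - np.sqrt(d0) * t0)
                elif code == _C_SXR:
                    c = x[a, i] * covmats[k, i, a]
                else:
                    c = covmats[k, i, a]
                g += betas[k] * c
            delta = g if x[i, a] == 0.0 else -g
            if delta > MAX_EXP:
                delta = MAX_EXP
            elif delta < -MAX_EXP:
                delta = -MAX_EXP
            wt[a] = np.exp(delta)
            total_w += wt[a]

        r = np.random.random() * total_w
        if r < 1.0:
            continue  # keep the network unchanged
        r -= 1.0
        a = -1
        acc = 0.0
        for k in range(n):
            acc += wt[k]
            if r < acc:
                a = k
                break
        if a < 0:
            continue
        if x[i, a] > 0.0:
            x[i, a] = 0.0
            outdeg[i] -= 1.0
            indeg[a] -= 1.0
        else:
            x[i, a] = 1.0
            outdeg[i] += 1.0
            indeg[a] += 1.0
    return steps


def simulate_period_python(
    x_start: np.ndarray,
    spec: ModelSpec,
    period: int,
    active: np.ndarray,
    presence: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Reference-path period simulation built on :func:`micro_step`."""
    x = np.asarray(x_start, dtype=float).copy()
    n = x.shape[0]
    rho = spec.rates[period]
    alpha = spec.rate_outdegree.parameter if spec.rate_outdegree else 0.0
    t, steps = 0.0, 0
    while True:
        lam = np.where(active, rho * np.exp(alpha * x.sum(axis=1)) * presence, 0.0)
        total = lam.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > 1.0:
            break
        t += dt
        steps += 1
        x = micro_step(x, spec, rng, period, active, presence)
    return x, steps
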