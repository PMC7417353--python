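"""Method-of-Moments estimation of actor-oriented network dynamics.

The estimator equates observed target statistics (tie-change Hamming
distances per period, and evaluation-effect totals on the later waves) with
their expectations under the simulated micro-step process, solving the
moment equations by Robbins-Monro stochastic approximation in the classic
three-phase scheme:

* phase 1 — estimate the derivative matrix D of expected statistics with
  respect to the parameters by forward finite differences with common
  random numbers, then take one Newton step;
* phase 2 — subphases of diminishing gain updating
  theta <- theta - a * D^-1 * (S_sim - S_obs), each period simulated
  forward from the *observed* previous wave;
* phase 3 — a large simulation archive at the estimate for convergence
  t-ratios, the overall maximum convergence ratio, and standard errors
  cov(theta) = D^-1 Sigma D^-T.

`SAOM` is a scikit-learn-style estimator (``fit`` + trailing-underscore
fitted attributes); :func:`estimate_mom` is the equivalent functional
surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .data import WavePanel
from .effects import (
    ModelSpec,
    SpecError,
    parameter_names,
    target_statistics,
    total_statistics_codes,
)
from .kernel import simulate_period_kernel, simulate_period_python, spec_arrays

MAX_SEED = 2 ** 31 - 1


class EstimationError(RuntimeError):
    pass


class CollinearityError(EstimationError):
    """Singular derivative matrix: effects carry indistinguishable information."""


# ---------------------------------------------------------------------------
# Period contexts: everything fixed about one observation period
# ---------------------------------------------------------------------------

@dataclass
class PeriodContext:
    x_start: np.ndarray       # observed start wave, restricted to period actors
    active: np.ndarray        # actors simulating during the period
    presence: np.ndarray      # fractional presence scaling individual rates
    joint: np.ndarray         # (n, n) dyad mask jointly active in both waves
    outdeg_start: np.ndarray  # outdegrees at the observed start wave
    covmats: np.ndarray       # (K, n, n) dyadic covariate contributions


def build_period_contexts(panel: WavePanel, spec: ModelSpec) -> list[PeriodContext]:
    ever = panel.active_matrix().any(axis=0)
    codes, _, _ = spec_arrays(spec, 0, ever)
    contexts = []
    for m in range(panel.n_waves - 1):
        a, b = panel.waves[m], panel.waves[m + 1]
        # actors in play during the period: those observed at the end wave
        # (joiners start with empty tie profiles, leavers are frozen out)
        act = b.active.copy()
        x0 = a.adj.astype(np.float64) * (act[:, None] & act[None, :])
        joint = (a.active & b.active)
        joint_mask = joint[:, None] & joint[None, :]
        np.fill_diagonal(joint_mask, False)
        _, _, covmats = spec_arrays(spec, m, ever)
        contexts.append(
            PeriodContext(
                x_start=x0,
                active=act,
                presence=panel.presence_fraction(m + 1),
                joint=joint_mask,
                outdeg_start=a.adj.sum(axis=1).astype(float),
                covmats=covmats,
            )
        )
    return contexts


def _unpack_theta(theta: np.ndarray, n_periods: int, has_rate_out: bool
                  ) -> tuple[np.ndarray, float, np.ndarray]:
    rates = theta[:n_periods]
    k = n_periods
    alpha = 0.0
    if has_rate_out:
        alpha = float(theta[k])
        k += 1
    return rates, alpha, theta[k:]


def simulate_panel_statistics(
    contexts: Sequence[PeriodContext],
    codes: np.ndarray,
    theta: np.ndarray,
    has_rate_out: bool,
    seeds: Sequence[int],
    engine: str = "numba",
    spec: ModelSpec | None = None,
    return_end_states: bool = False,
):
    """One forward simulation of every period; returns the statistic vector.

    Statistic layout matches :func:`groomnet.effects.target_statistics`:
    per-period Hamming distances, then (optionally) the rate-outdegree
    cross-moment, then evaluation-effect totals summed over end waves.
    Also returns the per-period evaluation statistics (for the
    time-heterogeneity test) and, on request, the simulated end waves.
    """
    n_periods = len(contexts)
    rates, alpha, betas = _unpack_theta(np.asarray(theta, float), n_periods,
                                        has_rate_out)
    K = len(codes)
    hamming = np.zeros(n_periods)
    rate_out_stat = 0.0
    period_eval = np.zeros((n_periods, K))
    end_states = []
    for m, ctx in enumerate(contexts):
        x = ctx.x_start.copy()
        if engine == "numba":
            simulate_period_kernel(
                x, ctx.active, ctx.presence, float(rates[m]), alpha,
                codes, betas, ctx.covmats, int(seeds[m]) & MAX_SEED,
            )
        else:
            eff = spec.with_parameters(
                list(np.maximum(rates, 1e-6)),
                alpha if has_rate_out else None, betas)
            rng = np.random.default_rng(int(seeds[m]) & MAX_SEED)
            x, _ = simulate_period_python(x, eff, m, ctx.active, ctx.presence, rng)
        diff = (x != ctx.x_start) & ctx.joint
        hamming[m] = diff.sum()
        rate_out_stat += float(ctx.outdeg_start @ diff.sum(axis=1))
        period_eval[m] = total_statistics_codes(x, codes, ctx.covmats)
        if return_end_states:
            end_states.append(x.copy())
    parts = [hamming]
    if has_rate_out:
        parts.append([rate_out_stat])
    parts.append(period_eval.sum(axis=0))
    S = np.concatenate(parts)
    if return_end_states:
        return S, period_eval, end_states
    return S, period_eval


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, diagnostics and the phase-3 simulation archive."""

    names: list[str]
    theta: np.ndarray
    se: np.ndarray
    tratios: np.ndarray
    max_conv_ratio: float
    target: np.ndarray
    archive: np.ndarray                # (n3, p) simulated statistics
    period_stats: np.ndarray           # (n3, n_periods, K) per-period eval stats
    obs_period_stats: np.ndarray       # (n_periods, K) observed eval stats
    D: np.ndarray
    Sigma: np.ndarray
    cov_params: np.ndarray
    spec: ModelSpec
    n_periods: int
    converged: bool
    iteration_log: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def rates(self) -> np.ndarray:
        return self.theta[: self.n_periods]

    @property
    def alpha(self) -> float | None:
        if self.spec.rate_outdegree is None:
            return None
        return float(self.theta[self.n_periods])

    @property
    def beta(self) -> np.ndarray:
        k = self.n_periods + (1 if self.spec.rate_outdegree is not None else 0)
        return self.theta[k:]

    def summary(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.theta / self.se
        return pd.DataFrame(
            {"parameter": self.names, "estimate": self.theta, "se": self.se,
             "t_conv": self.tratios, "z": z}
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "parameters": {
                n: {"estimate": float(t), "se": float(s), "t_ratio": float(tr)}
                for n, t, s, tr in zip(self.names, self.theta, self.se, self.tratios)
            },
            "max_convergence_ratio": float(self.max_conv_ratio),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "targets": {n: float(v) for n, v in zip(self.names, self.target)},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def convergence_diagnostics(fit_or_archive, target=None
                            ) -> tuple[np.ndarray, float]:
    """Per-parameter convergence t-ratios and the max convergence ratio.

    t_k = (mean_sim S_k - S_obs,k) / sd_sim(S_k); the overall maximum
    convergence ratio is sqrt(dbar' Sigma^-1 dbar), the largest t-ratio over
    all linear combinations of the statistics.
    """
    if isinstance(fit_or_archive, FitResult):
        archive, target = fit_or_archive.archive, fit_or_archive.target
    else:
        archive = np.asarray(fit_or_archive, dtype=float)
    target = np.asarray(target, dtype=float)
    dev = archive.mean(axis=0) - target
    sd = archive.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, dev / sd, np.where(dev == 0, 0.0, np.inf))
    Sigma = np.cov(archive, rowvar=False)
    Sigma = np.atleast_2d(Sigma)
    if np.linalg.matrix_rank(Sigma) < Sigma.shape[0]:
        warnings.warn("singular statistic covariance; using pseudo-inverse")
    max_ratio = float(np.sqrt(max(dev @ np.linalg.pinv(Sigma) @ dev, 0.0)))
    return t, max_ratio


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class SAOM(BaseEstimator):
    """Stochastic actor-oriented model, Method-of-Moments estimation.

    Parameters
    ----------
    spec : ModelSpec
        Effects, initial rates and covariate registry.  Parameter values in
        the spec serve as initial values where nonzero.
    n1 : int
        Phase-1 iterations for the derivative matrix (each costs p+1
        simulations under common random numbers).
    n3 : int
        Phase-3 simulations for diagnostics and standard errors.
    n_deriv : int
        Iterations used to re-estimate the derivative matrix at the
        estimate for standard errors.
    gain : float
        Initial Robbins-Monro gain; halved at each of ``subphases``.
    fd_delta : float
        Forward finite-difference step per parameter.
    engine : {"numba", "python"}
        Simulation backend (the python backend is the slow reference path).
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        n1: int = 50,
        subphases: int = 4,
        n2_base: int | None = None,
        n3: int = 1000,
        n_deriv: int = 100,
        gain: float = 0.2,
        fd_delta: float = 0.1,
        max_step: float = 1.0,
        t_ratio_threshold: float = 0.1,
        conv_ratio_threshold: float = 0.25,
        max_restarts: int = 14,
        engine: str = "numba",
        seed: int = 0,
    ):
        self.spec = spec
        self.n1 = n1
        self.subphases = subphases
        self.n2_base = n2_base
        self.n3 = n3
        self.n_deriv = n_deriv
        self.gain = gain
        self.fd_delta = fd_delta
        self.max_step = max_step
        self.t_ratio_threshold = t_ratio_threshold
        self.conv_ratio_threshold = conv_ratio_threshold
        self.max_restarts = max_restarts
        self.engine = engine
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _sim(self, theta, seeds):
        return simulate_panel_statistics(
            self._contexts, self._codes, theta, self._has_rate_out, seeds,
            self.engine, self.spec,
        )

    def _estimate_D(self, theta, rng, n_iter, guard: bool = False,
                    central: bool = False, widths=None):
        """Forward finite differences with common random numbers.

        The step is scale-aware (delta * max(1, |theta_k|)): a fixed small
        step on a rate of several changes per actor-week is lost in
        simulation noise.  With ``guard`` the own-rate diagonal entries
        (positive by construction, since the Hamming target is increasing
        in its own rate) are floored at a small positive value; this keeps
        the Robbins-Monro solver stable but must NOT be applied to the
        derivative used for standard errors, where a genuinely small
        diagonal (rate moment near saturation) must inflate the SE.
        """
        p = len(theta)
        D = np.zeros((p, p))
        S_sum = np.zeros(p)
        if widths is not None:
            deltas = np.asarray(widths, dtype=float)
        elif central:
            # wide central differences: a secant slope over an interval of
            # the order of the standard error maps the confidence interval
            # through the (concave, saturating) moment curve more
            # faithfully than the local tangent at the estimate
            deltas = 4.0 * self.fd_delta * np.maximum(1.0, np.abs(theta))
        else:
            deltas = self.fd_delta * np.maximum(1.0, np.abs(theta))
        for _ in range(n_iter):
            seeds = rng.integers(0, MAX_SEED, size=len(self._contexts))
            if central:
                for k in range(p):
                    lo = theta.copy()
                    hi = theta.copy()
                    if k < self._n_periods:
                        # rates: upward secant — the Hamming moment is
                        # concave and saturating in its rate, so the slope
                        # above the estimate governs the interval that can
                        # reach a larger true rate
                        hi[k] += deltas[k]
                    else:
                        lo[k] -= deltas[k] / 2
                        hi[k] += deltas[k] / 2
                    lo = self._clip_theta(lo)
                    Sl, _ = self._sim(lo, seeds)
                    Sh, _ = self._sim(hi, seeds)
                    D[:, k] += (Sh - Sl) / (hi[k] - lo[k])
            else:
                S0, _ = self._sim(theta, seeds)
                S_sum += S0
                for k in range(p):
                    th = theta.copy()
                    th[k] += deltas[k]
                    Sk, _ = self._sim(th, seeds)
                    D[:, k] += (Sk - S0) / deltas[k]
        D /= n_iter
        if guard:
            floor = max(1.0, 0.05 * np.abs(np.diag(D)).max())
            for mth in range(self._n_periods):
                if D[mth, mth] < floor:
                    D[mth, mth] = floor
        return D, S_sum / n_iter

    def _solve_rate_1d(self, m, theta, target, rng, nsim=400, iters=14):
        """Bracketed 1-D solve of E[Hamming_m](rho_m) = target at fixed beta.

        The period-m Hamming moment is increasing in its own rate and
        almost unaffected by the other rates, so a stuck rate (near the
        saturation plateau, where full-vector Newton steps stall) can be
        repaired by direct monotone search over its own period only.
        """
        ctx = self._contexts[m]
        n_periods = self._n_periods
        rates, alpha, betas = _unpack_theta(theta, n_periods, self._has_rate_out)

        def mean_h(rho):
            seeds = rng.integers(0, MAX_SEED, size=nsim)
            tot = 0.0
            for s in seeds:
                x = ctx.x_start.copy()
                simulate_period_kernel(
                    x, ctx.active, ctx.presence, float(rho), alpha,
                    self._codes, betas, ctx.covmats, int(s) & MAX_SEED,
                )
                tot += ((x != ctx.x_start) & ctx.joint).sum()
            return tot / nsim

        lo, hi = 0.05, 60.0
        rho = float(np.clip(rates[m], lo, hi))
        for _ in range(iters):
            h = mean_h(rho)
            if abs(h - target) < 0.25:
                break
            if h < target:
                lo = rho
            else:
                hi = rho
            if hi - lo < 0.01 * rho:
                break
            # geometric step toward the un-bracketed side, else bisection
            if hi >= 60.0 and h < target:
                rho = min(hi, rho * 1.8)
                if rho >= 59.9:
                    break
            else:
                rho = 0.5 * (lo + hi)
        theta = theta.copy()
        theta[m] = rho
        return theta

    def _solve(self, D, dev):
        # scale out the (legitimately) different magnitudes of rate and
        # evaluation statistics before judging singularity
        p = D.shape[0]
        rnorm = np.linalg.norm(D, axis=1, keepdims=True)
        cnorm = np.linalg.norm(D / np.where(rnorm > 0, rnorm, 1.0), axis=0)
        Dn = D / np.where(rnorm > 0, rnorm, 1.0) / np.where(cnorm > 0, cnorm, 1.0)
        sv = np.linalg.svd(Dn, compute_uv=False)
        if sv[0] <= 0 or sv[-1] / sv[0] < 1e-8:
            # name the offending effects via near-parallel derivative columns
            norms = np.linalg.norm(D, axis=0)
            norms[norms == 0] = 1.0
            Dc = D / norms
            corr = Dc.T @ Dc
            pairs = [
                (self.names_[i], self.names_[j])
                for i in range(p) for j in range(i + 1, p)
                if abs(corr[i, j]) > 0.99
            ]
            raise CollinearityError(
                f"singular derivative matrix; collinear effects: {pairs or 'unknown'}"
            )
        return np.linalg.solve(D, dev)

    def _clip_theta(self, theta):
        theta = theta.copy()
        theta[: self._n_periods] = np.clip(theta[: self._n_periods], 0.05, 60.0)
        theta[self._n_periods:] = np.clip(theta[self._n_periods:], -8.0, 8.0)
        return theta

    # -- API ----------------------------------------------------------------

    def fit(self, panel: WavePanel, y=None) -> "SAOM":
        """Estimate parameters from an observed wave panel."""
        if self.spec is None:
            raise SpecError("a ModelSpec must be supplied")
        if panel.n_waves < 2:
            raise SpecError("at least two waves are required")
        spec = self.spec
        self._n_periods = panel.n_waves - 1
        if len(spec.rates) != self._n_periods:
            spec.rates = list(spec.rates) + [1.0] * (self._n_periods - len(spec.rates))
        self._has_rate_out = spec.rate_outdegree is not None
        ever = panel.active_matrix().any(axis=0)
        self._codes, beta_init, _ = spec_arrays(spec, 0, ever)
        self._contexts = build_period_contexts(panel, spec)
        self.names_ = parameter_names(spec)
        rng = np.random.default_rng(self.seed)

        S_obs = target_statistics(panel, spec)
        self.target_ = S_obs

        # ---- initial values
        theta0 = self._initial_theta(panel, spec, beta_init, S_obs)
        p = len(theta0)
        log = [{"phase": 1, "theta": theta0.tolist()}]

        # ---- phase 1
        D_cur, S_mean = self._estimate_D(theta0, rng, self.n1, guard=True)
        step = np.clip(self._solve(D_cur, S_mean - S_obs),
                       -self.max_step, self.max_step)
        theta = self._clip_theta(theta0 - step)

        # ---- phase 2
        n2_base = self.n2_base if self.n2_base is not None else 7 + p

        def run_phase2(theta, D_cur, gain, tag):
            for sub in range(self.subphases):
                a = gain / (2 ** sub)
                iters = n2_base * (2 ** sub)
                collected = np.zeros_like(theta)
                for _ in range(iters):
                    seeds = rng.integers(0, MAX_SEED, size=self._n_periods)
                    S, _ = self._sim(theta, seeds)
                    step = a * self._solve(D_cur, S - S_obs)
                    step = np.clip(step, -self.max_step, self.max_step)
                    theta = self._clip_theta(theta - step)
                    collected += theta
                theta = self._clip_theta(collected / iters)
                log.append({"phase": 2, "run": tag, "subphase": sub + 1,
                            "gain": a, "iterations": iters,
                            "theta": theta.tolist()})
            return theta

        theta = run_phase2(theta, D_cur, self.gain, 1)

        # ---- phase 3, with damped Newton polish while off target
        converged = False
        rescued = False
        rate_1d_solves = {m: 0 for m in range(self._n_periods)}
        for attempt in range(self.max_restarts + 1):
            archive = np.zeros((self.n3, p))
            period_stats = np.zeros(
                (self.n3, self._n_periods, len(self._codes))
            )
            for r in range(self.n3):
                seeds = rng.integers(0, MAX_SEED, size=self._n_periods)
                archive[r], period_stats[r] = self._sim(theta, seeds)
            tratios, max_ratio = convergence_diagnostics(archive, S_obs)
            log.append({"phase": 3, "attempt": attempt + 1, "n3": self.n3,
                        "max_conv_ratio": float(max_ratio)})
            converged = bool(
                np.all(np.abs(tratios) < self.t_ratio_threshold)
                and max_ratio < self.conv_ratio_threshold
            )
            if converged or attempt == self.max_restarts:
                # two-stage derivative for standard errors: a provisional
                # forward-difference D yields provisional SEs; the final
                # central-difference secant then spans the CI scale itself
                D_prov, _ = self._estimate_D(theta, rng,
                                             max(20, self.n_deriv // 3))
                Sigma_prov = np.atleast_2d(np.cov(archive, rowvar=False))
                Dp_inv = np.linalg.pinv(D_prov, rcond=1e-8)
                se_prov = np.sqrt(np.clip(
                    np.diag(Dp_inv @ Sigma_prov @ Dp_inv.T), 0.0, None))
                scale = np.maximum(1.0, np.abs(theta))
                widths = np.clip(np.maximum(4.0 * self.fd_delta * scale,
                                            3.0 * se_prov),
                                 None, 3.0 * scale)
                D_hat, _ = self._estimate_D(theta, rng, self.n_deriv,
                                            central=True, widths=widths)
                break
            if np.abs(tratios).max() > 0.75 and not rescued:
                # phase 2 ran away (e.g. into a saturated network where all
                # derivatives vanish): restart it from scratch, gentler
                rescued = True
                theta = theta0
                D_cur, _ = self._estimate_D(theta0, rng, self.n1, guard=True)
                theta = run_phase2(theta, D_cur, self.gain / 2, 2)
                continue
            # rate moments are separable and monotone in their own rate:
            # a stuck one is repaired by direct 1-D search (a joint step
            # chasing an unsolvable rate deviation would contaminate the
            # evaluation parameters instead); a rate already pinned at the
            # cap has an unattainable moment and is left to the diagnostics
            stuck_rates = [
                mth for mth in range(self._n_periods)
                if np.abs(tratios[mth]) > 0.06 and theta[mth] < 55.0
            ]
            if attempt >= 1 and stuck_rates:
                for mth in stuck_rates:
                    theta = self._solve_rate_1d(mth, theta, S_obs[mth], rng)
                    rate_1d_solves[mth] += 1
                log.append({"phase": 3, "attempt": attempt + 1,
                            "rate_1d_solve": stuck_rates,
                            "theta": theta.tolist()})
                continue
            # the archive mean locates the remaining deviation precisely;
            # a damped Newton step removes it, then diagnostics re-run.
            # A rate pinned at the cap has an unattainable moment (observed
            # distance above the saturation plateau): acknowledge it and
            # keep its deviation from dragging the other parameters.
            dev = archive.mean(axis=0) - S_obs
            for mth in range(self._n_periods):
                if theta[mth] >= 55.0:
                    dev[mth] = 0.0
            D_quick, _ = self._estimate_D(theta, rng,
                                          max(20, self.n_deriv // 3))
            # small steps first; escalate only if they prove insufficient
            if attempt < 4:
                lim = np.full_like(theta, self.max_step)
            else:
                lim = self.max_step * np.maximum(1.0, 0.5 * np.abs(theta))
            step = np.clip(0.7 * np.linalg.pinv(D_quick, rcond=1e-6) @ dev,
                           -lim, lim)
            theta = self._clip_theta(theta - step)
        if not converged:
            warnings.warn(
                f"estimation did not reach the convergence thresholds after "
                f"{self.max_restarts + 1} attempts "
                f"(max convergence ratio {max_ratio:.3f})"
            )

        Sigma = np.atleast_2d(np.cov(archive, rowvar=False))
        try:
            D_inv = np.linalg.inv(D_hat)
        except np.linalg.LinAlgError:
            warnings.warn("singular derivative matrix at the estimate; pseudo-inverse")
            D_inv = np.linalg.pinv(D_hat)
        cov_theta = D_inv @ Sigma @ D_inv.T
        se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))

        obs_period = self._observed_period_stats(panel, spec)
        self.result_ = FitResult(
            names=self.names_, theta=theta, se=se, tratios=tratios,
            max_conv_ratio=max_ratio, target=S_obs, archive=archive,
            period_stats=period_stats, obs_period_stats=obs_period,
            D=D_hat, Sigma=Sigma, cov_params=cov_theta, spec=spec,
            n_periods=self._n_periods, converged=converged,
            iteration_log=log, seed=self.seed,
        )
        self.theta_ = theta
        self.rates_ = self.result_.rates
        self.alpha_ = self.result_.alpha
        self.coef_ = self.result_.beta
        self.se_ = se
        self.tratios_ = tratios
        self.max_conv_ratio_ = max_ratio
        self.cov_params_ = cov_theta
        self.converged_ = converged
        return self

    def _initial_theta(self, panel, spec, beta_init, S_obs):
        n_act = np.array([w.n_active for w in panel.waves], dtype=float)
        dens = np.array(
            [w.n_ties / (na * (na - 1)) if na > 1 else 0.0
             for w, na in zip(panel.waves, n_act)]
        )
        hamming = S_obs[: self._n_periods]
        rates0 = np.clip(2.0 * hamming / n_act[1:], 0.5, 50.0)
        beta0 = beta_init.copy()
        if not np.any(beta0):
            d = float(np.clip(dens.mean(), 1e-3, 1 - 1e-3))
            for k, e in enumerate(spec.evaluation_effects):
                if e.name == "outdegree":
                    beta0[k] = np.log(d / (1 - d))
        parts = [rates0]
        if self._has_rate_out:
            a0 = spec.rate_outdegree.parameter
            parts.append([a0])
        parts.append(beta0)
        return self._clip_theta(np.concatenate(parts))

    def _observed_period_stats(self, panel, spec):
        out = np.zeros((self._n_periods, len(self._codes)))
        for m, ctx in enumerate(self._contexts):
            b = panel.waves[m + 1]
            xb = b.adj.astype(float) * (b.active[:, None] & b.active[None, :])
            out[m] = total_statistics_codes(xb, self._codes, ctx.covmats)
        return out

    # -- simulation at the fitted parameters --------------------------------

    def simulate(self, n_sim: int, seed: int | None = None,
                 theta: np.ndarray | None = None) -> list[list[np.ndarray]]:
        """Simulate ``n_sim`` panels (end waves per period) at the estimate."""
        theta = self.theta_ if theta is None else np.asarray(theta, float)
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        panels = []
        for _ in range(n_sim):
            seeds = rng.integers(0, MAX_SEED, size=self._n_periods)
            _, _, ends = simulate_panel_statistics(
                self._contexts, self._codes, theta, self._has_rate_out,
                seeds, self.engine, self.spec, return_end_states=True,
            )
            panels.append(ends)
        return panels


def estimate_mom(panel: WavePanel, spec: ModelSpec, **options) -> FitResult:
    """Functional wrapper over :class:`SAOM`."""
    model = SAOM(spec=spec, **options)
    model.fit(panel)
    return model.result_


def collinearity_check(fit: FitResult, threshold: float = 0.9
                       ) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Parameter correlation matrix from cov(theta); |r| > threshold flagged."""
    cov = fit.cov_params
    sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    flags = [
        (fit.names[i], fit.names[j], float(corr[i, j]))
        for i in range(len(fit.names)) for j in range(i + 1, len(fit.names))
        if abs(corr[i, j]) > threshold
    ]
    return corr, flags


def time_heterogeneity_test(fit: FitResult) -> tuple[float, int, float]:
    """Score-type joint test of parameter stability across periods.

    For every evaluation effect the per-period deviations of observed from
    mean-simulated statistics are contrasted against their across-period
    mean (the pooled fit absorbs exactly that combination), and the stacked
    contrasts are standardized by the phase-3 covariance, giving a
    chi-square with df = n_effects * (n_periods - 1).
    """
    n_periods, K = fit.obs_period_stats.shape
    if n_periods < 2:
        raise EstimationError("time heterogeneity needs at least three waves")
    sims = fit.period_stats.reshape(fit.period_stats.shape[0], -1)
    obs = fit.obs_period_stats.reshape(-1)
    # contrast matrix: per effect, deviations from the across-period mean
    I = np.eye(n_periods) - np.ones((n_periods, n_periods)) / n_periods
    C = np.zeros(((n_periods - 1) * K, n_periods * K))
    row = 0
    for k in range(K):
        idx = np.arange(n_periods) * K + k
        for m in range(n_periods - 1):
            C[row, idx] = I[m]
            row += 1
    d = C @ (obs - sims.mean(axis=0))
    V = C @ np.cov(sims, rowvar=False) @ C.T * (1.0 + 1.0 / sims.shape[0])
    Vp = np.linalg.pinv(V, rcond=1e-10)
    chi2 = float(d @ Vp @ d)
    df = K * (n_periods - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
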