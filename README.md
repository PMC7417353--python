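# groomnet

Dynamic social-network analysis of dairy-cow allogrooming: weekly directed
contact networks built from behavioural event logs, descriptive network
statistics, dominance-rank indices, and a from-scratch stochastic
actor-oriented model (SAOM) engine — a continuous-time micro-step
simulator, Method-of-Moments estimation by Robbins–Monro stochastic
approximation, convergence diagnostics, goodness of fit, and a
time-heterogeneity test.

The package is written for behavioural ecologists and veterinary
epidemiologists who observe directed interactions (here: social licking
and headbutting in a herd of dairy cows regrouped after calving) and want
to model how the contact network changes week to week as a function of
structural processes and individual attributes.

## The model

Weekly binary directed networks `x(t_1), …, x(t_W)` (tie i→j iff cow i
groomed cow j that week) evolve between waves by a continuous-time Markov
chain of *micro-steps*. Actor i receives change opportunities at rate

    λ_i = ρ_m · exp(α · outdeg_i) · presence_i

and at each opportunity toggles one outgoing tie (or keeps the network)
with multinomial-logit probability ∝ exp(f_i(x′)), where

    f_i(x) = Σ_k β_k s_ik(x)

combines per-actor statistics: outdegree, reciprocity, transitive
triplets, three-cycles, transitive reciprocated triplets,
indegree/outdegree popularity, outdegree activity, out–out assortativity,
and ego/alter/homophily effects of covariates (age, social rank from the
Lamprecht dominance index, entry status, oestrus). Joiners and leavers
are handled by composition change. Parameters (β, α, per-period rates
ρ_m) are estimated by the Method of Moments: simulated statistics are
matched to their observed targets by three-phase Robbins–Monro stochastic
approximation, with convergence declared when all t-ratios for deviations
from targets are below 0.1 and the overall maximum convergence ratio is
below 0.25. See `docs/methods.md` for the full account.

## Worked example

Generate a small synthetic herd with known dynamics, fit the model, and
check goodness of fit — from a single YAML config:

```yaml
# study.yaml
seed: 11
synth:
  n_actors: 20
  n_waves: 5
  entry_schedule: [16, 4, 0, 0, 0]
  beta_true: {outdegree: -1.6, reciprocity: 1.1}
  rate_true: 4.0
  initial_density: 0.22
model:
  effects: {outdegree: 0.0, reciprocity: 0.0}
estimation:
  phase3: 500
```

```
$ groomnet run --config study.yaml --out demo --nsim 100
```

`demo/summary.csv` holds the per-wave descriptives (16 cows join wave 1,
4 more in wave 2; density, directed diameter, average path length,
reciprocity per wave):

```
week,n_nodes,n_ties,density,diameter,average_path_length,reciprocity
1,16,50,0.21,6.0,2.49,0.24
2,20,39,0.1,8.0,3.12,0.36
...
```

`demo/fit.json` carries the estimates with standard errors — the
generator's truth was outdegree −1.6, reciprocity 1.1, rate 4.0:

```
rate_period_1       5.449 (1.622)
rate_period_2       3.131 (0.943)
rate_period_3       6.089 (3.290)
rate_period_4       3.974 (1.518)
outdegree          -1.586 (0.104)
reciprocity         1.264 (0.220)
max conv ratio 0.086   converged True
```

Both behavioural effects are recovered within one standard error and the
fit satisfies the convergence thresholds (all |t| < 0.1, max ratio
0.086 < 0.25). `demo/gof.json` shows no auxiliary statistic rejecting the
model (outdegree distribution p = 0.57, indegree p = 0.49, triad census
p = 0.99, geodesics p = 0.82), and the time-heterogeneity test in
`demo/run.json` is non-significant (χ² = 1.73, df = 6, p = 0.94) — as it
should be, since the generating parameters were constant across periods.

Other subcommands: `groomnet synth` (write a synthetic study to disk:
event logs, actor table, wave matrices, GraphML), `groomnet describe`,
`groomnet rank` (weekly dominance indices + stability ICC),
`groomnet fit`, `groomnet validate`.

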