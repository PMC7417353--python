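# Methods

`groomnet` analyses the week-to-week dynamics of directed allogrooming
(social licking) networks in a dairy herd: who grooms whom, how those
choices depend on the current network (reciprocation, triadic closure,
popularity), on individual attributes (age, social rank, days since
joining the group, oestrus), and how confident we can be in the fitted
parameters. This note documents the model, the estimation machinery, the
synthetic herd generator, and the numerical choices.

## Data model

The observational unit is a dyadic behavioural event: actor, recipient,
behaviour (`groom` or `headbutt`), timestamp, session. Events are valid
only inside the declared observation calendar — five consecutive days per
week, two daily blocks (09:00–12:00, 18:00–21:00) of four 30-minute
continuous observation periods separated by 20-minute breaks. Weeks are
calendar-defined from a configured study start.

A grooming *bout* that pauses for at most 20 s and is not interrupted by
another behaviour of the same actor counts as one event; longer pauses or
interruptions split it (`merge_split_bouts`).

Weekly directed count matrices (weight = number of i→j grooming events)
are binarized at weight ≥ 1: two cows are connected in a week iff one
groomed the other at least once that week. The wording of the operational
definition ("at any point in the week") fixes the threshold at ≥ 1;
strictly "greater than one" would contradict it. Normalized weighted
out/in-degrees divide each cow's strength by `(n_active − 1) × max dyadic
weight` in that wave (configurable to plain `n_active − 1` for binary
degree), guaranteeing values in [0, 1] across networks of different
sizes.

Group composition changes are first-class: each actor has an entry week
(and optionally a leave week); waves record an active mask, and dyads are
only ever formed between jointly active actors. Actors observed for part
of a week can carry a fractional presence that scales their rate of
activity in the dynamic model.

## Dominance

Weekly headbutt count matrices give per-dyad dominance: the cow delivering
more headbutts in a dyad is dominant. The dominance index (DI) of a cow is
(number of her subordinates) / (number of animals she interacted with);
rank classes are low (DI < 0.40), medium (0.40 ≤ DI < 0.60), high
(DI ≥ 0.60). Dyads with equal counts are *tied*: they count toward the
partner total but contribute no subordinates (a `half_credit` policy
awarding 0.5 is available — the conservative default is the weaker claim).

Stability of the DI across weeks, and inter-observer reliability, use
ICC(A,k): two-way model, absolute agreement, mean over raters. The
computation is delegated to `pingouin.intraclass_corr` (ICC(A,k) row with
its F test and 95% CI); the test suite checks it against a longhand
two-way ANOVA decomposition to 1e-10. The social-rank covariate passed to
the dynamic model is the across-week mean DI per cow (the weekly index is
stable enough to be treated as constant); the 3-class code is kept for the
same-rank homophily and same-rank × reciprocity effects.

## The dynamic network model

Between weekly observations the network evolves in continuous time: actor
i receives change opportunities with intensity

    lambda_i = rho_m * exp(alpha * outdeg_i) * presence_i,

where `rho_m` is the period-m rate (expected opportunities per actor per
week), and `alpha` (the *outdegree effect on rate*) lets active groomers
change ties faster. At an opportunity the actor chooses among toggling one
outgoing tie or leaving the network unchanged, with multinomial-logit
probabilities proportional to `exp(f_i(x'))` over candidate networks x',
where the evaluation function

    f_i(x) = sum_k beta_k * s_ik(x)

is a linear combination of per-actor statistics: outdegree, reciprocity,
transitive triplets, three-cycles, transitive reciprocated triplets,
indegree popularity, outdegree popularity (sqrt), outdegree activity
(sqrt), out–out assortativity, and covariate ego / alter / same /
similarity effects plus the same-rank × reciprocity interaction. Formulas
are documented in `groomnet.effects`. Joiners activate with empty tie
profiles at the start of their entry period; leavers are frozen out of the
choice set and their ties removed from the statistics at departure.

Covariates are centered over the actors ever present; similarity scores
`1 − |v_i − v_j| / range(v)` are centered by the grand mean similarity.
Changing covariates (entry status, oestrus) take the value in force during
a period: the "newly entered" indicator of period m marks cows whose entry
wave is m+1, i.e. cows integrating into the group during that period.

Two implementations coexist deliberately: a readable numpy `micro_step`
(used for probability-level tests) and a numba-compiled period kernel for
the millions of micro-steps behind estimation and goodness of fit. Both
compute tie contributions in O(n) per candidate from shared aggregates,
and the suite cross-checks them distributionally. The kernel's limiting
behaviour is verified against an exactly solved 32-state Markov chain for
the outdegree-only model.

## Method-of-Moments estimation

Each free parameter is paired with a target statistic computed on the
observed waves: per-period Hamming distances over jointly active dyads
(for the rates), the cross-moment `sum_m sum_i outdeg_i(x_m) * (#row-i
changes)` (for the rate-outdegree parameter), and per-effect statistic
totals over the later waves (for the evaluation parameters). Simulated
counterparts are generated by running each period forward from the
*observed* previous wave, and the moment equations
`E_theta[S] = S_obs` are solved by Robbins–Monro stochastic approximation:

- **Phase 1** (default 50 iterations): the derivative matrix D is
  estimated by forward finite differences with common random numbers,
  after which one Newton step is taken. FD steps are scale-aware
  (`0.1 × max(1, |theta_k|)`); the own-rate diagonal entries, positive by
  construction, are floored at a small guard *for the solver only*.
- **Phase 2**: four subphases of diminishing gain (0.2, halved per
  subphase) update `theta ← theta − a·D⁻¹·(S_sim − S_obs)` with
  componentwise step clipping; the subphase average becomes the next
  starting point. Rates are kept in [0.05, 60] and evaluation parameters
  in [−8, 8]; a runaway into a saturated network triggers one clean
  restart at half gain.
- **Phase 3** (default 1000 simulations; 4000 matches the reported
  protocol and 500 is used in the scaled validation experiments): the
  simulation archive yields per-parameter convergence t-ratios
  `(mean_sim − obs)/sd_sim`, the overall maximum convergence ratio
  `sqrt(dbar' Sigma⁻¹ dbar)` (the largest t-ratio over all linear
  combinations), and standard errors `cov(theta) = D⁻¹ Sigma D⁻ᵀ`. While
  the thresholds (|t| < 0.1, max ratio < 0.25) are unmet, damped Newton
  polish steps driven by the archive mean re-center the estimate; a rate
  moment stuck near saturation is repaired by a bracketed one-dimensional
  solve of its own period.

Estimation is *unconditional*: rates are free parameters rather than
conditioned on observed change counts. This exposes a known fragility —
the expected Hamming distance saturates as `rho → ∞` at the distance
between the start wave and an independent stationary draw, so an
upper-tail observed distance can make a rate moment unsolvable. For the
standard errors this is handled honestly rather than hidden: the final
derivative is a two-stage secant (a provisional SE sets the secant width,
so the slope is measured over the confidence-interval scale; rate secants
point upward because the moment curve is concave), which lets the SE of a
near-saturated rate inflate as it should. A genuinely unsolvable moment
leaves the fit flagged non-converged.

Initial values: rates from observed Hamming distances (`2H/n`), the
outdegree parameter from the logit of mean observed density, all other
parameters 0.

`SAOM` is a scikit-learn-style estimator (`fit(panel)` with
trailing-underscore fitted attributes and `get_params`/`set_params`);
`estimate_mom` is the equivalent function.

## Goodness of fit, heterogeneity, selection

GOF simulates panels at the estimate and compares four auxiliary
statistics pooled over the later waves: cumulative out/indegree counts at
0..8, the 16-class directed triad census, and geodesic pair counts at
distances 1..5. Discrepancy is a Mahalanobis distance in the simulated
distribution (degenerate components dropped, pseudo-inverse); the
Monte-Carlo p is the share of simulations at least as discrepant as the
observed panel. Simulated distances are computed leave-one-out so that a
panel that *is* a model draw yields a uniform p — without this, in-sample
distances are deflated and the triad census over-rejects.

The time-heterogeneity test is score-type: per-period deviations of
observed from mean-simulated evaluation statistics are contrasted against
their across-period mean (the pooled fit absorbs exactly that
combination), standardized by the phase-3 covariance (inflated by
1 + 1/n3), and referred to chi-square with df = (#effects)·(W−2). Exact
per-period dummy re-estimation is out of scope; the score form is
calibrated on time-constant synthetic panels in the test suite.

Forward selection adds candidate effects one at a time and retains a
candidate iff the extended fit converges, `|estimate/SE| ≥ 1.96`, and no
auxiliary GOF p-value drops below 0.05 (below the threshold *and* worse
than the current model's p — a candidate is not blamed for an already-low
p). Every decision is recorded in a ledger. Collinearity is screened via
the parameter correlation matrix from `cov(theta)`, flagging |r| > 0.9.

## Synthetic herds

The generator reproduces the study conditions: 38 cows entering over six
weekly waves (25, +7, +1, +5, 0, 0); ages from a moment-matched truncated
normal (mean 4.5 y, SD 1.9 y, range 2.5–10.2 y — the underlying normal is
solved so the *truncated* moments hit the targets); weekly oestrus as
independent Bernoulli(0.15) per present cow-week (no incidence is
reported; the default simply guarantees oestrus cows exist in most weeks);
a latent dominance scale equal to standardized age plus Gaussian noise
(SD 0.5), reflecting that rank in such herds tracks seniority, with
logistic headbutt-direction steepness kappa = 3 and Poisson(0.5) headbutts
per co-present dyad-week; and grooming bouts of 1 + Poisson(0.1) events
per realized tie-week, placed uniformly inside the observation calendar
(the study's ~1,329 logged events alongside weekly tie counts summing to
1,329 imply close to one bout per realized tie-week; default herds log
~1,300–1,600 events). The guaranteed event per tie makes binarization
invertible: rebuilding the panel from the generated event log reproduces
the binary waves exactly.

Ground-truth dynamics default to reciprocity 1.118 and transitive triplets
0.133 — the reported magnitudes — with rate 4.0 opportunities per cow-week
and wave-1 density 0.25. The outdegree intercept is −1.35 rather than the
reported −1.965: under the micro-step model the intercept controls the
chain's quasi-stationary density, and −1.965 (a value conditional on the
full covariate model and its estimation context) drives chained
simulations to densities near 0.05, far below the observed 0.16–0.26
band. With −1.35 all waves stay within 0.14–0.27 across seeds. The
often-quoted `sigma(beta)` stationary density is *not* exact for this
chain — option-set normalizers depend on degree — which the suite
demonstrates against an exactly solved small chain.

What the generator does not emulate: spatial structure of the paddock,
calving/management events, diurnal activity rhythms, observer error, and
any dependence of grooming on milk yield or health. Passing tests
therefore certify the statistical machinery (construction, estimation,
diagnostics) under the model's own assumptions — not the biological
fidelity of any particular fitted coefficient on real data.

## Validation experiments and problem sizes

`groomnet.experiments` packages the simulation studies run by the suite
and by `scripts/acceptance.py`:

- **Parameter recovery**: 20 panels (30 actors, 6 waves) generated at
  rates 5.0, outdegree −2.0, reciprocity 1.2 and refit with phase-3 = 500;
  scored on all parameters lying within 3 estimated SEs and on the
  convergence thresholds.
- **GOF self-consistency**: 50 pseudo-observed panels drawn from a fitted
  model, each scored against 150 comparison simulations per auxiliary.
- **Heterogeneity calibration**: 50 time-constant panels (size) and 50
  with reciprocity doubled in the last period (power).

These sizes keep the full suite comfortably reproducible on a single CPU
while leaving the Monte-Carlo error well inside the tolerance of each
check.

## Known limitations

- Rate moments near saturation (networks close to their quasi-stationary
  regime at high rates) are weakly identified; estimates can legitimately
  pin at the cap with inflated SEs, and such fits are flagged rather than
  repaired.
- The score-type heterogeneity test is conservative when per-period rates
  absorb part of the between-period variation.
- Maximum-likelihood and Bayesian estimation, co-evolution with
  behavioural variables, and weighted-tie dynamics are out of scope.
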