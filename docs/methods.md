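# Methods

`rsmeta` estimates a *response surface* of study results for trials of
multicomponent ("complex") interventions: a model mapping component
combinations — and, in its extensions, study-level characteristics — to the
expected posttreatment outcome mean. Its goal is prediction and summary, not
causal effect estimation: the coefficients are reported as mean differences
associated with a component's presence, with no causal claim.

## The arm-based model

Let `Y_ij` be the posttreatment mean of arm `j` in study `i`, with sampling
variance `theta_ij^2` (from the reported standard error, or `sd^2/n`):

```
Y_ij   ~ N(mu_ij, theta_ij^2)
mu_ij  = b_0i + sum_{k=1..m} b_ki X_ijk
b_ki   ~ N(beta_k, tau_k^2)          (independent across k)
b_0i   ~ N(beta_0, tau_0^2)
```

`X_ijk` is the 0/1 indicator of component `k` in the arm; an all-zero row is
the no-intervention arm and `b_0i` is the study's baseline posttreatment
level. Every arm of every study contributes; multi-arm trials need not be
reduced to two arms. Additivity is the identifying assumption that lets the
`m`-parameter surface extrapolate across the `2^m - 1` combinations, of which
real collections observe only a few percent.

Exchangeable *study-level* coefficients (rather than fixed common effects)
absorb between-study heterogeneity separately per component. Their mutual
independence (diagonal covariance) is an assumption, reasonable when
components operate at different levels of the care system; a correlated
version is out of scope.

### Priors

Normal priors are parameterised by mean and **variance** throughout:

| parameter | prior | default | notes |
|---|---|---|---|
| `beta_0` | N(8, 100) | SD 10 | minimally informative on a percent-scale outcome centred near 8 |
| `beta_k` | N(0, 4) | SD 2 | component mean differences |
| `tau_0, tau_k` | U(0, 2) | — | between-study SDs; upper bound generous for %-scale outcomes |
| `gamma_l` | N(0, 2) | | product-term (interaction) coefficients |
| `phi, psi_k` | N(0, 4) | | modifier main effect and products |
| imputed ICC | U(0, 0.1) | | brackets typical primary-care ICC values (0.027, 0.07); configurable |
| imputed log theta | N(mu, s^2) | empirical | hyperparameters from arms with observed dispersion |

The variance reading of `N(a, b)` is a deliberate choice: it makes N(8, 100)
genuinely weak (SD 10 on a quantity near 8), whereas a precision reading
would make it absurdly tight. All of these are `PriorSpec` fields.

### Dispersion resolution and cluster designs

Before fitting, each arm's dispersion is resolved in this order: reported
`se`; else `sd/sqrt(n)`; else flagged for imputation. Cluster-randomised arms
whose reported variances ignore clustering are inflated by the design effect
`DEFF = 1 + (mbar - 1) * ICC` (`mbar` = average cluster size): deterministically
when the ICC is observed, or inside the sampler when it must be imputed.
Missing sampling SDs get a log-normal prior with empirical-Bayes
hyperparameters (mean and SD of log observed standard errors) — a pragmatic
way of sharing dispersion information across arms; both imputed quantities
are sampled jointly with the model so their uncertainty propagates. The
conventional comparator (below) instead uses the fixed imputations sd = 2.22
and ICC = 0.027, reproducing standard practice.

### Sampling scheme

Blocked Gibbs with exact conditional draws wherever they exist:

- **Population and study coefficients, jointly.** `(beta_0, beta)` is drawn
  from its conditional with the study effects integrated out — a GLS normal
  using the per-study marginal covariance `Theta_i + D_i diag(tau^2) D_i'`
  (small per-study matrices, solved batched) — followed by the exact
  multivariate-normal draw of each study's `(b_0i, b_ki)`. Drawing the block
  jointly avoids the severe slowdown of centred Gibbs when any `tau`
  approaches zero (the regime the conjugate-oracle test exercises).
- **Between-study SDs.** Under U(0, upper), `tau^2` has an exact truncated
  inverse-gamma conditional; it is drawn by an unconditional gamma draw with
  CDF-inversion fallback for truncation violations (the mixture is exactly
  the truncated law). This replaces generic slice sampling: simpler, exact,
  vectorised.
- **Fixed extension coefficients** (`gamma`, `phi`, `psi`): one joint
  multivariate-normal conditional draw.
- **Imputed log dispersions:** random-walk Metropolis on the log scale
  (fixed step 0.4, a reasonable scale for log-SEs of percent-scale arms).
- **Imputed ICCs:** independence proposals from the U(0, 0.1) prior.

Chains are seeded from a `SeedSequence` spawn of the run seed, making every
fit bit-reproducible. Default run lengths are 100,000 burn-in + 100,000 kept
iterations (long, conservative); all experiments and the test suite use
2,000/5,000 with two chains, which the Brooks–Gelman–Rubin diagnostic shows
is adequate for the population coefficients at these problem sizes. The
slowest-mixing quantities are between-study SDs whose posteriors sit near
zero; their PSRF can exceed 1.1 at short run lengths while the coefficient
inference is unaffected — the run-report convention is to state the fraction
of parameters with upper PSRF bound below 1.1 and 1.2.

### Convergence diagnostic

`gelman_rubin` implements the Brooks–Gelman *corrected* potential scale
reduction factor with its upper 97.5% bound (the `(d+3)/(d+1)`
degrees-of-freedom correction and the F-quantile bound), matching R `coda`'s
`gelman.diag` to 1e-6 in tests.

## Extensions

- **Interaction (nonadditivity):** one fit per focal component `r`, adding
  `gamma_l X_r X_l` for all partners `l` (so `m - 1` extra population-level
  parameters; 8 at m = 9). A single saturated all-pairs model would be
  weakly identified in sparse component data; the one-focal-at-a-time series
  keeps each fit identifiable. `gamma_l` is population-level, not
  study-random: a random version would be essentially unidentified when most
  pairs co-occur in a handful of studies.
- **Effect modification:** adds `phi Z + sum_k psi_k Z X_k` for a
  study-level covariate `Z` — binary at a cutpoint (default 8.0, the
  conventional threshold separating controlled from uncontrolled baseline
  HbA1c; boundary values code as "uncontrolled"), or mean-centered
  continuous. `m + 1` extra parameters (10 at m = 9). The contrast table for
  the binary coding reports, per component and per draw: uncontrolled
  baseline + strategy (`beta_0 + beta_k + phi + psi_k`), the difference
  under uncontrolled baseline (`beta_k + psi_k`), controlled + strategy
  (`beta_0 + beta_k`), the controlled difference (`beta_k`), and the
  difference between differences (`-psi_k`). All contrasts are computed per
  draw and then summarised — never sums of medians.
- **Difference (contrast-level) model:** analyses `Y_ij - Y_i,ref` with the
  reference arm chosen as the study's fewest-component arm (ties: lowest arm
  label). Study intercepts cancel, as do coefficients of components present
  in both arms of a contrast. Contrasts sharing a reference arm are
  correlated with covariance `theta_ref^2`; the likelihood uses the full
  per-study contrast covariance rather than ignoring it. This variant
  requires observed (or derivable) dispersions for every arm — the
  imputation machinery is implemented for the arm-based models only.

The arm-based and difference-based fits agree closely on additive synthetic
data (maximum posterior-median gap ~0.01 outcome units at 100 studies) but
are *not* the same posterior: the difference model discards level
information and estimates the heterogeneity SDs from contrasts only, so a
small systematic gap persists no matter how long the chains run.

## Prediction and ranking

For a combination `x_new`, the **posterior** surface value is
`beta_0 + sum beta_k x_k` per draw. The **predictive** value draws fresh
study-level coefficients `b_k,new ~ N(beta_k, tau_k^2)` for `k = 0..m` (one
draw per retained posterior draw), and optionally adds sampling noise
`N(0, theta_new^2)` for a planned study. Contrasts against the all-zero
combination share the intercept draw, so the null contrast is exactly zero
and the predictive contrast reduces to `sum_k b_k,new x_k`. Predictive
intervals are therefore wider than posterior intervals whenever any `tau_k`
is positive.

Ranking uses the population `beta_k` draws ("magnitude of the mean
differences"); lower is better by default (a reduction-is-benefit outcome),
with the direction recorded in every report. Ties are broken by a seeded
random permutation, which keeps the rank matrix exactly doubly stochastic.

## Evaluation

- **Mixed posterior predictive checks** replicate each arm as from a *new*
  study — fresh `b_0,new`, `b_k,new` from the population distributions, plus
  the arm's (possibly imputed) sampling noise — and report the one-sided
  probability P(Y_rep <= y_obs), ties counted as half. Densities are grouped
  by component presence (arms containing the component).

  A property worth knowing: because the `tau_k` are freely estimated up to
  their prior bound, misfit that is constant within (study, component
  pattern) is largely *variance-matched* into the heterogeneity SDs, which
  widens the replicate distribution and typically moves the probabilities
  toward the centre, not the extremes. The excess-mass-at-extremes signature
  of an omitted interaction appears when the nonadditive signal lives in
  within-study contrasts that the study-level effects cannot absorb —
  factorial-style trials with small true heterogeneity. The misspecification
  experiments use exactly that design.
- **DIC** = mean deviance + pD, with deviance = -2 x arm log-likelihood and
  the plug-in at the posterior mean of the arm means and effective variances
  (the focused, prediction-oriented parameterisation; this is stated in
  reports because pD depends on the focus).
- **Prior sensitivity** refits under alternative `PriorSpec`s with a shared
  seed and reports side-by-side medians/CrIs, the maximum median shift, and
  parameters whose CrI excludes zero under some specs but not others.

## The synthetic-data generator

`SimConfig` defaults describe the reference scenario the experiments run
under: 100 studies of 2–3 arms (90/10), 9 components with declining
prevalence in active arms (0.60 down to 0.12, producing the heavy
combination sparsity typical of component taxonomies — most observed
combinations are rare, many unique), `beta_0 = 8`, `tau_0 = 0.4`, component
effects from -0.36 to +0.03 with `tau_k = 0.15`, participant-level SD 1.34,
arm sizes 30–400, 85% of studies carrying a no-intervention arm, 25%
cluster-randomised (cluster sizes 5–60, ICC 0.03) with *unadjusted* reported
standard errors and design-effect-inflated outcome truth, 20% missing
dispersions and 50% missing ICCs. These magnitudes mirror a large
quality-improvement review of diabetes trials (percent-scale HbA1c outcome).

What the generator does **not** emulate: non-normal outcome or effect
distributions, selective reporting or publication bias, correlated component
coefficients, participant-level microdata (cluster arms are simulated at the
arm-mean level with inflated variance — sufficient for everything the model
sees), and measurement error in the component coding itself. Passing tests
therefore certify the estimation machinery under the model's own
assumptions, not robustness to violations of them.

Two switches exist for designed experiments: `co_occur` forces component
co-assignment (to demonstrate the confounding that biases the conventional
per-component comparator while leaving the surface model consistent), and
`arm_design` fixes every study's arm layout (e.g. a 2x2 factorial) for
misspecification experiments. Reported participant SDs are exact
(`sigma_within`), so resolved dispersions are treated as known — matching
the model's own assumption.

## Numerical choices and edge cases

- Truncated inverse-gamma draws guard `S_k` away from zero and clamp the
  inversion quantile below 1 - 1e-16; `tau` is capped at the prior bound.
- Pooling of rare components uses arm-prevalence strictly below the
  threshold; pooling is idempotent at a fixed threshold, and pooling
  everything is an error (the model would contain only the pooled
  category).
- Extreme-arm selection breaks intensity ties by lowest arm label (chosen
  for determinism under row permutation); the conventional comparator
  breaks a two-arm tie by taking the higher arm label as experimental.
- Components never present in any arm (or, in the difference model, never
  differing within any study) are refused rather than silently returning
  their prior.
- `se` wins over `sd/sqrt(n)` when both are present; a disagreement beyond
  25% logs a consistency warning.
- Problem sizes in the experiments (e.g. 50 recovery replicates at 100
  studies with 2,000/5,000 MCMC, 20-study conjugate checks, 80-study
  PPC designs) were chosen as the smallest collections at which the checked
  properties are stable, so the full suite runs comfortably on one CPU.

## Known limitations

- No discrete-outcome (e.g. binomial) likelihood; continuous outcome means
  only.
- No correlated random-coefficient structures; no three-way interactions;
  no multiple simultaneous modifiers.
- The modifier covariate must be observed for every study (no covariate
  imputation).
- The mixed PPC has limited power against misspecification that the
  heterogeneity SDs can absorb (see above).
- DIC is reported, never used for automated model selection.
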