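# Methods

## The problem

When individual-level data are pooled over several studies or centres
("clusters"), some covariates are often *systematically* missing — never
measured in one or more clusters — on top of the usual *sporadically*
missing values within clusters.  Discarding the affected clusters (the
naive analysis) wastes data; discarding the variables weakens the model.
Multilevel multiple-imputation methods can fill these gaps, but when the
analysis and imputation models need a random effect for every variable and
the number of clusters is small, two-step classical approaches become
unstable.

`bayimp` implements the joint alternative: the imputation model and the
analysis of interest are fitted together in a single Bayesian hierarchical
MCMC.  Missing cells are sampled as latent quantities inside the chain, so
imputation uncertainty propagates into the analysis posterior exactly,
without ever materializing multiple imputed datasets.

## Model

For subject $i$ in cluster $j$, with outcome $y_{ij}$ and covariates
$x_{kij}$:

**Analysis model** (continuous outcome)

$$y_{ij} \sim N(\alpha_j + \textstyle\sum_k \beta_{kj} x_{kij},\ \sigma_y^2),
\qquad \alpha_j \sim N(\alpha_0, \tau_\alpha^2),\qquad
\beta_{kj} \sim N(\beta_k, \tau_k^2)$$

for covariates declared *random*; a *fixed* covariate has $\beta_{kj}
\equiv \beta_k$.  A binary outcome is handled by the same latent-normal
(probit) augmentation used for binary covariates: $y = 1\{u > 0\}$ with
$u \sim N(\eta, 1)$, which keeps every update conjugate; its coefficients
are therefore on the probit scale (roughly log-odds / 1.6).

**Imputation model.**  Every covariate with at least one missing cell is an
imputation target.  The $d$ targets form a latent vector
$w_{ij} \sim \mathrm{MVN}(\mu_{ij}, \Sigma)$ with

$$\mu_{dij} = \gamma_{0dj} + \textstyle\sum_p \gamma_{pdj} z_{pij},$$

where the predictors $z$ are the fully observed covariates, each
$\gamma_{pdj}$ hierarchical like the analysis coefficients.  A continuous
target is $x = w$ (observed values pin the latent down); a binary target is
$x = 1\{w > 0\}$ with $\Sigma_{dd} = 1$ fixed for probit identifiability,
observed binaries constraining $w$ to the matching half-line.  Targets do
not predict one another's means — their mutual dependence is carried by
$\Sigma$, which is shared across clusters (a cluster-specific covariance is
unidentifiable where a target is systematically missing).

**The outcome and the imputations.**  Because the two models are fitted
jointly, the full conditional of each missing cell is the product of its
multivariate-normal imputation conditional and the analysis likelihood —
imputations are automatically informed by the outcome.  For this reason the
outcome is *not* also placed among the mean-model predictors $z$: doing so
would count the outcome–target association twice (the model graph would
contain the cycle $y \to x \to y$), and in desk-scale experiments it biased
$\sigma_y$ downward by ~20% and attenuated coefficients of fully observed
covariates.  `ImputationSpec.auto(..., include_outcome=True)` restores the
two-link variant for users who want to emulate a cut/two-step workflow.

**Priors** (on the standardized scale): $N(0, 10^2)$ for every location
parameter ($\alpha_0$, $\beta_k$, $\gamma_{pd}$); $\mathrm{Uniform}(0, 10)$
for every SD ($\sigma_y$, $\tau$'s, $\psi$'s, and the continuous scales of
$\Sigma$); the correlation part of $\Sigma$ (separation
$\Sigma = D\,R\,D$) gets a jointly uniform prior over valid correlation
matrices.  These are deliberately vague BUGS-style defaults; both scales
are configurable through `PriorConfig`.

## Sampling

A bespoke blocked Gibbs sampler:

* per-cluster coefficient vectors, global fixed effects and hyper-means:
  conjugate (multivariate) normal draws;
* variances under the uniform-on-SD prior: truncated inverse-gamma draws
  via the gamma inverse-CDF;
* latent normals for binary cells: truncated-normal draws through an
  inverse-CDF formulated in log space (`ndtri_exp`), stable arbitrarily far
  into the tail;
* missing binary cells: the side of zero is chosen with the exact posterior
  odds (probit conditional x analysis likelihood), then the latent is drawn
  from the matching truncated normal;
* missing continuous cells: conjugate normal combination of the imputation
  conditional and the analysis likelihood;
* free elements of $\Sigma$: Metropolis steps on log (scales) and atanh
  (correlations) with the exact Jacobians, step size $\max(0.02,
  2.5/\sqrt{n})$; a single continuous target degenerates to a conjugate
  truncated inverse-gamma update.

Chains run sequentially from a deterministic start (coefficients 0, SDs 1,
identity correlation, missing continuous cells at cluster means, latents at
$\pm 0.5$ matching observed binaries); chains beyond the first get seeded
jitter so they start dispersed.  Same seed, same settings: bit-identical
draws.  Every retained draw is checked against the hard constraint
sign$(w)$ = observed binary value.  Defaults are burn-in 5000, updates
10000, 2 chains, thin 1 — interactive-scale defaults; the tests and the
acceptance script use much shorter, explicitly stated runs.

Back-transformation to the original scale is applied per draw, never to
summaries: $\beta_k = \beta_k^* s_y/s_k$, $\alpha_0 = \bar y + s_y\alpha_0^*
- \sum_k \beta_k \bar x_k$, $\sigma_y = \sigma_y^* s_y$, $\tau_k = \tau_k^*
s_y/s_k$ (with $\bar x_k = 0$, $s_k = 1$ for variables left
unstandardized: binary imputation targets and a binary outcome).

## Diagnostics

* **R-hat**: split-chain potential scale reduction (each chain halved;
  $\hat R = \sqrt{((n'-1)/n'\,W + B/n')/W}$).  The modern split form is
  used instead of the original two-sequence statistic because it also
  detects within-chain trends; the warning threshold stays at 1.1
  ("increase burn-in period").
* **MCMC error**: batch means with $\lfloor\sqrt{n}\rfloor$ batches —
  simple, deterministic, BUGS-style "MC error"; warning when it exceeds 5%
  of a parameter's posterior SD ("increase number of updates").
* Output: results table (coefficient, estimate, SE, 95% CrI, MCMC error,
  R-hat), machine-readable warnings, BUGS-dialect CODA files
  (full-precision text; a round trip is bit-identical), and tidy
  trace/density data — plots are presentation, the data are the contract.

## Evaluation harness

`make_scenarios`/`apply_drop` impose systematic missingness by plan: by
default 1 cluster loses the continuous variable, 1 the binary variable and
3 both (5 affected clusters), randomized over scenarios.
`run_comparison` fits (a) the gold standard — the same hierarchical
analysis model on complete data, (b) the naive analysis after dropping
affected clusters, (c) the joint model on each mutilated copy, and pools
(b)–(c) over scenarios with Rubin's rules, treating scenarios like
imputations: $\bar Q$, $W$ (mean squared posterior SE), $B$, $T = W +
(1+1/m)B$.  Intervals use the normal 1.96 multiplier; the per-scenario
variance is the squared posterior SD (an interval-derived variance was the
other candidate; the posterior variance is exact for the quantity pooled).
External methods can be pooled on equal footing through `pool_external`
(CSV of scenario, variable, estimate, SE).

## Synthetic data

`synthdata` emulates a multicentre lung-function-style study: continuous
outcome on smoking (binary), weight, sex (binary), height, age; `full`
scale has 10 centres of 521–1047 subjects, `desk` 6 centres of 80–120 for
fast tests.  Covariates come from a Gaussian copula (binaries thresholded
at cluster-specific prevalences), giving explicit control of the
cross-covariate dependence the MVN imputation exploits.  Fixed effects are
0.2–1.0 on the standardized scale with heterogeneity ratios $\tau_k/\beta_k
\approx 0.2$–$0.5$ — heterogeneity visible but estimable with ~10 clusters.
Slope heterogeneity is applied around the covariate grand means
($y = \alpha_j + \sum\beta_k x_k + \sum(\beta_{kj}-\beta_k)(x_k - m_k) +
\varepsilon$): with uncentered covariates like height (~170), raw slope
deviations would shift cluster means by tens of outcome units and swamp
$\tau_\alpha$; the centered form keeps the between-centre outcome spread
governed by $\tau_\alpha$ alone, as in real multicentre data.  The fitted
model is unaffected (its intercepts are free).

What the generator does *not* emulate: real marginal distributions (only
structure, not values), missing-not-at-random mechanisms, more than two
grouping levels, longitudinal structure, or categorical (>2 level)
variables.  Passing tests therefore demonstrate correctness of the
machinery under MAR-type mechanisms with normal/probit-compatible
covariates, not robustness to model misspecification.

## Numerical and design notes

* Missing *outcome* rows are excluded (with a logged count), never imputed:
  the imputation model covers covariates only, and the right treatment of
  outcome missingness is a modelling decision the user should make
  explicitly.
* Cluster labels map to indices in sorted order — reproducible across runs
  and row orders.
* Quantiles are linear-interpolation (type 7); percentile differences
  against other conventions are below Monte-Carlo error at the default
  number of updates.
* Constant columns cannot be standardized and raise immediately.
* With zero imputation targets the joint model is refused with a pointer to
  the analysis-only route; a declared target with zero missing cells is
  legal and leaves the analysis posterior unchanged (used as a regression
  test).
* Degenerate R-hat (all draws identical) is reported as 1 with a flag
  rather than NaN.

## Problem sizes used in tests

The test-suite and acceptance-script runs use the desk preset (6 clusters
of 80–120, ~600 rows), short chains (burn-in 300–500, updates 600–4000, 1–2
chains) and 20 replicates for the coverage study.  These sizes were chosen
so the whole suite completes in a few minutes while leaving Monte-Carlo
error well below the tolerances being checked; all comparisons are stated
in units of the computed MCSE, so longer runs only tighten them.

## Known limitations

* The binary-outcome link is probit, not logistic; coefficients are not
  log-odds-ratios (divide by ~1.6 for an approximate conversion).
* The correlation block uses simple Metropolis steps; with many imputation
  targets (d > ~6) mixing of $\Sigma$ may need more updates.
* No Barnard–Rubin small-sample degrees-of-freedom correction is applied to
  pooled intervals by default (the normal multiplier is used).
* Two-level data only; no interactions are generated automatically in the
  imputation mean model.
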