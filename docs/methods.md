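# Methods

## Decision models and the adaptive battery

Delayed outcomes are valued hyperbolically, `V = A / (1 + k·D)` with `D`
in days.  Probabilistic outcomes use the same hyperbola on the odds
against winning, `θ = (1 − p)/p`, i.e. `V = A / (1 + k·θ)`; this is the
standard probability-discounting parameterization and makes `p = 1`
reduce to the certain amount.  Losses are carried as negative amounts so
values keep their sign.  Mixed gambles use the linear utility
`U = 0.5·gain − 0.5·λ·loss` for a 50/50 gamble; the 10 € task endowment
is bookkeeping only and never enters utility.

Choices follow a logistic (softmax) rule
`P(B) = 1/(1 + exp(−β·(V_B − V_A)))` with one inverse temperature β per
task.  The battery itself never names β; it is part of the adaptive
estimation machinery, and its treatment here (a per-task nuisance
dimension of the posterior grid) is this package's reconstruction of the
adaptive framework the battery descends from.

Estimation is grid-based sequential Bayes.  The joint posterior over
(log parameter, log β) lives on a fixed lattice:

| axis | range | nodes | rationale |
|---|---|---|---|
| log k (discounting) | [−7, 2] | 41 | covers human k from ~0.001/day to ~7/day |
| log λ (loss aversion) | [−2, 2] | 41 | λ from 0.14 to 7.4, centred on λ = 1 |
| log β | [−3, 2] | 11 | near-random to near-deterministic responding |

The initial prior is uniform (reproducible and unopinionated); the mass
is renormalized after every trial and must sum to 1 within 1e−9.  A
trial whose likelihood underflows to exactly zero on every node raises a
diagnostic error rather than silently renormalizing.

Offers adapt: the delay/probability (or the gamble loss, on a 0.50 €
lattice in [5, 20] €) is drawn uniformly from its menu, and the
adjustable amount — the certain/sooner amount against a fixed 10 €
delayed/probabilistic amount, or the gamble gain `λ̂·loss` — is set to
the indifference point under the posterior-mean parameter, rounded to
0.01 € and clipped to the task's range ([0.30, 10] € for discounting,
[1, 40] € for gamble gains).  Before the first trial the uniform grid's
mean is the grid centre, which anchors the first offer.  MAP extraction
breaks ties toward the smaller parameter value, deterministically.
In the probability-discounting-for-losses task the *certain* loss is the
adapted option (mirroring the gain tasks); the framework the battery
descends from does not pin this down.

Parameter recovery at these settings: 100 simulated agents per task with
β = 5 and parameters uniform over the central grid give Spearman
ρ ≈ 0.99 and median absolute error below 0.1 log units (30–40 trials).
β = 0 agents stay near the uniform-prior mean with a wide posterior;
the adaptive placement makes their trials *almost* — not exactly —
uninformative, so small drifts are expected.

## Synthetic cohort

The generator emulates a prospective community cohort of young adults
(19–27): groups SUD/ND/control of 100/118/120, Bernoulli(0.92) retention
with follow-up fields masked for dropouts, demographics (gender, IQ,
income and school-qualification indicators) anchored to the sample
being emulated, and covariate effects defaulting to zero but
configurable so the adjustment machinery is exercised.

Decision parameters are generated directly on the standardized scale:
z(log k) ~ N(group shift, 1), with default shifts equal to the
group-difference likelihood estimates (delay +0.24/+0.08, probability
discounting gains −0.09/−0.06, losses −0.27/−0.21, loss aversion
+0.09/+0.12 for SUD/ND).  The four parameters are independent by
default — a stated simplification, since their empirical correlations
are not reported anywhere usable.

Criterion counts use a latent-threshold construction: case groups draw
their class sum as 2 + Poisson (calibrated to class-sum medians of 3 for
SUD and 4 for ND cases), the other class is at most 1, controls at most
1 in both.  Follow-up counts come from a standardized latent change
`z = Σ assoc·z(param) + covariates + N(0, 1)` scaled by 2 criteria per
latent sd, rounded, added to baseline and clipped to [0, 11].  The
scale-2 mapping keeps rounding attenuation of standardized coefficients
below ~2%; clipping at zero (controls cannot lose criteria they do not
have) attenuates somewhat more, which is visible and intended — real
count outcomes do the same.

QFIs are log-normal per behaviour (non-negative and right-skewed like
consumption data), with engagement probabilities and quantity medians
per group chosen to roughly track the reported severity tables; the
follow-up quantity scales by `exp(0.35·z_class + noise)`.  Because many
participants have zero engagement in any given behaviour, QFI-change
associations are attenuated relative to the generating values — the
recovery guarantees in the tests therefore target the criteria outcomes,
and QFI models are exercised but not held to tight recovery.  Passing
tests show the pipeline recovers the structure it generates; they do not
show the generator reproduces every marginal feature of real cohorts.

## Severity outcomes

QFI = weekly frequency-category maximum × quantity per occasion, with
category maxima {almost daily: 7, 3–4/week: 4, 1–2/week: 2, 1–3/month:
0.75, less than monthly: 0.25} occasions/week (weekly scaling because
all QFIs are per week; the sub-monthly multiplier is configurable).
QFIs are z-standardized per behaviour pooling both waves, summed per
disorder class, and the class sums z-standardized again.  All
z-standardization uses the sample sd (n − 1), matching the convention of
the usual statistics packages; constant columns raise a degenerate-scale
error rather than producing NaNs.  Change outcomes are follow-up minus
baseline, z-standardized, with the z-scored baseline retained as a
covariate against regression to the mean; participants missing a wave
are dropped with a warning.  Tukey fences use linear-interpolation
quartiles: values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are excluded in
the sensitivity re-analysis.

## Bayesian regression

The sampler is Gibbs for the conjugate normal linear model: independent
normal priors per coefficient, inverse-gamma(0.01, 0.01) residual
variance.  Defaults mirror the analysis protocol: burn-in 5000, then
100 000 iterations keeping every second draw.  With the variance fixed
the sampler draws from the exact posterior, which is how it is checked
against the closed form; with vague priors its means match OLS.
Likelihood rows are OLS fits with Wald intervals (an assumption, made
explicit).  Priors: group differences N(0.37, 0.02) for delay
discounting, N(−0.16, 0.02) for both probability-discounting tasks,
N(−0.44, 0.02) for loss aversion; predictions N(±0.25, 0.016), i.e.
95% prior mass in [0, 0.5]; covariates and intercept N(0, 1e4).  Income
and education enter as binary indicators.  Directional probabilities are
`100·Φ(±mean/sd)` for normal summaries and the draw fraction (ties count
half) for MCMC output; the SUD-vs-ND contrast is the share of paired
posterior draws with the SUD coefficient above the ND coefficient.

The conjugate combination used for the table reproduction converts each
printed 95% interval to an sd (width / 3.9199) and precision-weights.
Seven of the published posterior rows — the ones whose models are
dominated by the marginal prior×likelihood structure — reproduce within
±0.01; the remainder reflect the joint covariate-adjusted sampler and
deviate by up to 0.13.  The reproduction table reports all deviations.

### Reverse-Bayes

Starting from the analysis prior, the prior mean moves in 0.1 steps
against the hypothesized direction with the variance fixed; each
candidate prior is combined with the likelihood and the walk stops at
the first posterior whose directional probability drops below the
threshold (default 95%), or at a floor 3 units out.  The function
returns the last passing mean and the full trace, which is provably
monotone.  Two grid anchorings are exposed — at the starting prior mean
(default) or snapped to decimal multiples of the step — because the
published sensitivity results do not state which was used and are not
recoverable from the printed likelihood summaries alone; this package
computes rather than copies them.

### Calibration under the null

With all generator effects zero, the *informative* priors still produce
directional probabilities far above 50% (a prior centred at 0.37 with sd
0.14 dominates a null likelihood) — that is the design of an
informative-prior analysis, not an error.  Calibration is therefore
assessed on the data term: OLS/vague-prior directional probabilities,
pooled over seeds and tasks, average 50% under the null configuration.

## Problem sizes

The test suite runs the battery recovery at 100 agents × 4 tasks,
sampler checks at burn-in 500 / 10 000 draws, and pipeline recovery over
20 cohort seeds; the analysis drivers default to the full sampler
settings.  These sizes are the package's reporting choices and are
overridable from every entry point.

## Known limitations

* The adaptive offer rule and β handling are a reconstruction; the
  original battery's exact trial-construction code may differ in
  rounding and menu handling.
* The cohort generator matches group-level moments and medians, not the
  full joint distribution of real severity data (no seasonal effects,
  no informative attrition, independence between decision facets).
* QFI-change effect sizes are attenuated by design (zero-engagement
  floor); criteria outcomes carry the recovery guarantees.
* The Gibbs sampler assumes homoscedastic normal residuals; count
  outcomes are modelled on the standardized-change scale, as in the
  analysis protocol, not with count likelihoods.
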