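# bayesdm

Adaptive Bayesian measurement of impulsive decision-making, and
informative-prior Bayesian analyses of how those measures relate to the
1-year course of addictive-disorder severity.

The package is aimed at researchers in computational psychiatry and
addiction epidemiology who want a fully reproducible, end-to-end
implementation of this analysis style: an adaptive behavioural battery,
a synthetic cohort with a known generative structure, and Bayesian
regression with explicit priors and prior-sensitivity analyses — all
runnable offline.

## What it implements

**The decision-making battery** (`bayesdm.task_engine`) measures four
facets of impulsivity with two-alternative choice tasks:

* *delay discounting* — hyperbolic value `V = A / (1 + k·D)` over delays
  of 3–365 days; larger `k` = steeper discounting = more impulsive;
* *probability discounting for gains and for losses* — the same
  hyperbola over the odds against winning, `θ = (1 − p)/p`, so
  `V = A / (1 + k·θ)` for p ∈ {2/3, 1/2, 1/3, 1/4, 1/5};
* *loss aversion* — 50/50 mixed gambles with linear utility
  `U = 0.5·gain − 0.5·λ·loss`; λ > 1 means losses loom larger than gains.

Choices follow a logistic rule with inverse temperature β.  A discrete
joint posterior over (log parameter, log β) is updated after every
trial, and the next offer is placed at the indifference point implied by
the current posterior mean, so each trial is maximally informative: 30
(discounting) or 40 (gambles) trials order simulated individuals with
Spearman ρ ≈ 0.99.

**The cohort generator** (`bayesdm.cohort`) builds a synthetic
three-group sample — substance use disorder (SUD, n = 100),
non-substance-related addictive disorder (ND, n = 118), controls
(n = 120), retention 92% — with standardized decision parameters shifted
per group, diagnostic criterion counts satisfying the group logic
(cases ≥ 2 of 11 criteria in their class), quantity-frequency indices
(QFI = weekly frequency maximum × quantity per occasion), and severity
change at follow-up driven by known standardized associations.

**The Bayes engine** (`bayesdm.bayes`, `bayesdm.severity`,
`bayesdm.pipeline`) fits the analyses: informative-prior Bayesian linear
regression (Gibbs sampler; burn-in 5000, 100 000 iterations, thinning 2
by default), directional posterior probabilities `100·Φ(±mean/sd)`,
posterior-draw group contrasts, group × predictor interaction models,
Tukey-fence outlier sensitivity, and reverse-Bayes prior relaxation —
walking the prior mean in 0.1 steps against the hypothesis to find the
most pessimistic prior that still supports the conclusion at 95%.

The published prior/likelihood/posterior summary rows for every analysis
block ship as a fixture (`bayesdm/data/printed_tables.csv`), and
`bayesdm.tables.reproduce_posteriors()` re-derives each posterior row
by the conjugate normal-normal combination (95% intervals → sd via
width/3.9199; precisions add; means precision-weighted).

## Worked example

```sh
python analysis/01_reproduce_posteriors.py
```

prints (abridged):

```
24 posterior rows recomputed; 15 agree with the printed mean within +-0.01.
...
Headline: delay-discounting SUD contrast posterior 0.30 (printed 0.30),
directional probability 99.9%.
```

i.e. combining the delay-discounting SUD prior (0.37, 95% interval
0.10–0.64) with the data likelihood (0.24, −0.02–0.51) yields a
posterior of 0.30 with 99.9% of its mass above zero: strong evidence
that the SUD group discounts delayed rewards more steeply than controls.
Rows that the marginal combination does not reproduce come from the
joint covariate-adjusted sampler and are listed, not hidden.

```sh
python analysis/02_simulate_tasks.py     # battery parameter recovery
python analysis/03_simulate_cohort.py    # synthetic cohort + severity data
python analysis/04_group_differences.py  # Bayesian group contrasts
python analysis/05_predictions.py        # 1-year change models + interactions
python analysis/06_reverse_bayes.py      # prior-relaxation sensitivity
```

Each driver narrates what it finds and writes its tables under
`results/`.  The same stages are exposed as a CLI
(`bayesdm simulate-tasks|simulate-cohort|analyze|reverse-bayes|report`),
every artifact carrying the seed and config hash in `manifest.json`.

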