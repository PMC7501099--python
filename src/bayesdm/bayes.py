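"""Informative-prior Bayesian linear regression and prior-sensitivity tools.

The analytical core of the pipeline:

* ``NormalSummary`` — (mean, sd) of a prior, likelihood or posterior for
  one regression coefficient; 95% intervals convert to sds via
  ``ci_to_sd`` (width / (2 * 1.959964)).
* ``combine_normal_summaries`` — the conjugate normal-normal combination:
  precisions add, the posterior mean is the precision-weighted average.
  This is the closed-form oracle the MCMC sampler is checked against and
  the engine behind the table-reproduction analyses.
* ``fit_bayes_lm`` — Gibbs sampler for the normal linear model with
  independent normal coefficient priors and an inverse-gamma residual
  variance prior.
* ``directional_probability`` — posterior mass on the hypothesized side
  of zero, in percent.
* ``reverse_bayes`` — walks the prior mean against the hypothesized
  direction in fixed steps to find the most pessimistic prior that still
  supports the conclusion at a given posterior threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959964  # standard-normal 97.5% quantile as printed by Stata

Direction = Literal["greater", "less"]


def ci_to_sd(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard deviation implied by a central normal interval."""
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    z = stats.norm.ppf(0.5 + level / 2.0) if level != 0.95 else Z975
    return (upper - lower) / (2.0 * z)


@dataclass(frozen=True)
class NormalSummary:
    """Normal (mean, sd) summary of a coefficient distribution."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be > 0")

    @classmethod
    def from_ci(cls, mean: float, lower: float, upper: float, level: float = 0.95) -> "NormalSummary":
        return cls(mean=mean, sd=ci_to_sd(lower, upper, level))

    @classmethod
    def from_variance(cls, mean: float, variance: float) -> "NormalSummary":
        return cls(mean=mean, sd=math.sqrt(variance))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.mean - Z975 * self.sd, self.mean + Z975 * self.sd)

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "NormalSummary":
        draws = np.asarray(draws, dtype=float)
        return cls(mean=float(draws.mean()), sd=float(draws.std(ddof=1)))


def combine_normal_summaries(prior: NormalSummary, likelihood: NormalSummary) -> NormalSummary:
    """Conjugate normal-normal combination (precision weighting)."""
    p1, p2 = 1.0 / prior.sd**2, 1.0 / likelihood.sd**2
    post_var = 1.0 / (p1 + p2)
    post_mean = (prior.mean * p1 + likelihood.mean * p2) * post_var
    return NormalSummary(mean=post_mean, sd=math.sqrt(post_var))


def directional_probability(summary_or_draws, direction: Direction) -> float:
    """Percent of posterior mass in the hypothesized direction.

    Accepts a :class:`NormalSummary` (closed form, 100*Phi(+-mean/sd)) or
    an array of posterior draws (draw fraction; exact zeros count half).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if isinstance(summary_or_draws, NormalSummary):
        z = summary_or_draws.mean / summary_or_draws.sd
        p = stats.norm.cdf(z if direction == "greater" else -z)
        return float(100.0 * p)
    draws = np.asarray(summary_or_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    side = draws > 0 if direction == "greater" else draws < 0
    return float(100.0 * (side.sum() + 0.5 * (draws == 0).sum()) / draws.size)


@dataclass(frozen=True)
class DirectionalResult:
    """Posterior coefficient summary with its directional probability."""

    summary: NormalSummary
    direction: Direction
    probability: float


# ---------------------------------------------------------------------------
# Priors and model specification
# ---------------------------------------------------------------------------

#: Hypothesized direction of each effect: steeper delay discounting
#: (larger k) in cases / predicting worsening; lower k and lambda for the
#: probability-discounting and loss-aversion facets.
DIRECTIONS: dict[str, Direction] = {
    "delay": "greater",
    "prob_gain": "less",
    "prob_loss": "less",
    "loss_aversion": "less",
}

#: Group-difference priors (from the earlier clinical study): mean and
#: variance on the standardized log-parameter scale.
GROUP_DIFF_PRIORS: dict[str, NormalSummary] = {
    "delay": NormalSummary.from_variance(0.37, 0.02),
    "prob_gain": NormalSummary.from_variance(-0.16, 0.02),
    "prob_loss": NormalSummary.from_variance(-0.16, 0.02),
    "loss_aversion": NormalSummary.from_variance(-0.44, 0.02),
}


def prediction_prior(direction: Direction) -> NormalSummary:
    """Medium-association prior: 95% mass in [0, 0.5] (or [-0.5, 0])."""
    sd = 0.25 / Z975
    return NormalSummary(mean=0.25 if direction == "greater" else -0.25, sd=sd)


VAGUE_SD = 100.0  # variance 1e4 for covariates and the intercept


@dataclass
class PriorSpec:
    """Coefficient-name -> normal prior; unnamed coefficients get a vague prior."""

    priors: dict[str, NormalSummary] = field(default_factory=dict)
    vague_sd: float = VAGUE_SD

    def for_coefficient(self, name: str) -> NormalSummary:
        return self.priors.get(name, NormalSummary(0.0, self.vague_sd))


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: burn-in iterations, retained-run length, thinning."""

    burn_in: int = 5000
    draws: int = 100_000
    thinning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.draws > self.burn_in > 0):
            raise ValueError("require draws > burn_in > 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass(frozen=True)
class RegressionSpec:
    """Design of one regression: outcome, focal predictor, dummies, covariates."""

    outcome: str
    predictor: str | None = None
    group_dummies: tuple[str, ...] = ()  # e.g. ("SUD", "ND"); control = reference
    covariates: tuple[str, ...] = ()
    interactions: bool = False  # add group x predictor terms

    def coefficient_names(self) -> list[str]:
        names = ["intercept"]
        if self.predictor:
            names.append(self.predictor)
        names.extend(self.group_dummies)
        names.extend(self.covariates)
        if self.interactions:
            if not (self.predictor and self.group_dummies):
                raise ValueError("interactions need a predictor and group dummies")
            names.extend(f"{g}:{self.predictor}" for g in self.group_dummies)
        return names


def build_design(data: pd.DataFrame, spec: RegressionSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix, outcome vector and coefficient names for ``spec``.

    Group dummies are expected as 0/1 columns named after the group;
    raises on rank deficiency.
    """
    names = spec.coefficient_names()
    cols = [np.ones(len(data))]
    for name in names[1:]:
        if ":" in name:
            g, pred = name.split(":", 1)
            cols.append(data[g].to_numpy(float) * data[pred].to_numpy(float))
        else:
            cols.append(data[name].to_numpy(float))
    X = np.column_stack(cols)
    y = data[spec.outcome].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, y, names


def ols_fit(data: pd.DataFrame, spec: RegressionSpec) -> dict[str, NormalSummary]:
    """Ordinary least squares with Wald summaries (the 'likelihood' rows)."""
    import statsmodels.api as sm

    X, y, names = build_design(data, spec)
    res = sm.OLS(y, X).fit()
    return {
        name: NormalSummary(mean=float(b), sd=float(se))
        for name, b, se in zip(names, res.params, res.bse)
    }


def fit_bayes_lm(
    data: pd.DataFrame,
    spec: RegressionSpec,
    priors: PriorSpec,
    mcmc: McmcConfig,
    sigma2: float | None = None,
) -> dict[str, np.ndarray]:
    """Gibbs sampler for the normal linear model with normal coefficient priors.

    Residual variance gets an inverse-gamma(0.01, 0.01) prior unless
    ``sigma2`` fixes it (used by the conjugate closed-form checks).
    Returns thinned post-burn-in draws per coefficient, plus ``"sigma2"``.
    """
    X, y, names = build_design(data, spec)
    n, p = X.shape
    rng = np.random.default_rng(mcmc.seed)
    prior_means = np.array([priors.for_coefficient(nm).mean for nm in names])
    prior_prec = np.array([1.0 / priors.for_coefficient(nm).sd ** 2 for nm in names])
    XtX = X.T @ X
    Xty = X.T @ y
    a0 = b0 = 0.01  # inverse-gamma shape/rate for sigma2

    s2 = float(sigma2) if sigma2 is not None else float(np.var(y)) or 1.0
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    n_iter = mcmc.burn_in + mcmc.draws
    keep = [i for i in range(mcmc.burn_in, n_iter) if (i - mcmc.burn_in) % mcmc.thinning == 0]
    out = np.empty((len(keep), p))
    s2_out = np.empty(len(keep))
    j = 0
    for it in range(n_iter):
        prec = np.diag(prior_prec) + XtX / s2
        chol = np.linalg.cholesky(prec)
        rhs = prior_prec * prior_means + Xty / s2
        mean = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(chol.T, z)
        if sigma2 is None:
            resid = y - X @ beta
            s2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * resid @ resid))
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            out[j] = beta
            s2_out[j] = s2
            j += 1
    draws = {name: out[:, i] for i, name in enumerate(names)}
    draws["sigma2"] = s2_out
    return draws


def group_contrast(draws_sud: np.ndarray, draws_nd: np.ndarray) -> float:
    """Percent of paired posterior draws with SUD coefficient above ND.

    Differences exactly zero count half (unbiased for discrete draws).
    """
    draws_sud = np.asarray(draws_sud, dtype=float)
    draws_nd = np.asarray(draws_nd, dtype=float)
    if draws_sud.shape != draws_nd.shape:
        raise ValueError("draw vectors must have equal length")
    diff = draws_sud - draws_nd
    return float(100.0 * ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def fit_interaction_model(
    data: pd.DataFrame,
    spec: RegressionSpec,
    priors: PriorSpec,
    mcmc: McmcConfig,
    directions: Mapping[str, Direction] | Direction = "greater",
) -> dict[str, DirectionalResult]:
    """Fit a model with group x predictor terms; report each interaction.

    ``directions`` may be one direction for all interaction coefficients
    or a mapping per coefficient name.
    """
    if not spec.interactions:
        spec = RegressionSpec(
            outcome=spec.outcome,
            predictor=spec.predictor,
            group_dummies=spec.group_dummies,
            covariates=spec.covariates,
            interactions=True,
        )
    draws = fit_bayes_lm(data, spec, priors, mcmc)
    out: dict[str, DirectionalResult] = {}
    for g in spec.group_dummies:
        name = f"{g}:{spec.predictor}"
        direction = directions if isinstance(directions, str) else directions.get(name, "greater")
        d = draws[name]
        out[name] = DirectionalResult(
            summary=NormalSummary.from_draws(d),
            direction=direction,
            probability=directional_probability(d, direction),
        )
    return out


# ---------------------------------------------------------------------------
# Reverse-Bayes prior relaxation
# ---------------------------------------------------------------------------

def reverse_bayes(
    likelihood: NormalSummary,
    prior_var: float,
    direction: Direction,
    threshold: float = 0.95,
    step: float = 0.1,
    start_mean: float = 0.0,
    floor: float | None = None,
    anchor: Literal["start", "decimal"] = "start",
) -> tuple[float | None, list[tuple[float, float]]]:
    """Most pessimistic prior mean still supporting the conclusion.

    Walks the prior mean from ``start_mean`` in ``step`` increments
    against the hypothesized ``direction`` (variance held fixed), combines
    each candidate prior with the likelihood, and returns the last mean
    whose posterior directional probability is >= ``threshold``, together
    with the full (mean, probability) trace.  ``anchor='decimal'`` snaps
    the grid to multiples of ``step``.  Returns ``None`` as the mean when
    even the starting prior fails.  The walk stops at the first failure
    or at ``floor`` (default: 3 units against the direction).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if step <= 0:
        raise ValueError("step must be > 0")
    sign = 1.0 if direction == "greater" else -1.0
    if anchor == "decimal":
        start_mean = sign * math.floor(sign * start_mean / step) * step
    if floor is None:
        floor = start_mean - sign * 3.0
    sd = math.sqrt(prior_var)
    trace: list[tuple[float, float]] = []
    last_passing: float | None = None
    m = start_mean
    while sign * (m - floor) >= -1e-12:
        prob = directional_probability(
            combine_normal_summaries(NormalSummary(m, sd), likelihood), direction
        ) / 100.0
        trace.append((round(m, 10), 100.0 * prob))
        if prob >= threshold:
            last_passing = round(m, 10)
        else:
            break
        m -= sign * step
    return last_passing, trace
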