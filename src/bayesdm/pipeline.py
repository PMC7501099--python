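"""End-to-end analyses over a (synthetic) cohort.

Mirrors the study's analysis plan:

* group differences — Bayesian linear regression of each z-scaled
  decision parameter on SUD/ND dummies (control = reference) with the
  informative group-difference priors, demographic covariates, a
  posterior-draw SUD-vs-ND contrast, and directional probabilities;
* predictions — Bayesian regression of each standardized severity-change
  outcome on each baseline decision parameter with the medium-association
  prior, demographics and the baseline value as covariates;
* interactions — the prediction models with group x predictor terms;
* outlier sensitivity — group differences after Tukey-fence exclusion;
* reverse-Bayes — prior-mean relaxation per analysis block.

Each result carries prior, likelihood (OLS/Wald) and posterior rows in
the published table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import (
    DIRECTIONS,
    GROUP_DIFF_PRIORS,
    Direction,
    DirectionalResult,
    McmcConfig,
    NormalSummary,
    PriorSpec,
    RegressionSpec,
    directional_probability,
    fit_bayes_lm,
    fit_interaction_model,
    group_contrast,
    ols_fit,
    prediction_prior,
    reverse_bayes,
)
from .cohort import OUTCOMES, PARAM_COLS, TASKS
from .severity import build_change_outcome, tukey_filter, zscore

DEMOGRAPHICS = ("age_z", "female", "iq_z", "income_lt1500", "abitur")


@dataclass
class AnalysisBlock:
    """Posterior/prior/likelihood rows plus the directional probability."""

    analysis: str
    task: str
    target: str
    direction: Direction
    prior: NormalSummary
    likelihood: NormalSummary
    posterior: NormalSummary
    probability: float  # posterior directional probability, percent
    likelihood_probability: float  # same, from the data term alone
    contrast: float | None = None  # % of draws with SUD coef above ND

    def to_rows(self) -> list[dict]:
        rows = []
        for row, s in (("posterior", self.posterior), ("prior", self.prior), ("likelihood", self.likelihood)):
            lo, hi = s.ci95
            rows.append(
                {
                    "analysis": self.analysis,
                    "task": self.task,
                    "target": self.target,
                    "row": row,
                    "mean": s.mean,
                    "lower": lo,
                    "upper": hi,
                    "probability": self.probability if row == "posterior" else np.nan,
                    "direction": self.direction,
                }
            )
        return rows


def prepare_analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analysis-ready frame: z-scaled parameters/covariates, group dummies."""
    df = cohort.copy()
    df["SUD"] = (df["group"] == "SUD").astype(float)
    df["ND"] = (df["group"] == "ND").astype(float)
    df["age_z"] = zscore(df["age"])
    df["iq_z"] = zscore(df["iq"])
    for col in PARAM_COLS.values():
        df[f"{col}_z"] = zscore(df[col])
    return df


def group_difference_analysis(
    cohort: pd.DataFrame,
    task: str,
    priors: dict[str, NormalSummary] | None = None,
    mcmc: McmcConfig | None = None,
) -> AnalysisBlock | dict[str, AnalysisBlock]:
    """Group-difference model for one task; returns a block per group."""
    df = prepare_analysis_frame(cohort)
    mcmc = mcmc or McmcConfig()
    prior = (priors or GROUP_DIFF_PRIORS)[task]
    direction = DIRECTIONS[task]
    spec = RegressionSpec(
        outcome=f"{PARAM_COLS[task]}_z",
        group_dummies=("SUD", "ND"),
        covariates=DEMOGRAPHICS,
    )
    lik = ols_fit(df, spec)
    prior_spec = PriorSpec(priors={"SUD": prior, "ND": prior})
    draws = fit_bayes_lm(df, spec, prior_spec, mcmc)
    contrast = group_contrast(draws["SUD"], draws["ND"])
    out = {}
    for g in ("SUD", "ND"):
        post = NormalSummary.from_draws(draws[g])
        out[g] = AnalysisBlock(
            analysis="group_diff",
            task=task,
            target=g,
            direction=direction,
            prior=prior,
            likelihood=lik[g],
            posterior=post,
            probability=directional_probability(draws[g], direction),
            likelihood_probability=directional_probability(lik[g], direction),
            contrast=contrast,
        )
    return out


def prediction_analysis(
    cohort: pd.DataFrame,
    task: str,
    outcome: str,
    mcmc: McmcConfig | None = None,
    change: pd.DataFrame | None = None,
    severity_long: pd.DataFrame | None = None,
) -> AnalysisBlock:
    """Change-score model: outcome change_z ~ parameter_z + covariates + baseline."""
    mcmc = mcmc or McmcConfig()
    direction = DIRECTIONS[task]
    df = _prediction_frame(cohort, change, severity_long)
    clazz = outcome.split("_")[0]
    kind = "qfi" if outcome.endswith("qfi") else "criteria"
    pred = f"{PARAM_COLS[task]}_z"
    spec = RegressionSpec(
        outcome=f"{clazz}_{kind}_change_z",
        predictor=pred,
        covariates=DEMOGRAPHICS + (f"{clazz}_{kind}_bl_z",),
    )
    lik = ols_fit(df, spec)
    prior = prediction_prior(direction)
    draws = fit_bayes_lm(df, spec, PriorSpec(priors={pred: prior}), mcmc)
    return AnalysisBlock(
        analysis="prediction",
        task=task,
        target=outcome,
        direction=direction,
        prior=prior,
        likelihood=lik[pred],
        posterior=NormalSummary.from_draws(draws[pred]),
        probability=directional_probability(draws[pred], direction),
        likelihood_probability=directional_probability(lik[pred], direction),
    )


def _prediction_frame(
    cohort: pd.DataFrame,
    change: pd.DataFrame | None = None,
    severity_long: pd.DataFrame | None = None,
) -> pd.DataFrame:
    if change is None:
        change = build_change_outcome(cohort, severity_long)
    df = prepare_analysis_frame(cohort)
    return df.merge(change, on="id", how="inner")


def interaction_analysis(
    cohort: pd.DataFrame,
    task: str,
    outcome: str,
    mcmc: McmcConfig | None = None,
    change: pd.DataFrame | None = None,
    severity_long: pd.DataFrame | None = None,
) -> dict[str, DirectionalResult]:
    """Prediction model with group x predictor terms (control = reference)."""
    mcmc = mcmc or McmcConfig()
    direction = DIRECTIONS[task]
    df = _prediction_frame(cohort, change, severity_long)
    clazz = outcome.split("_")[0]
    kind = "qfi" if outcome.endswith("qfi") else "criteria"
    pred = f"{PARAM_COLS[task]}_z"
    spec = RegressionSpec(
        outcome=f"{clazz}_{kind}_change_z",
        predictor=pred,
        group_dummies=("SUD", "ND"),
        covariates=DEMOGRAPHICS + (f"{clazz}_{kind}_bl_z",),
        interactions=True,
    )
    prior = prediction_prior(direction)
    return fit_interaction_model(
        df, spec, PriorSpec(priors={pred: prior}), mcmc, directions=direction
    )


def outlier_sensitivity_analysis(
    cohort: pd.DataFrame,
    task: str,
    mcmc: McmcConfig | None = None,
) -> dict[str, AnalysisBlock]:
    """Group differences after excluding Tukey-fence outliers on the parameter."""
    col = PARAM_COLS[task]
    mask = tukey_filter(cohort[col].to_numpy(float))
    return group_difference_analysis(cohort.loc[mask].reset_index(drop=True), task, mcmc=mcmc)


def reverse_bayes_analysis(
    blocks: dict | list[AnalysisBlock],
    threshold: float = 0.95,
    step: float = 0.1,
    anchor: str = "start",
) -> pd.DataFrame:
    """Prior-mean relaxation per analysis block, from its likelihood row."""
    if isinstance(blocks, dict):
        blocks = list(blocks.values())
    rows = []
    for blk in blocks:
        most_pessimistic, trace = reverse_bayes(
            likelihood=blk.likelihood,
            prior_var=blk.prior.sd**2,
            direction=blk.direction,
            threshold=threshold,
            step=step,
            start_mean=blk.prior.mean,
            anchor=anchor,
        )
        rows.append(
            {
                "analysis": blk.analysis,
                "task": blk.task,
                "target": blk.target,
                "direction": blk.direction,
                "start_prior_mean": blk.prior.mean,
                "most_pessimistic_mean": most_pessimistic,
                "n_steps_tested": len(trace),
                "trace": ";".join(f"{m:.2f}:{p:.1f}" for m, p in trace),
            }
        )
    return pd.DataFrame(rows)


def blocks_to_table(blocks) -> pd.DataFrame:
    """Flatten AnalysisBlocks into the published three-row table layout."""
    if isinstance(blocks, dict):
        blocks = list(blocks.values())
    rows: list[dict] = []
    for blk in blocks:
        rows.extend(blk.to_rows())
    return pd.DataFrame(rows)
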