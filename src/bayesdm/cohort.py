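"""Synthetic three-group cohort with the structure the analyses assume.

Generates participants in three groups — substance use disorder (SUD,
n=100), non-substance-related addictive disorder (ND, n=118) and healthy
controls (n=120) — with demographics, standardized true decision
parameters, per-behaviour diagnostic criteria and quantity-frequency
data at baseline and 1-year follow-up, and a 92% retention process.

The generative model:

* decision parameters (z-scaled log k per task, log lambda) are drawn
  N(group shift, 1); the default shifts equal the group-difference
  likelihood estimates of the study conditions being emulated
  (e.g. delay discounting: SUD +0.24, ND +0.08 vs controls);
* baseline criterion counts satisfy the diagnostic logic (cases fulfil
  >= 2 criteria in their class and <= 1 in the other; controls <= 1 in
  both), calibrated to class-sum medians of 3 (SUD) and 4 (ND);
* the standardized latent change in each severity outcome is
  z = sum(assoc * z_param) + covariate terms + N(0, noise_sd), mapped to
  integer follow-up counts by scaling, rounding and clipping to [0, 11];
  the default associations equal the prediction likelihood estimates
  (e.g. delay -> SUD criteria +0.10, loss aversion -> SUD criteria -0.13);
* engagement quantities are log-normal (right-skewed, non-negative) and
  follow-up quantities scale with the latent class-QFI change.

Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .severity import BEHAVIOUR_CLASS, FREQ_PER_WEEK, compute_qfi

GROUPS = ("SUD", "ND", "control")
TASKS = ("delay", "prob_gain", "prob_loss", "loss_aversion")
OUTCOMES = ("sud_criteria", "nd_criteria", "sud_qfi", "nd_qfi")
PARAM_COLS = {
    "delay": "log_k_delay",
    "prob_gain": "log_k_pgain",
    "prob_loss": "log_k_ploss",
    "loss_aversion": "log_lambda",
}
BEHAVIOURS = tuple(BEHAVIOUR_CLASS)
FREQ_LABELS = tuple(FREQ_PER_WEEK)

#: Default standardized group-control differences in decision parameters.
DEFAULT_GROUP_SHIFT: dict[str, dict[str, float]] = {
    "delay": {"SUD": 0.24, "ND": 0.08},
    "prob_gain": {"SUD": -0.09, "ND": -0.06},
    "prob_loss": {"SUD": -0.27, "ND": -0.21},
    "loss_aversion": {"SUD": 0.09, "ND": 0.12},
}

#: Default standardized associations between baseline decision parameters
#: and 1-year severity change, per (task, outcome).
DEFAULT_ASSOC: dict[tuple[str, str], float] = {
    ("delay", "sud_criteria"): 0.10,
    ("delay", "nd_criteria"): 0.00,
    ("delay", "sud_qfi"): 0.11,
    ("delay", "nd_qfi"): 0.05,
    ("prob_gain", "sud_criteria"): -0.02,
    ("prob_gain", "nd_criteria"): -0.03,
    ("prob_gain", "sud_qfi"): 0.00,
    ("prob_gain", "nd_qfi"): 0.03,
    ("prob_loss", "sud_criteria"): 0.05,
    ("prob_loss", "nd_criteria"): -0.06,
    ("prob_loss", "sud_qfi"): 0.02,
    ("prob_loss", "nd_qfi"): 0.02,
    ("loss_aversion", "sud_criteria"): -0.13,
    ("loss_aversion", "nd_criteria"): -0.07,
    ("loss_aversion", "sud_qfi"): -0.04,
    ("loss_aversion", "nd_qfi"): -0.02,
}

#: Quantity-per-occasion log-normal medians (cigarettes, grams ethanol, hours).
_QUANTITY_MEDIAN = {
    "tobacco": 2.5,
    "alcohol": 36.0,
    "internet": 2.0,
    "gaming": 1.5,
    "gambling": 0.5,
    "shopping": 0.5,
}
_QUANTITY_SIGMA = 0.6

#: Frequency-category weights: own-class behaviours skew frequent.
_FREQ_W_OWN = np.array([0.40, 0.25, 0.20, 0.10, 0.05])
_FREQ_W_OTHER = np.array([0.08, 0.12, 0.25, 0.25, 0.30])

#: Engagement probability of each behaviour by group.
_ENGAGE = {
    "tobacco": {"SUD": 0.70, "ND": 0.25, "control": 0.25},
    "alcohol": {"SUD": 0.90, "ND": 0.70, "control": 0.70},
    "internet": {"SUD": 0.55, "ND": 0.95, "control": 0.55},
    "gaming": {"SUD": 0.35, "ND": 0.55, "control": 0.35},
    "gambling": {"SUD": 0.10, "ND": 0.12, "control": 0.05},
    "shopping": {"SUD": 0.10, "ND": 0.12, "control": 0.08},
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"SUD": 100, "ND": 118, "control": 120}
    )
    retention: float = 0.92
    group_shift_z: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_GROUP_SHIFT
    )
    assoc_z: Mapping[tuple[str, str], float] = field(default_factory=lambda: DEFAULT_ASSOC)
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    criteria_change_scale: float = 2.0  # criteria units per latent sd
    qfi_change_scale: float = 0.35  # log-scale units per latent sd
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def null_config(seed: int = 0) -> CohortConfig:
    """All group shifts and associations zero (calibration runs)."""
    return CohortConfig(
        group_shift_z={t: {"SUD": 0.0, "ND": 0.0} for t in TASKS},
        assoc_z={k: 0.0 for k in DEFAULT_ASSOC},
        seed=seed,
    )


def _baseline_criteria(group: str, rng: np.random.Generator) -> dict[str, int]:
    """Per-behaviour baseline criterion counts satisfying the group logic."""
    crit = {b: 0 for b in BEHAVIOURS}
    if group == "SUD":
        u = rng.random()
        subtypes = ["alcohol"] if u < 0.45 else ["tobacco"] if u < 0.84 else ["alcohol", "tobacco"]
        crit[subtypes[0]] = 2 + int(rng.poisson(1.0))
        for b in subtypes[1:]:
            crit[b] = int(rng.poisson(1.5))
        if rng.random() < 0.25:  # sub-threshold other-class symptom
            crit["internet"] = 1
    elif group == "ND":
        u = rng.random()
        subtypes = (
            ["internet"] if u < 0.70 else ["gaming"] if u < 0.84 else
            ["internet", "gaming"] if u < 0.99 else ["gambling"]
        )
        crit[subtypes[0]] = 2 + int(rng.poisson(2.0))
        for b in subtypes[1:]:
            crit[b] = int(rng.poisson(1.5))
        if rng.random() < 0.25:
            crit["alcohol"] = 1
    else:
        if rng.random() < 0.25:
            crit["alcohol"] = 1
        if rng.random() < 0.2:
            crit["internet"] = 1
    return crit


def _class_sum(crit: Mapping[str, int], clazz: str) -> int:
    return sum(v for b, v in crit.items() if BEHAVIOUR_CLASS[b] == clazz)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the wide cohort frame (one row per participant).

    Columns: id, group, demographics (age, female, iq, income_lt1500,
    abitur), true z-scaled decision parameters, per-class criterion
    counts at both waves, per-behaviour criteria / quantity / frequency
    at both waves, and the retention flag.  Follow-up fields of
    non-retained participants are masked to NaN.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    pid = 0
    for group in GROUPS:
        for _ in range(int(config.group_sizes[group])):
            row: dict = {"id": pid, "group": group}
            pid += 1
            # demographics (distributional anchors from the emulated sample)
            row["age"] = int(rng.integers(19, 28))
            row["female"] = int(rng.random() < {"SUD": 0.53, "ND": 0.59, "control": 0.63}[group])
            row["iq"] = float(np.round(rng.normal(104.0, 10.0), 1))
            row["income_lt1500"] = int(rng.random() < 0.76)
            row["abitur"] = int(rng.random() < {"SUD": 0.69, "ND": 0.72, "control": 0.82}[group])
            # true decision parameters, z-scaled
            for task in TASKS:
                shift = 0.0 if group == "control" else float(config.group_shift_z[task][group])
                row[PARAM_COLS[task]] = shift + rng.standard_normal()
            # baseline criteria
            crit_bl = _baseline_criteria(group, rng)
            for b in BEHAVIOURS:
                row[f"{b}_criteria_bl"] = crit_bl[b]
            row["sud_criteria_bl"] = _class_sum(crit_bl, "sud")
            row["nd_criteria_bl"] = _class_sum(crit_bl, "nd")
            # baseline engagement
            for b in BEHAVIOURS:
                engaged = crit_bl[b] > 0 or rng.random() < _ENGAGE[b][group]
                own = BEHAVIOUR_CLASS[b] == ("sud" if group == "SUD" else "nd" if group == "ND" else "")
                w = _FREQ_W_OWN if (own and crit_bl[b] > 0) else _FREQ_W_OTHER
                row[f"{b}_freq_bl"] = str(rng.choice(FREQ_LABELS, p=w / w.sum()))
                q = float(np.exp(rng.normal(math.log(_QUANTITY_MEDIAN[b]), _QUANTITY_SIGMA))) if engaged else 0.0
                row[f"{b}_quantity_bl"] = round(q, 2)
            # latent standardized severity change per outcome
            cov_term = sum(
                coef * row.get(cov, 0.0) for cov, coef in config.covariate_effects.items()
            )
            latent = {}
            for outcome in OUTCOMES:
                signal = sum(
                    float(config.assoc_z.get((task, outcome), 0.0)) * row[PARAM_COLS[task]]
                    for task in TASKS
                )
                latent[outcome] = signal + cov_term + rng.normal(0.0, config.noise_sd)
            # follow-up criteria: scale, round, clip per class; split per behaviour
            for clazz in ("sud", "nd"):
                bl = row[f"{clazz}_criteria_bl"]
                change = int(round(config.criteria_change_scale * latent[f"{clazz}_criteria"]))
                fu = int(np.clip(bl + change, 0, 11))
                row[f"{clazz}_criteria_fu"] = fu
                behs = [b for b in BEHAVIOURS if BEHAVIOUR_CLASS[b] == clazz]
                weights = np.array([crit_bl[b] + 0.25 for b in behs])
                alloc = rng.multinomial(fu, weights / weights.sum())
                for b, c in zip(behs, alloc):
                    row[f"{b}_criteria_fu"] = int(c)
            # follow-up engagement: quantities scale with latent class-QFI change
            for b in BEHAVIOURS:
                clazz = BEHAVIOUR_CLASS[b]
                q_bl = row[f"{b}_quantity_bl"]
                factor = math.exp(
                    config.qfi_change_scale * latent[f"{clazz}_qfi"] + rng.normal(0.0, 0.25)
                )
                row[f"{b}_quantity_fu"] = round(q_bl * factor, 2)
                row[f"{b}_freq_fu"] = row[f"{b}_freq_bl"]
            rows.append(row)
    df = pd.DataFrame(rows)
    return attrit(df, config.retention, rng)


def attrit(participants: pd.DataFrame, retention: float, rng_or_seed) -> pd.DataFrame:
    """Bernoulli retention thinning; masks follow-up fields of dropouts."""
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    df = participants.copy()
    df["retained"] = rng.random(len(df)) < retention
    fu_cols = [c for c in df.columns if c.endswith("_fu")]
    df.loc[~df["retained"], fu_cols] = np.nan
    return df


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format severity records: id, wave, behaviour, quantity,
    frequency, criteria, qfi (retained participants only at follow-up)."""
    rows = []
    for _, r in cohort.iterrows():
        for wave, suffix in (("baseline", "bl"), ("follow_up", "fu")):
            if wave == "follow_up" and not bool(r["retained"]):
                continue
            for b in BEHAVIOURS:
                q = float(r[f"{b}_quantity_{suffix}"])
                freq = r[f"{b}_freq_{suffix}"]
                rows.append(
                    {
                        "id": r["id"],
                        "wave": wave,
                        "behaviour": b,
                        "quantity": q,
                        "frequency": freq,
                        "criteria": int(r[f"{b}_criteria_{suffix}"]),
                        "qfi": compute_qfi(q, freq),
                    }
                )
    return pd.DataFrame(rows)
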