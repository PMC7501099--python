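"""Severity outcomes: criterion sums, quantity-frequency indices, change scores.

Addictive-disorder severity is tracked two ways at each wave:

* the number of fulfilled diagnostic criteria per disorder class
  (substance-related vs non-substance-related), and
* a quantity-frequency index (QFI) of engagement per behaviour —
  units per occasion (cigarettes, grams of ethanol, hours) times the
  weekly maximum of the reported frequency category.

QFIs are z-standardized in long format (pooling both waves) so different
behaviours are comparable, summed per disorder class, and the class sums
are z-standardized again.  Change outcomes are follow-up minus baseline,
z-standardized, with the baseline value retained as a covariate to guard
against regression to the mean.  A Tukey-fences filter supports the
extreme-value sensitivity analysis.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Frequency category -> maximum occasions per week.  Weekly scaling is
#: used because all QFIs are reported per week; configurable.
FREQ_PER_WEEK: dict[str, float] = {
    "almost_daily": 7.0,
    "3-4_per_week": 4.0,
    "1-2_per_week": 2.0,
    "1-3_per_month": 0.75,
    "less_than_monthly": 0.25,
}

#: Behaviour -> disorder class.
BEHAVIOUR_CLASS: dict[str, str] = {
    "tobacco": "sud",
    "alcohol": "sud",
    "internet": "nd",
    "gaming": "nd",
    "gambling": "nd",
    "shopping": "nd",
}

WAVES = ("baseline", "follow_up")


class DegenerateScaleError(ValueError):
    """A column to be standardized has no spread."""


def compute_qfi(quantity: float, frequency: str, per_week: Mapping[str, float] | None = None) -> float:
    """Quantity-frequency index: category weekly maximum times quantity."""
    per_week = FREQ_PER_WEEK if per_week is None else per_week
    if frequency not in per_week:
        raise ValueError(f"unknown frequency category {frequency!r}")
    if quantity < 0:
        raise ValueError("quantity must be >= 0")
    return per_week[frequency] * quantity


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Z-standardize with sample sd by default; error on constant input."""
    v = np.asarray(values, dtype=float)
    if np.unique(v[~np.isnan(v)]).size < 2:
        raise DegenerateScaleError("cannot standardize a constant column")
    sd = np.nanstd(v, ddof=ddof)
    return (v - np.nanmean(v)) / sd


def standardize_long(
    records: pd.DataFrame,
    value_col: str = "qfi",
    ddof: int = 1,
) -> pd.DataFrame:
    """Two-stage long-format standardization of per-behaviour values.

    Stage 1: z-standardize ``value_col`` per behaviour, pooling both
    waves.  Stage 2: sum the z-scores per (participant, wave, disorder
    class) and z-standardize the class sums again (pooled over waves).
    Returns a frame with columns id, wave, clazz, z_sum, z.
    """
    df = records.copy()
    df["clazz"] = df["behaviour"].map(BEHAVIOUR_CLASS)
    if df["clazz"].isna().any():
        bad = sorted(df.loc[df["clazz"].isna(), "behaviour"].unique())
        raise ValueError(f"unknown behaviours {bad}")
    df["value_z"] = df.groupby("behaviour")[value_col].transform(lambda s: zscore(s, ddof=ddof))
    sums = (
        df.groupby(["id", "wave", "clazz"], as_index=False)["value_z"]
        .sum()
        .rename(columns={"value_z": "z_sum"})
    )
    sums["z"] = sums.groupby("clazz")["z_sum"].transform(lambda s: zscore(s, ddof=ddof))
    return sums


def build_change_outcome(
    cohort: pd.DataFrame,
    severity_long: pd.DataFrame | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-participant standardized change outcomes with baseline covariates.

    Expects the wide cohort frame (``sud_criteria_bl`` etc. and a
    ``retained`` flag); ``severity_long`` optionally supplies the
    per-behaviour QFI records for the class-QFI outcomes.  Non-retained
    participants (or those missing a wave) are excluded.  Returns one row
    per retained participant with, per class, ``*_criteria_change_z`` and
    the z-scored baseline covariate; analogously for QFI when available.
    """
    df = cohort.copy()
    n_all = len(df)
    df = df[df["retained"].astype(bool)]
    missing = df[[c for c in ("sud_criteria_fu", "nd_criteria_fu") if c in df]].isna().any(axis=1)
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} retained participants missing a wave")
        df = df[~missing]
    if len(df) < n_all:
        pass  # non-retained excluded by contract
    out = pd.DataFrame({"id": df["id"].to_numpy()})
    for clazz in ("sud", "nd"):
        change = df[f"{clazz}_criteria_fu"].to_numpy(float) - df[f"{clazz}_criteria_bl"].to_numpy(float)
        out[f"{clazz}_criteria_change_z"] = zscore(change, ddof=ddof)
        out[f"{clazz}_criteria_bl_z"] = zscore(df[f"{clazz}_criteria_bl"].to_numpy(float), ddof=ddof)
    if severity_long is not None:
        sl = severity_long[severity_long["id"].isin(out["id"])]
        sums = standardize_long(sl, ddof=ddof)
        wide = sums.pivot_table(index="id", columns=["clazz", "wave"], values="z", observed=True)
        for clazz in ("sud", "nd"):
            change = (wide[(clazz, "follow_up")] - wide[(clazz, "baseline")]).reindex(out["id"]).to_numpy()
            out[f"{clazz}_qfi_change_z"] = zscore(change, ddof=ddof)
            out[f"{clazz}_qfi_bl_z"] = zscore(
                wide[(clazz, "baseline")].reindex(out["id"]).to_numpy(), ddof=ddof
            )
    return out


def tukey_filter(values) -> np.ndarray:
    """Inclusion mask by Tukey fences: keep Q1-1.5*IQR <= x <= Q3+1.5*IQR.

    Quartiles use linear-interpolation quantiles.  With zero IQR the
    fences collapse to the quartiles and equal values are all retained.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v >= lo) & (v <= hi)
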