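"""Published summary tables bundled as a fixture, and their conjugate check.

``printed_tables.csv`` holds, for every analysis block (group differences
per task and group; prediction models per task and severity outcome),
the published posterior, prior and likelihood rows: mean, 95% interval,
and — for posterior rows — the directional probability in percent.

``reproduce_posteriors`` re-derives every posterior row from its prior
and likelihood rows through the conjugate normal-normal combination
(intervals converted to sds via width / 3.9199) and reports the computed
posterior mean, interval and directional probability next to the printed
ones.  Agreement validates the precision-weighting reading of the
published analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .bayes import NormalSummary, combine_normal_summaries, directional_probability


def load_printed_tables() -> pd.DataFrame:
    """The bundled published prior/likelihood/posterior summary rows."""
    with resources.files("bayesdm.data").joinpath("printed_tables.csv").open() as fh:
        return pd.read_csv(fh)


def printed_summary(
    tables: pd.DataFrame, analysis: str, task: str, target: str, row: str
) -> NormalSummary:
    """One printed row as a NormalSummary (sd from the 95% interval)."""
    sel = tables[
        (tables["analysis"] == analysis)
        & (tables["task"] == task)
        & (tables["target"] == target)
        & (tables["row"] == row)
    ]
    if len(sel) != 1:
        raise KeyError(f"no unique row for {(analysis, task, target, row)}")
    r = sel.iloc[0]
    return NormalSummary.from_ci(float(r["mean"]), float(r["lower"]), float(r["upper"]))


def reproduce_posteriors(tables: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every posterior row from its printed prior and likelihood.

    Returns one row per analysis block with printed and computed
    posterior mean, 95% interval and directional probability.
    """
    if tables is None:
        tables = load_printed_tables()
    blocks = tables[tables["row"] == "posterior"][
        ["analysis", "task", "target", "mean", "lower", "upper", "probability", "direction"]
    ].rename(
        columns={
            "mean": "printed_mean",
            "lower": "printed_lower",
            "upper": "printed_upper",
            "probability": "printed_probability",
        }
    )
    rows = []
    for _, blk in blocks.iterrows():
        prior = printed_summary(tables, blk["analysis"], blk["task"], blk["target"], "prior")
        lik = printed_summary(tables, blk["analysis"], blk["task"], blk["target"], "likelihood")
        post = combine_normal_summaries(prior, lik)
        prob = directional_probability(post, blk["direction"])
        lo, hi = post.ci95
        rows.append(
            {
                **blk,
                "computed_mean": post.mean,
                "computed_lower": lo,
                "computed_upper": hi,
                "computed_probability": prob,
            }
        )
    return pd.DataFrame(rows)
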