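"""Reproduce the published posterior summaries by conjugate combination.

For every analysis block (group differences per task/group; prediction
models per task/outcome) the published prior and likelihood rows are
combined by precision weighting and compared with the published
posterior row.  Writes results/table_reproduction.csv.
"""

from pathlib import Path

import pandas as pd

from bayesdm.tables import reproduce_posteriors

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rep = reproduce_posteriors()
    OUT.mkdir(exist_ok=True)
    rep.to_csv(OUT / "table_reproduction.csv", index=False, float_format="%.4f")
    rep["dev"] = (rep["computed_mean"] - rep["printed_mean"]).abs()
    exact = rep[rep["dev"] <= 0.01]
    print(f"{len(rep)} posterior rows recomputed; {len(exact)} agree with the "
          f"printed mean within +-0.01.")
    print("Rows where the marginal conjugate combination deviates (these "
          "summaries come from the joint covariate-adjusted sampler):")
    for _, r in rep[rep["dev"] > 0.01].iterrows():
        print(f"  {r.analysis:10s} {r.task:13s} {r.target:12s} "
              f"printed {r.printed_mean:+.2f} vs conjugate {r.computed_mean:+.2f}")
    key = rep[(rep.analysis == "group_diff") & (rep.task == "delay") & (rep.target == "SUD")].iloc[0]
    print(f"\nHeadline: delay-discounting SUD contrast posterior "
          f"{key.computed_mean:.2f} (printed {key.printed_mean:.2f}), "
          f"directional probability {key.computed_probability:.1f}%.")


if __name__ == "__main__":
    main()
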