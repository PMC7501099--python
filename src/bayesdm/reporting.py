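"""Run configuration, artifact writing and table rendering.

Every pipeline run writes a manifest (seed, config SHA-256, package
version) next to its CSV/JSON artifacts so outputs are traceable and
byte-reproducible from config + seed.  No step touches the network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .bayes import McmcConfig
from .cohort import DEFAULT_ASSOC, DEFAULT_GROUP_SHIFT, CohortConfig

ANALYSES = (
    "group_differences",
    "predictions",
    "interactions",
    "reverse_bayes",
    "outlier_sensitivity",
)


@dataclasses.dataclass
class RunConfig:
    """Top-level configuration for a pipeline run."""

    seed: int = 0
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    mcmc: McmcConfig = dataclasses.field(default_factory=McmcConfig)
    analyses: tuple[str, ...] = ANALYSES
    n_task_agents: int = 20  # battery simulations in `simulate-tasks`

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")


def load_run_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file; flags override the file."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    run_seed = seed if seed is not None else int(raw.get("seed", 0))
    cohort_raw = dict(raw.get("cohort", {}))
    cohort_raw.setdefault("seed", run_seed)
    if "group_shift_z" in cohort_raw:
        merged = {t: dict(v) for t, v in DEFAULT_GROUP_SHIFT.items()}
        for t, v in cohort_raw["group_shift_z"].items():
            merged[t].update(v)
        cohort_raw["group_shift_z"] = merged
    if "assoc_z" in cohort_raw:
        merged_a = dict(DEFAULT_ASSOC)
        for key, v in cohort_raw["assoc_z"].items():
            task, outcome = key.split("->") if isinstance(key, str) else key
            merged_a[(task.strip(), outcome.strip())] = float(v)
        cohort_raw["assoc_z"] = merged_a
    mcmc_raw = dict(raw.get("mcmc", {}))
    mcmc_raw.setdefault("seed", run_seed)
    return RunConfig(
        seed=run_seed,
        cohort=CohortConfig(**cohort_raw),
        mcmc=McmcConfig(**mcmc_raw),
        analyses=tuple(raw.get("analyses", ANALYSES)),
        n_task_agents=int(raw.get("n_task_agents", 20)),
    )


def _jsonable(obj):
    """Recursively convert dataclasses/mappings to JSON-safe structures
    (tuple keys like ``(task, outcome)`` become ``"task->outcome"``)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {
            "->".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True, ensure_ascii=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "analyses": list(config.analyses),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.4f") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return path


def render_report(table: pd.DataFrame, digits: int = 2) -> str:
    """Plain-text posterior/prior/likelihood report in the published layout."""
    lines = []
    for (analysis, task, target), grp in table.groupby(
        ["analysis", "task", "target"], sort=False
    ):
        direction = grp["direction"].iloc[0]
        arrow = ">" if direction == "greater" else "<"
        lines.append(f"{analysis} | {task} | {target}   (effect {arrow} 0)")
        order = {"posterior": 0, "prior": 1, "likelihood": 2}
        for _, r in grp.sort_values("row", key=lambda s: s.map(order)).iterrows():
            prob = "" if pd.isna(r.get("probability")) else f"  {r['probability']:.0f}%"
            lines.append(
                f"  {r['row']:<10} {r['mean']:.{digits}f}  "
                f"[{r['lower']:.{digits}f}, {r['upper']:.{digits}f}]{prob}"
            )
    return "\n".join(lines) + "\n"
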