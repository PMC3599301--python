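"""End-to-end experiment runner: simulate → validate (CV and 3WS) → power/ANOVA.

Seeding contract: every (scenario, replicate) unit derives its random streams
from the master seed through ``numpy.random.SeedSequence`` spawn keys
``(scenario_id, replicate, purpose)`` with purpose 0 = data simulation,
1 = CV splitting, 2 = 3WS splitting.  Unit seeds therefore do not depend on
execution order, and a rerun with the same master seed reproduces every
selection exactly.  Runs are resumable: completed (scenario, replicate, method)
rows found in ``selections.csv`` are skipped, provided the stored config hash
matches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_mdr_file
from .power import POWER_DEFINITIONS, aggregate, anova, classify_outcome, render_results
from .scenarios import enumerate_scenarios, scenario_design
from .simulate import simulate_dataset
from .validation import CV, TWS, SplitSpec, select_model


@dataclass
class ExperimentConfig:
    """Configuration of one full simulation experiment."""

    scenario_ids: tuple[int, ...] | None = None  # None = all 21
    n_replicates: int = 25
    n_cases: int = 500
    n_controls: int = 500
    n_total_loci: int = 25
    maf_noise: float = 0.5
    target_h2: float = 0.05
    methods: tuple[str, ...] = (CV, TWS)
    master_seed: int = 0
    tws_x: int | None = None  # None = number of loci
    n_workers: int = 1  # accepted for interface stability; execution is serial
    write_datasets: bool = False

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        for method in self.methods:
            if method not in (CV, TWS):
                raise ValueError(f"unknown method {method!r}")

    def k_max_for(self, scenario) -> int:
        """Search depth rule: k = 2 for two-locus scenarios, 4 for four-locus."""
        return scenario.n_disease_loci

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario_ids"] = list(self.scenario_ids) if self.scenario_ids else None
        d["methods"] = list(self.methods)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("scenario_ids"):
            raw["scenario_ids"] = tuple(raw["scenario_ids"])
        if raw.get("methods"):
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


class ConfigMismatchError(RuntimeError):
    """An existing partial run was produced under a different configuration."""


def unit_seed(master_seed: int, scenario_id: int, replicate: int, purpose: int):
    """Counter-based sub-seed for one unit of work (see module docstring)."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(scenario_id, replicate, purpose)
    )


def analyze_dataset(dataset, k_max: int, method: str, seed) -> dict:
    """Run one validation method on one dataset and flatten the result to a row."""
    spec = SplitSpec(method=method, seed=seed)
    selected = select_model(dataset, k_max, spec)
    return {
        "method": method,
        "loci": "|".join(str(l) for l in selected.loci),
        "size": selected.size,
        "cv_consistency": selected.cv_consistency if method == CV else "",
        "prediction_accuracy": selected.prediction_accuracy,
    }


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute the full experiment and write the results directory.

    Layout: ``manifest.json``, ``selections.csv`` (one row per scenario x
    replicate x method), ``power.csv``, ``size_stats.csv``, ``anova.csv``,
    ``figures/`` and, when ``config.write_datasets`` is set, ``datasets/`` with
    MDR flat files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    selections_path = out_dir / "selections.csv"

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": __version__,
    }
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != manifest["config_hash"]:
            raise ConfigMismatchError(
                f"{out_dir} holds a partial run with config hash "
                f"{previous.get('config_hash')}, but this run has "
                f"{manifest['config_hash']}; use a fresh output directory"
            )
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    all_scenarios = enumerate_scenarios(
        target_h2=config.target_h2, n_total_loci=config.n_total_loci
    )
    wanted = set(config.scenario_ids) if config.scenario_ids else None
    scenarios = [s for s in all_scenarios if wanted is None or s.scenario_id in wanted]
    truth_by_id = {s.scenario_id: s for s in scenarios}

    done: set[tuple[int, int, str]] = set()
    rows: list[dict] = []
    if selections_path.exists():
        existing = pd.read_csv(selections_path, keep_default_na=False)
        rows = existing.to_dict("records")
        done = {
            (int(r["scenario_id"]), int(r["replicate"]), str(r["method"])) for r in rows
        }

    columns = [
        "scenario_id", "replicate", "method", "loci", "size",
        "cv_consistency", "prediction_accuracy",
    ]
    if config.write_datasets:
        (out_dir / "datasets").mkdir(exist_ok=True)

    for scenario in scenarios:
        sid = scenario.scenario_id
        k_max = config.k_max_for(scenario)
        new_rows = False
        for rep in range(config.n_replicates):
            pending = [m for m in config.methods if (sid, rep, m) not in done]
            if not pending and not config.write_datasets:
                continue
            dataset = simulate_dataset(
                scenario,
                n_cases=config.n_cases,
                n_controls=config.n_controls,
                maf_noise=config.maf_noise,
                seed=unit_seed(config.master_seed, sid, rep, 0),
            )
            if config.write_datasets:
                write_mdr_file(
                    dataset, out_dir / "datasets" / f"scenario{sid:02d}_rep{rep:03d}.txt"
                )
            for method in pending:
                purpose = 1 if method == CV else 2
                row = analyze_dataset(
                    dataset, k_max, method, unit_seed(config.master_seed, sid, rep, purpose)
                )
                rows.append({"scenario_id": sid, "replicate": rep, **row})
                done.add((sid, rep, method))
                new_rows = True
        if new_rows:  # checkpoint after each scenario so runs are resumable
            pd.DataFrame(rows, columns=columns).to_csv(selections_path, index=False)

    selections = pd.DataFrame(rows, columns=columns)
    selections = selections.sort_values(["scenario_id", "replicate", "method"])
    selections.to_csv(selections_path, index=False)

    records = selections.copy()
    flags = [
        classify_outcome(
            [int(l) for l in str(r["loci"]).split("|")], truth_by_id[int(r["scenario_id"])]
        ).as_dict()
        for r in records.to_dict("records")
    ]
    for name in POWER_DEFINITIONS:
        records[name] = [f[name] for f in flags]

    power_table = aggregate(records)
    anova_result = None
    design = scenario_design()
    methods_present = records["method"].nunique()
    scenarios_present = records["scenario_id"].nunique()
    if methods_present == 2 and scenarios_present >= 8:
        # the factorial ANOVA needs both methods and enough scenarios to
        # estimate all four main effects
        anova_result = anova(power_table, design)
    render_results(power_table, out_dir, anova_result=anova_result)

    figures = out_dir / "figures"
    figures.mkdir(exist_ok=True)
    for png in out_dir.glob("power_*.png"):
        png.replace(figures / png.name)
    return out_dir
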