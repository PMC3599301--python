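"""Scoring selected models against ground truth; power aggregation; ANOVA.

Six success definitions compare the selected locus set to the two true
submodels' loci L1 and L2:

* ``conservative`` — exactly L1 ∪ L2 (all true disease loci, nothing else);
* ``mod1`` / ``mod2`` — L1 (resp. L2) is contained in the selection;
* ``onlymod1`` / ``onlymod2`` — the selection is exactly L1 (resp. L2);
* ``nofalse`` — the selection contains no false-positive locus (subset of L1 ∪ L2).

Power is the percentage of replicates meeting a definition, per
(scenario, method).  The factorial ANOVA regresses each power definition on the
main effects of validation method, heterogeneity level, model type and
odds-ratio class (Type-II sums of squares via statsmodels OLS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scenarios import HeterogeneityScenario

POWER_DEFINITIONS = ("conservative", "mod1", "onlymod1", "mod2", "onlymod2", "nofalse")

ANOVA_EFFECTS = ("method", "heterogeneity", "model_type", "odds_ratio")


@dataclass(frozen=True)
class OutcomeFlags:
    conservative: bool
    mod1: bool
    onlymod1: bool
    mod2: bool
    onlymod2: bool
    nofalse: bool

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in POWER_DEFINITIONS}


def classify_outcome(selected_loci, truth: HeterogeneityScenario) -> OutcomeFlags:
    """Apply the six success definitions to one selected locus set."""
    selected = set(int(l) for l in selected_loci)
    if not selected:
        raise ValueError("selected locus set is empty; MDR always returns at least one locus")
    L1, L2 = set(truth.loci1), set(truth.loci2)
    if L1 & L2:
        raise ValueError("truth submodel loci must be disjoint")
    return OutcomeFlags(
        conservative=selected == L1 | L2,
        mod1=L1 <= selected,
        onlymod1=selected == L1,
        mod2=L2 <= selected,
        onlymod2=selected == L2,
        nofalse=selected <= L1 | L2,
    )


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(scenario, method) power table from per-replicate outcome records.

    ``records`` needs columns ``scenario_id``, ``method``, ``size`` and one
    boolean column per power definition.  Powers are percentages; the model-size
    mode breaks ties toward the smaller size.
    """
    required = {"scenario_id", "method", "size", *POWER_DEFINITIONS}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    rows = []
    for (sid, method), grp in records.groupby(["scenario_id", "method"], sort=True):
        n = len(grp)
        sizes = grp["size"].to_numpy()
        values, counts = np.unique(sizes, return_counts=True)
        mode = int(values[counts == counts.max()].min())
        row = {
            "scenario_id": sid,
            "method": method,
            "n_replicates": n,
            "mean_size": float(sizes.mean()),
            "mode_size": mode,
        }
        for name in POWER_DEFINITIONS:
            successes = int(grp[name].sum())
            row[f"count_{name}"] = successes
            row[f"power_{name}"] = 100.0 * successes / n
        rows.append(row)
    return pd.DataFrame(rows).set_index(["scenario_id", "method"])


def anova(power_table: pd.DataFrame, design: dict[int, dict[str, str]]) -> pd.DataFrame:
    """Main-effects ANOVA of each power definition on the simulation factors.

    ``design`` maps scenario_id to its factor levels (model_type,
    heterogeneity, odds_ratio); the validation method is the fourth factor.
    Returns a DataFrame of F-test p-values, effects x power definitions.
    """
    df = power_table.reset_index()
    for factor in ("model_type", "heterogeneity", "odds_ratio"):
        df[factor] = df["scenario_id"].map(lambda sid: design[sid][factor])

    terms = ["C(method)", "C(heterogeneity)", "C(model_type)", "C(odds_ratio)"]
    pvals = {}
    for name in POWER_DEFINITIONS:
        formula = f"power_{name} ~ " + " + ".join(terms)
        model = smf.ols(formula, data=df)
        exog = model.exog
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            aliased = _aliased_terms(model)
            raise ValueError(
                f"rank-deficient ANOVA design for {name}: aliased terms {aliased}"
            )
        table = sm.stats.anova_lm(model.fit(), typ=2)
        pvals[name] = {
            "method": table.loc["C(method)", "PR(>F)"],
            "heterogeneity": table.loc["C(heterogeneity)", "PR(>F)"],
            "model_type": table.loc["C(model_type)", "PR(>F)"],
            "odds_ratio": table.loc["C(odds_ratio)", "PR(>F)"],
        }
    out = pd.DataFrame(pvals)
    out.index.name = "effect"
    return out.loc[list(ANOVA_EFFECTS)]


def _aliased_terms(model) -> list[str]:
    names = model.exog_names
    exog = model.exog
    keep, aliased = [], []
    for j, name in enumerate(names):
        trial = exog[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(name)
    return aliased


def render_results(
    power_table: pd.DataFrame,
    out_dir,
    anova_result: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the power/size CSV tables and the four power bar charts.

    Deterministic given the table: ``power.csv`` and ``size_stats.csv`` are
    byte-stable, and one figure is produced per family of power definitions
    (conservative; mod1/mod2; onlymod1/onlymod2; nofalse), each comparing the
    two validation methods across scenarios.
    """
    if power_table.empty:
        raise ValueError("cannot render an empty power table")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    power_cols = [f"power_{name}" for name in POWER_DEFINITIONS]
    power_csv = out_dir / "power.csv"
    power_table[["n_replicates", *power_cols]].to_csv(power_csv, float_format="%.6g")
    written.append(power_csv)

    size_csv = out_dir / "size_stats.csv"
    power_table[["n_replicates", "mean_size", "mode_size"]].to_csv(
        size_csv, float_format="%.6g"
    )
    written.append(size_csv)

    if anova_result is not None:
        anova_csv = out_dir / "anova.csv"
        anova_result.to_csv(anova_csv, float_format="%.6g")
        written.append(anova_csv)

    wide = power_table.reset_index()
    methods = sorted(wide["method"].unique())
    scenarios = sorted(wide["scenario_id"].unique())
    families = [
        ("conservative", ["conservative"]),
        ("mod", ["mod1", "mod2"]),
        ("onlymod", ["onlymod1", "onlymod2"]),
        ("nofalse", ["nofalse"]),
    ]
    for family, names in families:
        fig, axes = plt.subplots(
            len(names), 1, figsize=(10, 3.2 * len(names)), squeeze=False, sharex=True
        )
        for ax, name in zip(axes[:, 0], names):
            width = 0.8 / len(methods)
            xs = np.arange(len(scenarios))
            for i, method in enumerate(methods):
                sub = wide[wide["method"] == method].set_index("scenario_id")
                vals = [sub.loc[s, f"power_{name}"] for s in scenarios]
                ax.bar(xs + i * width, vals, width=width, label=method.upper())
            ax.set_ylabel(f"{name} power (%)")
            ax.set_ylim(0, 100)
            ax.legend(frameon=False)
        axes[-1, 0].set_xticks(xs + 0.4 - width / 2)
        axes[-1, 0].set_xticklabels([str(s) for s in scenarios])
        axes[-1, 0].set_xlabel("simulation scenario")
        fig.tight_layout()
        fig_path = out_dir / f"power_{family}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        written.append(fig_path)
    return written
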