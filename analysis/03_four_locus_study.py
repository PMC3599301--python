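#!/usr/bin/env python
"""Run the four-locus XOR heterogeneity experiment (scenarios 15-21) at desk scale.

Each scenario mixes two two-locus XOR submodels (purely epistatic: no marginal
single-locus effects at allele frequency 0.5); MDR searches models of size 1-4.
Desk default: 8 replicates per scenario (the size-4 search over C(25,4) = 12650
locus quadruples dominates the runtime; scripts/acceptance.py runs 20).

Writes results/four_locus/.
"""

from pathlib import Path

import pandas as pd

from hetmdr import ExperimentConfig, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "four_locus"


def main():
    config = ExperimentConfig(
        scenario_ids=tuple(range(15, 22)),
        n_replicates=8,
        master_seed=1,
    )
    run_experiment(config, OUT)
    sel = pd.read_csv(OUT / "selections.csv")
    sizes = sel.groupby("method")["size"].agg(["mean", lambda s: s.mode().min()])
    sizes.columns = ["mean_size", "mode_size"]
    print(sizes)
    print(
        "\nWith four sizes on offer, the three-way split's validate-stage refit "
        "almost always rewards the size-4 model; CV stays small."
    )
    print(f"results in {OUT}")


if __name__ == "__main__":
    main()
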