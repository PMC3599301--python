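#!/usr/bin/env python
"""Construct the six penetrance models of the simulation grid.

Solves each (model type, odds ratio) pair for heritability 0.05 under the
odds-structured penetrance patterns and tabulates what each model actually
realises.  For five of the six pairs the odds-ratio constraint bounds the
attainable heritability below 0.05 (see docs/methods.md); those models are
built at their heritability ceiling, which the table reports.

Writes results/penetrance_models.csv.
"""

from pathlib import Path

import pandas as pd

from hetmdr import build_penetrance

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    rows = []
    for model_type in ("additive", "recessive", "xor"):
        for odds in (1.5, 2.0):
            m = build_penetrance(model_type, odds, 0.05, on_infeasible="cap")
            rows.append(
                {
                    "model_type": model_type,
                    "target_or": odds,
                    "realized_or": round(m.realized_or, 6),
                    "target_h2": 0.05,
                    "realized_h2": round(m.realized_h2, 6),
                    "h2_at_ceiling": m.h2_capped,
                    "maf": m.maf,
                    "baseline_penetrance": round(m.baseline_penetrance, 6),
                    "prevalence": round(m.prevalence, 6),
                }
            )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "penetrance_models.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {OUT / 'penetrance_models.csv'}")
    capped = table[table.h2_at_ceiling]
    print(
        f"\n{len(capped)} of 6 models sit at their heritability ceiling: holding the "
        "penetrance odds ratio at 1.5 or 2 caps h2 below the 0.05 target."
    )


if __name__ == "__main__":
    main()
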