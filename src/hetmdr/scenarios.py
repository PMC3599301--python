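"""The 21 two-component genetic heterogeneity scenarios of the simulation study.

Each scenario mixes two penetrance models: individuals are assigned to the first
submodel with probability ``weight1`` and to the second otherwise, and disease
status then depends only on the assigned submodel's loci.  Scenarios 1-7 mix two
additive single-locus models (2 disease loci), 8-14 two recessive single-locus
models (2 disease loci), and 15-21 two two-locus XOR models (4 disease loci).
Mixing weights are 25/75 or 50/50 and per-submodel odds ratios are 1.5 or 2,
each submodel solved for heritability 0.05 (capped at the structure's attainable
maximum where the odds-ratio constraint makes 0.05 unreachable; see
``penetrance``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .penetrance import PenetranceModel, build_penetrance

#: (scenario_id, model_type, heterogeneity, or1, weight1, or2, weight2)
SCENARIO_TABLE = [
    (1, "additive", "25/75", 1.5, 0.25, 1.5, 0.75),
    (2, "additive", "25/75", 2.0, 0.25, 2.0, 0.75),
    (3, "additive", "25/75", 1.5, 0.25, 2.0, 0.75),
    (4, "additive", "25/75", 2.0, 0.25, 1.5, 0.75),
    (5, "additive", "50/50", 1.5, 0.50, 1.5, 0.50),
    (6, "additive", "50/50", 2.0, 0.50, 2.0, 0.50),
    (7, "additive", "50/50", 1.5, 0.50, 2.0, 0.50),
    (8, "recessive", "25/75", 1.5, 0.25, 1.5, 0.75),
    (9, "recessive", "25/75", 2.0, 0.25, 2.0, 0.75),
    (10, "recessive", "25/75", 1.5, 0.25, 2.0, 0.75),
    (11, "recessive", "25/75", 2.0, 0.25, 1.5, 0.75),
    (12, "recessive", "50/50", 1.5, 0.50, 1.5, 0.50),
    (13, "recessive", "50/50", 2.0, 0.50, 2.0, 0.50),
    (14, "recessive", "50/50", 1.5, 0.50, 2.0, 0.50),
    (15, "xor", "25/75", 1.5, 0.25, 1.5, 0.75),
    (16, "xor", "25/75", 2.0, 0.25, 2.0, 0.75),
    (17, "xor", "25/75", 1.5, 0.25, 2.0, 0.75),
    (18, "xor", "25/75", 2.0, 0.25, 1.5, 0.75),
    (19, "xor", "50/50", 1.5, 0.50, 1.5, 0.50),
    (20, "xor", "50/50", 2.0, 0.50, 2.0, 0.50),
    (21, "xor", "50/50", 1.5, 0.50, 2.0, 0.50),
]

DEFAULT_N_LOCI = 25
DEFAULT_H2 = 0.05


@dataclass(frozen=True)
class HeterogeneityScenario:
    """One row of the simulated-model grid: two submodels plus mixing weights."""

    scenario_id: int
    model_type: str
    heterogeneity: str  # "25/75" or "50/50"
    model1: PenetranceModel
    model2: PenetranceModel
    weight1: float
    weight2: float
    loci1: tuple[int, ...]
    loci2: tuple[int, ...]
    n_total_loci: int = DEFAULT_N_LOCI

    def __post_init__(self):
        if abs(self.weight1 + self.weight2 - 1.0) > 1e-12:
            raise ValueError("mixing weights must sum to 1")
        if set(self.loci1) & set(self.loci2):
            raise ValueError("submodel disease loci must be disjoint")
        if len(self.loci1) != self.model1.n_loci or len(self.loci2) != self.model2.n_loci:
            raise ValueError("locus tuples must match submodel arity")
        if max(self.disease_loci) >= self.n_total_loci:
            raise ValueError("disease loci out of range")

    @property
    def disease_loci(self) -> tuple[int, ...]:
        return self.loci1 + self.loci2

    @property
    def n_disease_loci(self) -> int:
        return len(self.disease_loci)

    @property
    def n_noise_loci(self) -> int:
        return self.n_total_loci - self.n_disease_loci


def enumerate_scenarios(
    target_h2: float = DEFAULT_H2,
    n_total_loci: int = DEFAULT_N_LOCI,
    maf: float = 0.5,
) -> list[HeterogeneityScenario]:
    """Construct all 21 heterogeneity scenarios of the study grid, in order.

    Submodels are built with ``on_infeasible="cap"`` so that the grid exists for
    every nominal odds ratio; disease loci occupy the first 2 (single-locus
    submodels) or 4 (XOR submodels) columns, with submodel 1 first.
    """
    cache: dict[tuple[str, float], PenetranceModel] = {}

    def model(model_type: str, odds_ratio: float) -> PenetranceModel:
        key = (model_type, odds_ratio)
        if key not in cache:
            cache[key] = build_penetrance(
                model_type, odds_ratio, target_h2, maf=maf, on_infeasible="cap"
            )
        return cache[key]

    scenarios = []
    for sid, mtype, het, or1, w1, or2, w2 in SCENARIO_TABLE:
        m1, m2 = model(mtype, or1), model(mtype, or2)
        if mtype == "xor":
            loci1, loci2 = (0, 1), (2, 3)
        else:
            loci1, loci2 = (0,), (1,)
        scenarios.append(
            HeterogeneityScenario(
                scenario_id=sid,
                model_type=mtype,
                heterogeneity=het,
                model1=m1,
                model2=m2,
                weight1=w1,
                weight2=w2,
                loci1=loci1,
                loci2=loci2,
                n_total_loci=n_total_loci,
            )
        )
    return scenarios


def scenario_design() -> dict[int, dict[str, str]]:
    """Factor levels per scenario for the factorial analysis of the power results.

    The odds-ratio factor is coded unordered ({both 1.5, both 2, mixed}) because
    the ordered "2/1.5" arrangement occurs only at 25/75 heterogeneity and would
    otherwise be entangled with the heterogeneity factor.
    """
    design = {}
    for sid, mtype, het, or1, _w1, or2, _w2 in SCENARIO_TABLE:
        ors = sorted([or1, or2])
        or_class = "mixed" if ors[0] != ors[1] else f"both {ors[0]:g}"
        design[sid] = {
            "model_type": mtype,
            "heterogeneity": het,
            "odds_ratio": or_class,
        }
    return design
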