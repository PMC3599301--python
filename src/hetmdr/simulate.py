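"""Balanced case-control dataset simulation under two-component heterogeneity.

Each individual is assigned to one of the two submodels (probability ``weight1``
for the first), genotypes at all loci are drawn independently under
Hardy-Weinberg equilibrium (disease loci at the submodels' risk-allele
frequency, noise loci at ``maf_noise``), and disease status is a Bernoulli draw
from the assigned submodel's penetrance evaluated at that submodel's loci only.
Rejection sampling then retains individuals until exactly ``n_cases`` cases and
``n_controls`` controls are collected, emulating case-control ascertainment from
an unbounded source population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import HeterogeneityScenario


class SamplingStallError(RuntimeError):
    """Case/control ascertainment failed to fill within the attempt cap."""


@dataclass
class Dataset:
    """A simulated (or loaded) case-control genotype dataset."""

    genotypes: np.ndarray  # (N, K) int8, minor/risk-allele counts in {0, 1, 2}
    status: np.ndarray  # (N,) int8, 1 = case
    locus_names: list[str]
    truth: HeterogeneityScenario | None = None
    seed: int | None = None
    submodel: np.ndarray | None = None  # (N,) int8 in {1, 2}; diagnostics only

    @property
    def n_individuals(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == 0))


def default_locus_names(n_loci: int) -> list[str]:
    return [f"L{i + 1}" for i in range(n_loci)]


def simulate_dataset(
    scenario: HeterogeneityScenario,
    n_cases: int = 500,
    n_controls: int = 500,
    maf_noise: float = 0.5,
    seed=None,
    max_attempts: int = 10_000_000,
) -> Dataset:
    """Draw a balanced case-control dataset from a heterogeneity scenario.

    Reproducible given ``seed`` (any ``numpy.random.default_rng`` seed).  Raises
    :class:`SamplingStallError` if the scenario's prevalence is so extreme that
    one class cannot be filled within ``max_attempts`` sampled individuals.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    rng = np.random.default_rng(seed)
    K = scenario.n_total_loci

    maf = np.full(K, maf_noise)
    for locus in scenario.loci1:
        maf[locus] = scenario.model1.maf
    for locus in scenario.loci2:
        maf[locus] = scenario.model2.maf

    lut1 = scenario.model1.penetrance_lookup()
    lut2 = scenario.model2.penetrance_lookup()
    loci1, loci2 = list(scenario.loci1), list(scenario.loci2)

    geno_parts, status_parts, sub_parts = [], [], []
    need_cases, need_controls = n_cases, n_controls
    attempts = 0
    batch = max(1024, 2 * (n_cases + n_controls))

    while need_cases > 0 or need_controls > 0:
        if attempts >= max_attempts:
            raise SamplingStallError(
                f"drew {attempts} individuals without filling {need_cases} cases / "
                f"{need_controls} controls; scenario prevalence is too extreme"
            )
        n = min(batch, max_attempts - attempts)
        attempts += n
        geno = rng.binomial(2, maf, size=(n, K)).astype(np.int8)
        assign1 = rng.random(n) < scenario.weight1
        pen = np.where(
            assign1,
            lut1[tuple(geno[:, loc] for loc in loci1)],
            lut2[tuple(geno[:, loc] for loc in loci2)],
        )
        status = (rng.random(n) < pen).astype(np.int8)

        case_rows = np.flatnonzero(status == 1)[:need_cases]
        ctrl_rows = np.flatnonzero(status == 0)[:need_controls]
        keep = np.sort(np.concatenate([case_rows, ctrl_rows]))
        if keep.size:
            geno_parts.append(geno[keep])
            status_parts.append(status[keep])
            sub_parts.append(np.where(assign1[keep], 1, 2).astype(np.int8))
            need_cases -= case_rows.size
            need_controls -= ctrl_rows.size

    return Dataset(
        genotypes=np.concatenate(geno_parts),
        status=np.concatenate(status_parts),
        locus_names=default_locus_names(K),
        truth=scenario,
        seed=seed if isinstance(seed, int) else None,
        submodel=np.concatenate(sub_parts),
    )
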