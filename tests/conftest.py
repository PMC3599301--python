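"""Shared fixtures: small synthetic datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hetmdr import Dataset, enumerate_scenarios


@pytest.fixture(scope="session")
def scenarios():
    """The full 21-scenario grid (session-scoped: solver runs once)."""
    return enumerate_scenarios()


@pytest.fixture(scope="session")
def scenario_by_id(scenarios):
    return {s.scenario_id: s for s in scenarios}


def random_dataset(rng, n=60, K=6, case_fraction=0.5) -> Dataset:
    """Pure-noise case-control data: genotypes independent of status."""
    genotypes = rng.integers(0, 3, size=(n, K)).astype(np.int8)
    n_cases = int(round(n * case_fraction))
    status = np.array([1] * n_cases + [0] * (n - n_cases), dtype=np.int8)
    rng.shuffle(status)
    return Dataset(genotypes, status, [f"L{i+1}" for i in range(K)])


def planted_dataset(rng, n=80, K=6, locus=2) -> Dataset:
    """One locus perfectly determines status (genotype 2 = case)."""
    status = np.array([1] * (n // 2) + [0] * (n - n // 2), dtype=np.int8)
    rng.shuffle(status)
    genotypes = rng.integers(0, 3, size=(n, K)).astype(np.int8)
    genotypes[:, locus] = np.where(status == 1, 2, rng.integers(0, 2, size=n))
    return Dataset(genotypes, status, [f"L{i+1}" for i in range(K)])


@pytest.fixture
def rng():
    return np.random.default_rng(20120623)
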