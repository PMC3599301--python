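"""The MDR engine: multifactor tabulation, risk classification, scoring, search.

Multifactor Dimensionality Reduction pools the ``3**k`` genotype combinations
("multifactor classes") of a k-locus model into two classes: a cell is
high-risk when its case:control count ratio reaches the sample-wide ratio
``n1/n0`` (so exactly 1 for balanced data), low-risk otherwise.  The resulting
one-dimensional classifier is scored by balanced accuracy, the mean of
sensitivity and specificity, which coincides with raw accuracy on balanced
data.  The exhaustive search evaluates every combination of s loci for
s = 1..k_max and ranks them by training balanced accuracy.

The array helpers at the bottom (`all_combinations`, `cell_indices`,
`count_by_group`, `classify_counts`, `balanced_accuracy_counts`) are the
vectorised batch path used by the validation strategies; the scalar API above
them mirrors the textbook description and is cross-checked against naive
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .simulate import Dataset


class UndefinedAccuracyError(ValueError):
    """Balanced accuracy is undefined when the evaluation data lack a class."""


@dataclass(frozen=True)
class MultifactorTable:
    """Case/control counts over the ``3**k`` genotype combinations of ``loci``.

    Cell index is mixed-radix with the first locus least significant:
    ``cell = sum(g_i * 3**i)``.
    """

    loci: tuple[int, ...]
    case_counts: np.ndarray
    control_counts: np.ndarray

    @property
    def n_cells(self) -> int:
        return 3 ** len(self.loci)

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())


@dataclass(frozen=True)
class RiskClassification:
    """High/low-risk call per multifactor class, at a given threshold."""

    loci: tuple[int, ...]
    high_risk: np.ndarray  # bool over 3**k cells
    threshold: float


@dataclass(frozen=True)
class ModelScore:
    loci: tuple[int, ...]
    train_balanced_accuracy: float
    eval_balanced_accuracy: float | None = None


def _genotype_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, Dataset):
        return data.genotypes, data.status
    genotypes, status = data
    return np.asarray(genotypes), np.asarray(status)


def tabulate(data, loci) -> MultifactorTable:
    """Count cases and controls in every multifactor class of ``loci``."""
    genotypes, status = _genotype_matrix(data)
    loci = tuple(int(l) for l in loci)
    if len(set(loci)) != len(loci):
        raise ValueError(f"loci must be distinct, got {loci}")
    if genotypes.shape[0] == 0:
        raise ValueError("cannot tabulate an empty dataset")
    if any(l < 0 or l >= genotypes.shape[1] for l in loci):
        raise ValueError(f"loci {loci} out of range for K={genotypes.shape[1]}")
    cells = cell_indices(genotypes, np.array([loci]))[:, 0]
    n_cells = 3 ** len(loci)
    case_counts = np.bincount(cells[status == 1], minlength=n_cells)
    control_counts = np.bincount(cells[status == 0], minlength=n_cells)
    return MultifactorTable(loci, case_counts, control_counts)


def classify(table: MultifactorTable, threshold: float) -> RiskClassification:
    """Call each cell high-risk iff cases/controls >= threshold.

    Cells with cases and no controls have ratio +inf (high-risk); empty cells
    (0/0) are low-risk.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    cases, controls = table.case_counts, table.control_counts
    high = cases >= threshold * controls
    high &= (cases + controls) > 0
    return RiskClassification(table.loci, high, float(threshold))


def balanced_accuracy(classification: RiskClassification, eval_table: MultifactorTable) -> float:
    """(sensitivity + specificity) / 2 of the classification on ``eval_table``."""
    if classification.loci != eval_table.loci:
        raise ValueError("classification and evaluation table refer to different loci")
    n1, n0 = eval_table.n_cases, eval_table.n_controls
    if n1 == 0 or n0 == 0:
        raise UndefinedAccuracyError("evaluation data must contain both cases and controls")
    high = classification.high_risk
    sensitivity = eval_table.case_counts[high].sum() / n1
    specificity = eval_table.control_counts[~high].sum() / n0
    return float((sensitivity + specificity) / 2.0)


def exhaustive_search(data, k_max: int) -> dict[int, list[ModelScore]]:
    """Evaluate every combination of s loci for s = 1..k_max on the supplied data.

    Each combination is scored by the balanced accuracy of its own fitted
    high/low-risk classification (training accuracy, threshold n1/n0).  Returns,
    per size, the full ranked list (descending accuracy, ties in ascending
    lexicographic locus order).
    """
    genotypes, status = _genotype_matrix(data)
    K = genotypes.shape[1]
    if not (1 <= k_max <= K):
        raise ValueError(f"k_max must lie in [1, {K}], got {k_max}")
    n1, n0 = int((status == 1).sum()), int((status == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAccuracyError("data must contain both cases and controls")

    group = (status == 1).astype(np.intp)  # 0 = control stratum, 1 = case stratum
    results: dict[int, list[ModelScore]] = {}
    for s in range(1, k_max + 1):
        combos = all_combinations(K, s)
        counts = count_by_group(genotypes, combos, group, 2)
        ctrl, case = counts[..., 0], counts[..., 1]
        high = classify_counts(case, ctrl, n1, n0)
        acc = balanced_accuracy_counts(high, case, ctrl, n1, n0)
        order = np.lexsort((np.arange(len(combos)), -acc))
        results[s] = [
            ModelScore(tuple(combos[i]), float(acc[i])) for i in order
        ]
    return results


# ---------------------------------------------------------------------------
# vectorised batch helpers


def all_combinations(K: int, s: int) -> np.ndarray:
    """All C(K, s) locus combinations, lexicographic, as an (C, s) int array."""
    if not (1 <= s <= K):
        raise ValueError(f"combination size {s} out of range for K={K}")
    out = np.fromiter(
        (l for combo in combinations(range(K), s) for l in combo),
        dtype=np.int64,
        count=comb(K, s) * s,
    )
    return out.reshape(-1, s)


def cell_indices(genotypes: np.ndarray, combos: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Mixed-radix cell index of every individual under every combination.

    Returns an (N, C) int32 array; ``chunk`` bounds the temporary gather size.
    """
    N = genotypes.shape[0]
    C, s = combos.shape
    out = np.empty((N, C), dtype=np.int32)
    for start in range(0, C, chunk):
        block = combos[start : start + chunk]
        out[:, start : start + chunk] = _cells_for_block(genotypes, block)
    return out


def _cells_for_block(genotypes: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Horner-style mixed-radix index for one block of combinations."""
    cells = genotypes[:, block[:, 0]].astype(np.int32)  # (N, c)
    for j in range(1, block.shape[1]):
        cells += genotypes[:, block[:, j]].astype(np.int32) * (3 ** j)
    return cells


def count_by_group(
    genotypes: np.ndarray,
    combos: np.ndarray,
    group: np.ndarray,
    n_groups: int,
    chunk: int = 4096,
) -> np.ndarray:
    """Cell counts per combination and individual group.

    ``group`` assigns each individual to one of ``n_groups`` strata (e.g.
    fold x status).  Returns an int32 array of shape (C, 3**s, n_groups).
    """
    C, s = combos.shape
    n_cells = 3 ** s
    group = np.asarray(group)
    rows_by_group = [np.flatnonzero(group == g) for g in range(n_groups)]
    counts = np.empty((C, n_cells, n_groups), dtype=np.int32)
    for start in range(0, C, chunk):
        block = combos[start : start + chunk]
        c = block.shape[0]
        cells = _cells_for_block(genotypes, block)  # (N, c)
        offset = np.arange(c, dtype=np.int32) * n_cells
        for g, rows in enumerate(rows_by_group):
            flat = cells[rows] + offset[None, :]
            binned = np.bincount(flat.ravel(), minlength=c * n_cells)
            counts[start : start + c, :, g] = binned.reshape(c, n_cells)
    return counts


def classify_counts(case, ctrl, n1: int, n0: int) -> np.ndarray:
    """Vectorised high-risk call: cases/controls >= n1/n0, empty cells low-risk.

    Integer cross-multiplication avoids division; works on arrays of any
    matching shape (..., cells).
    """
    if n1 <= 0 or n0 <= 0:
        raise UndefinedAccuracyError("training data must contain both cases and controls")
    case = np.asarray(case, dtype=np.int64)
    ctrl = np.asarray(ctrl, dtype=np.int64)
    high = case * n0 >= ctrl * n1
    high &= (case + ctrl) > 0
    return high


def balanced_accuracy_counts(high, case_eval, ctrl_eval, n1_eval: int, n0_eval: int):
    """Balanced accuracy of high/low-risk calls against evaluation counts.

    All arrays share a trailing cells axis, which is reduced; leading axes
    (combinations, folds, ...) broadcast.
    """
    if n1_eval == 0 or n0_eval == 0:
        raise UndefinedAccuracyError("evaluation data must contain both cases and controls")
    sens = np.where(high, case_eval, 0).sum(axis=-1) / n1_eval
    spec = np.where(high, 0, ctrl_eval).sum(axis=-1) / n0_eval
    return (sens + spec) / 2.0
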