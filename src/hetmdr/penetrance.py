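"""Construction of single- and two-locus penetrance models.

A penetrance model assigns to every genotype combination ``g`` (minor/risk-allele
counts, each in {0, 1, 2}) the probability of disease ``f_g``.  Models are
parameterised on the odds scale: a baseline odds ``b`` is multiplied by a fixed
pattern of odds-ratio factors determined by the model type,

* ``additive``  — one locus, ``odds(g) = b * OR**g`` (multiplicative per risk allele);
* ``recessive`` — one locus, ``odds = b * OR`` for the homozygous-risk genotype,
  ``b`` otherwise;
* ``xor``       — two loci, ``odds = b * OR`` for combinations in which exactly one
  locus is heterozygous, ``b`` otherwise (the classic two-locus pattern with no
  marginal single-locus effect at allele frequency 0.5).

Under Hardy–Weinberg genotype frequencies at the model's risk-allele frequency,
the narrow/broad heritability of the resulting binary trait on the observed scale
is ``h2 = Var(f_g) / (K (1 - K))`` with prevalence ``K = E[f_g]``.  The solver
fixes the odds-ratio structure exactly and chooses ``b`` so that ``h2`` matches a
target value.

A mathematical caveat documented in :mod:`docs/methods.md`: holding the
penetrance odds ratio at a small value bounds the attainable heritability.  For a
two-class model (recessive, XOR) the supremum of ``h2`` is about 0.0102 at OR=1.5
and 0.0294 at OR=2, and for the additive pattern about 0.0205 at OR=1.5 — all
below the conventional target 0.05 used in low-signal power studies.  For such
combinations ``build_penetrance`` either raises (``on_infeasible="raise"``) or
returns the maximum-heritability model of that odds structure
(``on_infeasible="cap"``), with the achieved value recorded in ``realized_h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb

import numpy as np
from scipy import optimize

MODEL_TYPES = ("additive", "recessive", "xor")

#: Convergence tolerance on the heritability constraint.
H2_TOL = 1e-9

_LOG_B_BOUNDS = (-16.0, 16.0)


class InfeasibleModelError(ValueError):
    """No penetrance table satisfies the requested odds-ratio / heritability pair."""

    def __init__(self, message: str, max_h2: float | None = None):
        super().__init__(message)
        self.max_h2 = max_h2


class DegenerateModelError(ValueError):
    """The model's prevalence is 0 or 1, so heritability is undefined."""


def _odds_multipliers(model_type: str, target_or: float):
    """Genotype-combination cells and their odds-ratio multipliers.

    Returns ``(cells, multipliers)`` where ``cells`` is the list of genotype
    tuples in mixed-radix order (first locus least significant) and
    ``multipliers[i]`` is the factor applied to the baseline odds in cell i.
    """
    if model_type == "additive":
        cells = [(g,) for g in range(3)]
        mult = np.array([target_or ** g for (g,) in cells])
    elif model_type == "recessive":
        cells = [(g,) for g in range(3)]
        mult = np.array([target_or if g == 2 else 1.0 for (g,) in cells])
    elif model_type == "xor":
        # mixed-radix order: cell = g1 + 3*g2
        cells = [(g1, g2) for g2 in range(3) for g1 in range(3)]
        mult = np.array(
            [target_or if (g1 == 1) != (g2 == 1) else 1.0 for (g1, g2) in cells]
        )
    else:
        raise ValueError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")
    return cells, mult


def _hwe_probs(cells, maf: float) -> np.ndarray:
    """Hardy–Weinberg probability of each genotype-combination cell."""
    single = np.array([comb(2, g) * maf ** g * (1 - maf) ** (2 - g) for g in range(3)])
    return np.array([np.prod([single[g] for g in cell]) for cell in cells])


@dataclass(frozen=True)
class PenetranceModel:
    """A genotype-combination → penetrance map with its solved parameters."""

    model_type: str
    n_loci: int
    target_or: float
    target_h2: float
    maf: float
    baseline_odds: float
    penetrance: dict[tuple[int, ...], float]
    realized_or: float
    realized_h2: float
    prevalence: float
    h2_capped: bool = False
    _lookup: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def baseline_penetrance(self) -> float:
        return self.baseline_odds / (1.0 + self.baseline_odds)

    def penetrance_lookup(self) -> np.ndarray:
        """Penetrance as an array of shape ``(3,) * n_loci`` indexed by genotype."""
        lut = np.zeros((3,) * self.n_loci)
        for cell, f in self.penetrance.items():
            lut[cell] = f
        return lut

    def penetrance_of(self, genotypes: np.ndarray) -> np.ndarray:
        """Vectorised penetrance for a ``(n, n_loci)`` genotype matrix."""
        genotypes = np.asarray(genotypes)
        if genotypes.ndim == 1:
            genotypes = genotypes[:, None]
        lut = self.penetrance_lookup()
        return lut[tuple(genotypes[:, i] for i in range(self.n_loci))]


def _h2_from_penetrance(probs: np.ndarray, f: np.ndarray) -> float:
    K = float(probs @ f)
    if K <= 0.0 or K >= 1.0:
        raise DegenerateModelError(f"prevalence {K} leaves no penetrance variance scale")
    var = float(probs @ (f - K) ** 2)
    return var / (K * (1.0 - K))


def heritability(model: PenetranceModel) -> float:
    """Observed-scale heritability ``Var(f_g) / (K(1-K))`` under HWE at ``model.maf``.

    Recomputed from the penetrance table itself (not the cached solver value).
    """
    cells, _ = _odds_multipliers(model.model_type, model.target_or)
    probs = _hwe_probs(cells, model.maf)
    f = np.array([model.penetrance[c] for c in cells])
    return _h2_from_penetrance(probs, f)


def _realized_or(model_type: str, penetrance: dict, target_or: float) -> float:
    """Odds ratio realised by the table: high- vs low-risk class (per-allele for additive)."""
    odds = {c: f / (1.0 - f) for c, f in penetrance.items()}
    if model_type == "additive":
        return odds[(1,)] / odds[(0,)]
    if model_type == "recessive":
        return odds[(2,)] / odds[(0,)]
    # xor: any elevated cell vs any baseline cell
    return odds[(1, 0)] / odds[(0, 0)]


def build_penetrance(
    model_type: str,
    target_or: float,
    target_h2: float,
    maf: float = 0.5,
    on_infeasible: str = "raise",
) -> PenetranceModel:
    """Solve the baseline odds so the table realises ``target_or`` and ``target_h2``.

    The odds-ratio structure makes the realised OR equal to ``target_or`` exactly
    for any baseline, so the solve reduces to a one-dimensional root find for the
    baseline odds ``b`` on the heritability constraint.  ``h2(b)`` rises from 0,
    peaks, and falls back to 0; the smaller root (lower prevalence) is returned.

    Parameters
    ----------
    model_type : {"additive", "recessive", "xor"}
    target_or : float
        Penetrance odds ratio of the pattern; must exceed 1.
    target_h2 : float
        Observed-scale heritability in (0, 1).
    maf : float
        Risk-allele frequency of the disease locus/loci (HWE), in (0, 0.5].
    on_infeasible : {"raise", "cap"}
        When ``target_h2`` exceeds the structure's attainable maximum, either
        raise :class:`InfeasibleModelError` or return the maximum-heritability
        table with ``h2_capped=True``.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")
    if target_or <= 1.0:
        raise InfeasibleModelError(
            f"target odds ratio must exceed 1 (got {target_or}): a flat or inverted "
            "odds pattern cannot carry positive heritability"
        )
    if not (0.0 < target_h2 < 1.0):
        raise ValueError(f"target heritability must lie in (0, 1), got {target_h2}")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"risk-allele frequency must lie in (0, 0.5], got {maf}")
    if on_infeasible not in ("raise", "cap"):
        raise ValueError("on_infeasible must be 'raise' or 'cap'")

    cells, mult = _odds_multipliers(model_type, target_or)
    probs = _hwe_probs(cells, maf)

    def h2_of_log_b(log_b: float) -> float:
        odds = np.exp(log_b) * mult
        f = odds / (1.0 + odds)
        return _h2_from_penetrance(probs, f)

    opt = optimize.minimize_scalar(
        lambda lb: -h2_of_log_b(lb), bounds=_LOG_B_BOUNDS, method="bounded",
        options={"xatol": 1e-12},
    )
    log_b_max, h2_max = float(opt.x), float(-opt.fun)

    capped = False
    if h2_max + H2_TOL < target_h2:
        if on_infeasible == "raise":
            raise InfeasibleModelError(
                f"{model_type} model with penetrance odds ratio {target_or} cannot "
                f"reach heritability {target_h2}: attainable maximum is {h2_max:.6g} "
                "(the odds-ratio constraint bounds the penetrance spread)",
                max_h2=h2_max,
            )
        capped = True
        log_b = log_b_max
    else:
        # smaller root: h2 is increasing on (-inf, log_b_max]
        log_b = optimize.brentq(
            lambda lb: h2_of_log_b(lb) - target_h2,
            _LOG_B_BOUNDS[0], log_b_max, xtol=1e-14,
        )

    b = float(np.exp(log_b))
    odds = b * mult
    f = odds / (1.0 + odds)
    penetrance = {cell: float(fi) for cell, fi in zip(cells, f)}
    realized_h2 = _h2_from_penetrance(probs, f)
    prevalence = float(probs @ f)

    return PenetranceModel(
        model_type=model_type,
        n_loci=len(cells[0]),
        target_or=target_or,
        target_h2=target_h2,
        maf=maf,
        baseline_odds=b,
        penetrance=penetrance,
        realized_or=_realized_or(model_type, penetrance, target_or),
        realized_h2=realized_h2,
        prevalence=prevalence,
        h2_capped=capped,
    )
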