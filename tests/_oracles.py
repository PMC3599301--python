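"""Independent brute-force reference implementations used only by the tests.

Everything here is written with plain Python loops and dictionaries, sharing no
code with the package's vectorised engine, so agreement between the two is a
meaningful cross-check.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


# ---------------------------------------------------------------------------
# penetrance oracles


def grid_search_baseline_odds(multipliers, probs, target_h2, n_grid=20001):
    """Scan baseline odds over a log grid, minimising the h2 residual.

    Returns (best_b, best_residual); independent of the package's root finder.
    """
    best_b, best_res = None, np.inf
    for log_b in np.linspace(-12, 6, n_grid):
        b = float(np.exp(log_b))
        f = np.array([m * b / (1 + m * b) for m in multipliers])
        K = float(np.dot(probs, f))
        h2 = float(np.dot(probs, (f - K) ** 2)) / (K * (1 - K))
        res = abs(h2 - target_h2)
        if res < best_res:
            best_b, best_res = b, res
    return best_b, best_res


def hand_h2_single_locus(f0, f1, f2, maf):
    """Three-term heritability summation for a single-locus table."""
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    fs = [f0, f1, f2]
    K = sum(pr * f for pr, f in zip(probs, fs))
    var = sum(pr * (f - K) ** 2 for pr, f in zip(probs, fs))
    return var / (K * (1 - K))


# ---------------------------------------------------------------------------
# MDR oracles


def naive_tabulate(genotypes, status, loci):
    """Double-loop case/control counts per genotype tuple."""
    k = len(loci)
    case = {c: 0 for c in product(range(3), repeat=k)}
    ctrl = {c: 0 for c in product(range(3), repeat=k)}
    for row, s in zip(genotypes, status):
        cell = tuple(int(row[l]) for l in loci)
        if s == 1:
            case[cell] += 1
        else:
            ctrl[cell] += 1
    return case, ctrl


def naive_cell_of(cell_tuple):
    """Mixed-radix index, first locus least significant."""
    return sum(g * 3 ** i for i, g in enumerate(cell_tuple))


def naive_classify(case, ctrl, threshold):
    """High-risk call per cell dict; empty cells low-risk."""
    high = {}
    for cell in case:
        n1, n0 = case[cell], ctrl[cell]
        if n1 == 0 and n0 == 0:
            high[cell] = False
        elif n0 == 0:
            high[cell] = True
        else:
            high[cell] = (n1 / n0) >= threshold
    return high


def naive_balanced_accuracy(high, case_eval, ctrl_eval):
    n1 = sum(case_eval.values())
    n0 = sum(ctrl_eval.values())
    tp = sum(case_eval[c] for c in case_eval if high[c])
    tn = sum(ctrl_eval[c] for c in ctrl_eval if not high[c])
    return (tp / n1 + tn / n0) / 2


def naive_train_ba(genotypes, status, loci):
    """Fit-and-score balanced accuracy of one locus set on its own data."""
    case, ctrl = naive_tabulate(genotypes, status, loci)
    n1, n0 = sum(case.values()), sum(ctrl.values())
    high = naive_classify(case, ctrl, n1 / n0)
    return naive_balanced_accuracy(high, case, ctrl)


def naive_exhaustive(genotypes, status, k_max):
    """Ranked (descending accuracy, lexicographic ties) lists per size."""
    K = genotypes.shape[1]
    out = {}
    for s in range(1, k_max + 1):
        scored = [
            (loci, naive_train_ba(genotypes, status, loci))
            for loci in combinations(range(K), s)
        ]
        scored.sort(key=lambda t: (-t[1], t[0]))
        out[s] = scored
    return out


# ---------------------------------------------------------------------------
# validation oracles (selection logic replayed with plain loops)


def naive_cv_select(genotypes, status, k_max, fold, m, winner_by="train"):
    """Reference m-fold CV selection given a fold assignment."""
    K = genotypes.shape[1]
    per_size = {}
    for s in range(1, k_max + 1):
        combos = list(combinations(range(K), s))
        eval_ba = {c: [] for c in combos}
        train_ba = {c: [] for c in combos}
        for f in range(m):
            tr = fold != f
            te = fold == f
            g_tr, y_tr = genotypes[tr], status[tr]
            g_te, y_te = genotypes[te], status[te]
            n1_tr = int((y_tr == 1).sum())
            n0_tr = int((y_tr == 0).sum())
            for c in combos:
                case_tr, ctrl_tr = naive_tabulate(g_tr, y_tr, c)
                high = naive_classify(case_tr, ctrl_tr, n1_tr / n0_tr)
                case_te, ctrl_te = naive_tabulate(g_te, y_te, c)
                eval_ba[c].append(naive_balanced_accuracy(high, case_te, ctrl_te))
                train_ba[c].append(naive_balanced_accuracy(high, case_tr, ctrl_tr))
        criterion = train_ba if winner_by == "train" else eval_ba
        cvc = {c: 0 for c in combos}
        for f in range(m):
            winner = max(combos, key=lambda c: (criterion[c][f], [-l for l in c]))
            cvc[winner] += 1
        mean_ba = {c: sum(eval_ba[c]) / m for c in combos}
        best = max(combos, key=lambda c: (cvc[c], mean_ba[c], [-l for l in c]))
        per_size[s] = (best, mean_ba[best], cvc[best])

    sizes = sorted(per_size)
    best_acc = max(sizes, key=lambda s: (per_size[s][1], -s))
    best_cvc = max(sizes, key=lambda s: (per_size[s][2], -s))
    final = best_acc if best_acc == best_cvc else min(best_acc, best_cvc)
    return per_size[final][0], final, per_size


def naive_tws_select(genotypes, status, k_max, part, x):
    """Reference three-way-split selection given a part assignment."""
    K = genotypes.shape[1]
    splits = []
    for p in range(3):
        mask = part == p
        splits.append((genotypes[mask], status[mask]))

    per_size = {}
    for s in range(1, k_max + 1):
        combos = list(combinations(range(K), s))
        ba_tr = {c: naive_train_ba(*splits[0], c) for c in combos}
        ranked = sorted(combos, key=lambda c: (-ba_tr[c], c))
        keep = ranked[: min(x, len(combos))]
        ba_te = {c: naive_train_ba(*splits[1], c) for c in keep}
        best2 = max(keep, key=lambda c: (ba_te[c], [-l for l in c]))
        ba_va = naive_train_ba(*splits[2], best2)
        per_size[s] = (best2, ba_va)

    sizes = sorted(per_size)
    final = max(sizes, key=lambda s: (per_size[s][1], -s))
    return per_size[final][0], final, per_size


# ---------------------------------------------------------------------------
# ANOVA oracle


def hand_anova_f(values, labels):
    """One-way between-groups F statistic by explicit sums of squares."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(values) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)
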