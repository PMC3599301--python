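"""Internal model validation: splits, CV, 3WS, fit accounting, permutation test."""

import numpy as np
import pytest

from hetmdr import (
    SplitConfigError,
    SplitSpec,
    cv_select,
    expected_fit_counts,
    permutation_test,
    tws_select,
)
from hetmdr.validation import stratified_folds, three_way_split

from _oracles import naive_cv_select, naive_tws_select
from conftest import planted_dataset, random_dataset


def test_five_folds_of_200_on_n1000():
    status = np.array([1] * 500 + [0] * 500, dtype=np.int8)
    fold = stratified_folds(status, 5, np.random.default_rng(0))
    for f in range(5):
        assert (fold == f).sum() == 200
        assert ((fold == f) & (status == 1)).sum() == 100


@pytest.mark.parametrize("n,case_fraction", [(53, 0.4), (101, 0.55), (97, 0.33)])
def test_fold_stratification_within_one_individual(n, case_fraction, rng):
    status = (rng.random(n) < case_fraction).astype(np.int8)
    if status.sum() < 5 or (1 - status).sum() < 5:
        status[:5] = 1
        status[5:10] = 0
    fold = stratified_folds(status, 5, rng)
    overall = status.mean()
    for f in range(5):
        sub = status[fold == f]
        # class counts per fold differ from proportionality by at most one
        assert abs(sub.sum() - overall * sub.size) <= 1 + 1e-9


def test_three_way_split_sizes_400_400_200():
    status = np.array([1] * 500 + [0] * 500, dtype=np.int8)
    part = three_way_split(status, (2, 2, 1), np.random.default_rng(0))
    assert [(part == p).sum() for p in range(3)] == [400, 400, 200]
    for p in range(3):
        assert ((part == p) & (status == 1)).sum() in (100, 200)


def test_three_way_split_remainder_goes_to_training():
    status = np.array([1] * 7 + [0] * 7, dtype=np.int8)
    part = three_way_split(status, (2, 2, 1), np.random.default_rng(1))
    # per class: 7 -> test 2, validate 1, train 4 (remainder 2 added to train)
    assert [(part == p).sum() for p in range(3)] == [8, 4, 2]


def test_split_config_errors(rng):
    status = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=np.int8)
    with pytest.raises(SplitConfigError):
        stratified_folds(status, 5, rng)  # only 2 cases for 5 folds
    with pytest.raises(SplitConfigError):
        stratified_folds(np.array([1, 0], dtype=np.int8), 5, rng)
    with pytest.raises(SplitConfigError):
        three_way_split(np.array([1, 1, 0, 0], dtype=np.int8), (2, 2, 1), rng)
    with pytest.raises(ValueError):
        SplitSpec(method="bootstrap")
    with pytest.raises(SplitConfigError):
        SplitSpec(method="3ws", ratio=(2, 2))


def test_cv_selects_planted_locus_with_full_consistency(rng):
    ds = planted_dataset(rng, n=100, K=6, locus=2)
    sel = cv_select(ds, 2, SplitSpec(method="cv", seed=1))
    assert sel.loci == (2,)
    assert sel.size == 1
    assert sel.cv_consistency == 5
    assert sel.prediction_accuracy == pytest.approx(1.0)


def test_tws_selects_planted_locus_through_all_stages(rng):
    ds = planted_dataset(rng, n=100, K=6, locus=2)
    sel = tws_select(ds, 2, SplitSpec(method="3ws", seed=1))
    # larger models containing the perfect locus tie at accuracy 1; parsimony wins
    assert sel.loci == (2,)
    assert sel.size == 1
    assert sel.per_size_candidates[1][0] == (2,)


def test_methods_agree_on_overwhelming_main_effect(rng):
    ds = planted_dataset(rng, n=120, K=8, locus=5)
    cv = cv_select(ds, 2, SplitSpec(method="cv", seed=3))
    tws = tws_select(ds, 2, SplitSpec(method="3ws", seed=3))
    assert cv.loci == tws.loci == (5,)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("winner_by", ["train", "test"])
def test_cv_matches_naive_reference(seed, winner_by):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=30, K=5)
    spec = SplitSpec(method="cv", seed=seed, fold_winner_by=winner_by)
    sel = cv_select(ds, 2, spec)

    fold = stratified_folds(np.asarray(ds.status), 5, np.random.default_rng(seed))
    loci, size, per_size = naive_cv_select(
        ds.genotypes, np.asarray(ds.status), 2, fold, 5, winner_by=winner_by
    )
    assert sel.loci == loci
    assert sel.size == size
    for s in (1, 2):
        assert sel.per_size_candidates[s][0] == per_size[s][0]
        assert sel.per_size_candidates[s][1] == pytest.approx(per_size[s][1], abs=1e-12)
        assert sel.per_size_consistency[s] == per_size[s][2]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tws_matches_naive_reference(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=40, K=5)
    spec = SplitSpec(method="3ws", x=5, seed=seed)
    sel = tws_select(ds, 2, spec)

    part = three_way_split(np.asarray(ds.status), (2, 2, 1), np.random.default_rng(seed))
    loci, size, per_size = naive_tws_select(ds.genotypes, np.asarray(ds.status), 2, part, 5)
    assert sel.loci == loci
    assert sel.size == size
    for s in (1, 2):
        assert sel.per_size_candidates[s][0] == per_size[s][0]
        assert sel.per_size_candidates[s][1] == pytest.approx(per_size[s][1], abs=1e-12)


def test_candidate_map_covers_every_size(rng):
    ds = random_dataset(rng, n=60, K=6)
    for sel in (
        cv_select(ds, 3, SplitSpec(method="cv", seed=0)),
        tws_select(ds, 3, SplitSpec(method="3ws", seed=0)),
    ):
        assert sorted(sel.per_size_candidates) == [1, 2, 3]
        assert 1 <= sel.size <= 3
        assert sel.loci == sel.per_size_candidates[sel.size][0]


def test_fit_count_accounting(rng):
    """CV costs m*C(K,s) fits per size; 3WS costs C(K,s) + x + 1 — the claimed
    five-fold advantage, asserted as operation counts."""
    ds = random_dataset(rng, n=60, K=10)
    cv_spec = SplitSpec(method="cv", seed=0)
    tws_spec = SplitSpec(method="3ws", seed=0)  # x defaults to K
    cv = cv_select(ds, 3, cv_spec)
    tws = tws_select(ds, 3, tws_spec)
    assert cv.n_fits == expected_fit_counts(10, 3, cv_spec)
    assert tws.n_fits == expected_fit_counts(10, 3, tws_spec)
    from math import comb
    for s in (1, 2, 3):
        assert cv.n_fits[s] == 5 * comb(10, s)
        assert tws.n_fits[s] == comb(10, s) + min(10, comb(10, s)) + 1
        assert tws.n_fits[s] < cv.n_fits[s]


def test_fit_count_with_wide_screening(rng):
    """x larger than the number of size-s models cannot be screened past C(K,s)."""
    ds = random_dataset(rng, n=40, K=6)
    spec = SplitSpec(method="3ws", x=10, seed=0)
    tws = tws_select(ds, 1, spec)
    assert tws.n_fits[1] == 6 + 6 + 1


def test_refit_switch_changes_only_scoring_not_contract(rng):
    ds = random_dataset(rng, n=60, K=5)
    a = tws_select(ds, 2, SplitSpec(method="3ws", seed=4, refit_per_stage=False))
    b = tws_select(ds, 2, SplitSpec(method="3ws", seed=4, refit_per_stage=False))
    assert a == b
    assert 1 <= a.size <= 2


def test_permutation_test_contracts(rng):
    strong = planted_dataset(rng, n=60, K=4, locus=1)
    p_strong = permutation_test(strong, method="cv", k_max=1, n_perm=19, seed=5)
    assert p_strong == pytest.approx(1 / 20)
    # determinism
    assert p_strong == permutation_test(strong, method="cv", k_max=1, n_perm=19, seed=5)
    with pytest.raises(ValueError):
        permutation_test(strong, n_perm=0, seed=1)


def test_permutation_null_is_roughly_uniform():
    """On pure noise the permutation p-value should not pile up near 0."""
    from scipy import stats

    ps = []
    for seed in range(12):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n=40, K=4)
        ps.append(permutation_test(ds, method="cv", k_max=1, n_perm=9, seed=seed))
    # discrete support {0.1, ..., 1.0}; a loose KS sanity check against U(0,1)
    assert stats.kstest(ps, "uniform").pvalue > 1e-3
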