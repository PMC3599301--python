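"""Outcome classification, power aggregation, factorial ANOVA, rendering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hetmdr import (
    POWER_DEFINITIONS,
    aggregate,
    anova,
    classify_outcome,
    render_results,
)

from _oracles import hand_anova_f


# ---------------------------------------------------------------------------
# outcome classification


@pytest.fixture(scope="module")
def xor_truth(scenarios=None):
    from hetmdr import enumerate_scenarios

    return [s for s in enumerate_scenarios() if s.model_type == "xor"][0]


@pytest.mark.parametrize(
    "selected,expected",
    [
        ({0, 1, 2, 3}, dict(conservative=True, mod1=True, mod2=True, nofalse=True,
                            onlymod1=False, onlymod2=False)),
        ({0, 1, 5}, dict(conservative=False, mod1=True, onlymod1=False, mod2=False,
                         onlymod2=False, nofalse=False)),
        ({0}, dict(conservative=False, mod1=False, onlymod1=False, mod2=False,
                   onlymod2=False, nofalse=True)),
        ({0, 1}, dict(conservative=False, mod1=True, onlymod1=True, mod2=False,
                      onlymod2=False, nofalse=True)),
        ({2, 3}, dict(conservative=False, mod1=False, onlymod1=False, mod2=True,
                      onlymod2=True, nofalse=True)),
    ],
)
def test_outcome_definitions(xor_truth, selected, expected):
    """The six success definitions against a four-locus truth L1={0,1}, L2={2,3}."""
    flags = classify_outcome(selected, xor_truth).as_dict()
    assert flags == expected


def test_empty_selection_rejected(xor_truth):
    with pytest.raises(ValueError):
        classify_outcome(set(), xor_truth)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.sets(st.integers(min_value=0, max_value=9), min_size=1))
def test_flag_implications_hold_for_any_selection(selected):
    """onlymodX implies modX and nofalse; conservative implies mod1, mod2, nofalse."""
    from hetmdr import enumerate_scenarios

    truth = [s for s in enumerate_scenarios() if s.model_type == "xor"][0]
    f = classify_outcome(selected, truth)
    assert not f.onlymod1 or (f.mod1 and f.nofalse)
    assert not f.onlymod2 or (f.mod2 and f.nofalse)
    assert not f.conservative or (f.mod1 and f.mod2 and f.nofalse)
    assert f.conservative == (f.mod1 and f.mod2 and f.nofalse)


# ---------------------------------------------------------------------------
# aggregation


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["scenario_id", "method", "size", *POWER_DEFINITIONS],
    )


def test_aggregate_percentages_and_sizes():
    rows = []
    for i in range(100):
        flags = [i < 12, True, False, False, False, i < 40]
        rows.append([1, "cv", 1 if i % 3 else 2, *flags])
    table = aggregate(_records(rows))
    row = table.loc[(1, "cv")]
    assert row["power_conservative"] == pytest.approx(12.0)
    assert row["power_nofalse"] == pytest.approx(40.0)
    assert row["n_replicates"] == 100
    assert row["count_conservative"] == 12


def test_aggregate_mean_and_mode():
    rows = [[2, "3ws", s, *([False] * 6)] for s in (1, 1, 2)]
    table = aggregate(_records(rows))
    row = table.loc[(2, "3ws")]
    assert row["mean_size"] == pytest.approx(4 / 3)
    assert row["mode_size"] == 1
    # mode tie -> smaller size
    rows = [[3, "cv", s, *([False] * 6)] for s in (1, 2)]
    assert aggregate(_records(rows)).loc[(3, "cv"), "mode_size"] == 1


def test_aggregate_requires_flag_columns():
    with pytest.raises(ValueError):
        aggregate(pd.DataFrame({"scenario_id": [1], "method": ["cv"], "size": [1]}))


def test_power_orderings_from_real_outcomes(xor_truth, rng):
    """conservative <= min(mod1, mod2) and onlymodX <= modX, per aggregated cell."""
    rows = []
    for rep in range(60):
        n = int(rng.integers(1, 5))
        selected = set(rng.choice(6, size=n, replace=False).tolist())
        flags = classify_outcome(selected, xor_truth).as_dict()
        rows.append([xor_truth.scenario_id, "cv", len(selected), *flags.values()])
    table = aggregate(_records(rows))
    row = table.iloc[0]
    assert row["power_conservative"] <= min(row["power_mod1"], row["power_mod2"])
    assert row["power_onlymod1"] <= row["power_mod1"]
    assert row["power_onlymod2"] <= row["power_mod2"]
    assert row["power_conservative"] <= row["power_nofalse"]


# ---------------------------------------------------------------------------
# ANOVA


def _balanced_fixture(method_shift=0.0, noise_scale=1.0, seed=9):
    """A fully crossed 2^4 design: 8 synthetic scenarios x 2 methods."""
    rng = np.random.default_rng(seed)
    design = {}
    rows = []
    sid = 0
    for het, mtype, oclass in itertools.product(
        ("25/75", "50/50"), ("additive", "recessive"), ("both 1.5", "both 2")
    ):
        sid += 1
        design[sid] = {
            "model_type": mtype, "heterogeneity": het, "odds_ratio": oclass,
        }
        for method in ("cv", "3ws"):
            value = 20.0 + (method_shift if method == "cv" else 0.0)
            value += noise_scale * rng.normal()
            row = {"scenario_id": sid, "method": method, "n_replicates": 100,
                   "mean_size": 1.5, "mode_size": 1}
            for name in POWER_DEFINITIONS:
                row[f"power_{name}"] = value
                row[f"count_{name}"] = int(value)
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["scenario_id", "method"])
    return table, design


def test_anova_no_effect_gives_p_one():
    """Identical power vectors for both methods: F = 0, p = 1."""
    table, design = _balanced_fixture(method_shift=0.0, noise_scale=0.0)
    # add scenario-level variation so the residual is positive
    values = np.repeat(np.arange(8, dtype=float), 2)
    for name in POWER_DEFINITIONS:
        table[f"power_{name}"] = 10.0 + values
    result = anova(table, design)
    assert np.allclose(result.loc["method"], 1.0)


def test_anova_detects_planted_method_effect():
    table, design = _balanced_fixture(method_shift=40.0, noise_scale=0.5)
    result = anova(table, design)
    assert (result.loc["method"] < 1e-10).all()
    assert (result.loc["heterogeneity"] > 0.05).all()


def test_anova_matches_hand_sums_of_squares():
    """Balanced orthogonal design: Type-II F equals the explicit SS decomposition."""
    table, design = _balanced_fixture(method_shift=8.0, noise_scale=3.0, seed=4)
    result = anova(table, design)

    df = table.reset_index()
    y = df["power_conservative"].to_numpy(dtype=float)
    labels = {
        "method": df["method"].to_numpy(),
        "heterogeneity": df["scenario_id"].map(lambda s: design[s]["heterogeneity"]).to_numpy(),
        "model_type": df["scenario_id"].map(lambda s: design[s]["model_type"]).to_numpy(),
        "odds_ratio": df["scenario_id"].map(lambda s: design[s]["odds_ratio"]).to_numpy(),
    }
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss = {}
    for effect, lab in labels.items():
        ss[effect] = sum(
            (y[lab == g].size) * (y[lab == g].mean() - grand) ** 2 for g in np.unique(lab)
        )
    ss_res = ss_total - sum(ss.values())
    df_res = len(y) - 1 - 4
    for effect in ss:
        F = (ss[effect] / 1) / (ss_res / df_res)
        p = stats.f.sf(F, 1, df_res)
        assert result.loc[effect, "conservative"] == pytest.approx(p, rel=1e-6)


def test_anova_names_aliased_factors():
    table, design = _balanced_fixture()
    # make odds_ratio a relabelling of heterogeneity: perfectly aliased
    for sid in design:
        design[sid]["odds_ratio"] = "dup-" + design[sid]["heterogeneity"]
    with pytest.raises(ValueError, match="aliased"):
        anova(table, design)


# ---------------------------------------------------------------------------
# rendering


def test_render_outputs_and_determinism(tmp_path):
    table, design = _balanced_fixture(method_shift=5.0, noise_scale=2.0)
    result = anova(table, design)
    written = render_results(table, tmp_path / "out", anova_result=result)
    names = sorted(p.name for p in written)
    assert names == [
        "anova.csv", "power.csv", "power_conservative.png", "power_mod.png",
        "power_nofalse.png", "power_onlymod.png", "size_stats.csv",
    ]
    first = (tmp_path / "out" / "power.csv").read_bytes()
    render_results(table, tmp_path / "out", anova_result=result)
    assert (tmp_path / "out" / "power.csv").read_bytes() == first


def test_render_rejects_empty_table(tmp_path):
    with pytest.raises(ValueError):
        render_results(pd.DataFrame(), tmp_path)
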