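"""Contracts of the group-comparison layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tilrep.compare import compare_groups, correlate_diversity_composition


def test_paired_t_identical_pairs_is_null():
    res = compare_groups((np.arange(10.0), np.arange(10.0)), "paired_t")
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_paired_t_matches_scipy(rng):
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    res = compare_groups((x, y), "paired_t")
    t, p = sps.ttest_rel(x, y)
    assert res.statistic == pytest.approx(float(t))
    assert res.pvalue == pytest.approx(float(p))


def test_paired_t_constant_nonzero_diff_errors():
    with pytest.raises(ValueError, match="zero variance"):
        compare_groups((np.arange(5.0), np.arange(5.0) + 2.0), "paired_t")


def test_paired_t_drops_nan_pairs(rng):
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
    y = np.array([1.5, 1.0, 3.0, np.nan, 4.0, 5.0])
    res = compare_groups((x, y), "paired_t")
    assert res.n_dropped == 2
    assert res.group_sizes == {"x": 4, "y": 4}


def test_pearson_perfect_correlation():
    x = np.arange(10.0)
    res = compare_groups((x, x), "pearson")
    assert res.statistic == pytest.approx(1.0)
    assert res.pvalue < 1e-10


def test_pearson_degenerate_inputs():
    with pytest.raises(ValueError, match="3 complete pairs"):
        compare_groups(([1.0, 2.0], [1.0, 2.0]), "pearson")
    with pytest.raises(ValueError, match="zero variance"):
        compare_groups(([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]), "pearson")


def test_anova_matches_scipy_and_tukey_adjustment(rng):
    groups = {
        "a": rng.normal(0.0, 1.0, 20),
        "b": rng.normal(0.4, 1.0, 20),
        "c": rng.normal(1.0, 1.0, 20),
    }
    res = compare_groups(groups, "anova_tukey")
    f, p = sps.f_oneway(*groups.values())
    assert res.statistic == pytest.approx(float(f))
    assert res.pvalue == pytest.approx(float(p))
    assert len(res.pairwise) == 3
    # Tukey-adjusted p is never below the raw pairwise p
    assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()


def test_anova_degenerate_inputs():
    with pytest.raises(ValueError, match="fewer than 2"):
        compare_groups({"a": [1.0], "b": [1.0, 2.0]}, "anova_tukey")
    with pytest.raises(ValueError, match="zero variance"):
        compare_groups({"a": [1.0, 1.0], "b": [1.0, 1.0]}, "anova_tukey")
    with pytest.raises(ValueError, match="unknown design"):
        compare_groups({}, "kruskal")


def _twoway_df(rng, effect=0.0):
    rows = []
    for a in ("cd4", "cd8"):
        for b in ("pre", "post"):
            shift = effect if a == "cd4" else 0.0
            for v in rng.normal(shift, 1.0, 8):
                rows.append({"value": v, "factor_a": a, "factor_b": b})
    return pd.DataFrame(rows)


def test_twoway_sidak_structure(rng):
    res = compare_groups(_twoway_df(rng, effect=2.0), "twoway_sidak")
    assert res.pvalue < 0.01  # strong factor_a main effect
    assert {"p_factor_b", "p_interaction"} <= set(res.extra)
    assert len(res.pairwise) == 2  # cd4 vs cd8 within pre and within post
    assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()
    # Sidak with m=2: p_adj = 1-(1-p)^2
    for _, row in res.pairwise.iterrows():
        assert row["p_adj"] == pytest.approx(1 - (1 - row["p_raw"]) ** 2)


def test_twoway_requires_filled_cells(rng):
    df = _twoway_df(rng).iloc[:17]  # last cell underfilled
    df = pd.concat([df[df["factor_b"] == "pre"], df[df["factor_b"] == "post"].iloc[:1]])
    with pytest.raises(ValueError):
        compare_groups(df, "twoway_sidak")


def test_correlate_diversity_composition_sign_recovery():
    """Cohorts where CD4 content drives clonality show r(nsw, %CD4) < 0."""
    from tilrep.stats import normalized_shannon_wiener
    from tilrep.synthetic import mixed_initial_repertoire

    rng = np.random.default_rng(77)
    wins = 0
    n_rep = 10
    for rep_i in range(n_rep):
        rows = []
        for _ in range(6):
            pct = float(rng.uniform(15, 85))
            rep = mixed_initial_repertoire(
                pct, n_clonotypes=400, seed=int(rng.integers(2**31))
            )
            rows.append(
                {
                    "nsw": normalized_shannon_wiener(rep).nsw,
                    "pct_cd4": pct,
                    "pct_cd8": 100 - pct,
                }
            )
        res = correlate_diversity_composition(pd.DataFrame(rows))
        if res["cd4"].statistic < 0 < res["cd8"].statistic:
            wins += 1
        # relabeling symmetry: swapping the composition columns swaps r
        assert res["cd4"].statistic == pytest.approx(-res["cd8"].statistic)
    assert wins >= int(0.9 * n_rep)


def test_correlate_degenerate():
    df = pd.DataFrame({"nsw": [0.5, 0.5, 0.5], "pct_cd4": [10.0, 50.0, 90.0], "pct_cd8": [90.0, 50.0, 10.0]})
    with pytest.raises(ValueError, match="zero variance"):
        correlate_diversity_composition(df)
    with pytest.raises(ValueError, match="3 samples"):
        correlate_diversity_composition(df.iloc[:2])
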