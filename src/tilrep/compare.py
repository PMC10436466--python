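"""Group-comparison statistics used for every figure-panel analogue.

A thin, contract-tested layer over scipy/statsmodels:

* ``anova_tukey`` — ordinary one-way ANOVA with Tukey HSD pairwise
  contrasts (CDR3 property comparisons across sample groups).
* ``paired_t`` — paired t-test (diversity of CD4+ vs CD8+ samples from
  the same biopsy slices).
* ``twoway_sidak`` — ordinary two-way ANOVA with Sidak-adjusted pairwise
  contrasts of the primary factor within levels of the secondary one
  (before/after expansion designs).
* ``pearson`` — Pearson correlation (diversity vs subset composition).

Missing values are dropped pairwise with the dropped count reported;
degenerate inputs (a group smaller than 2, zero variance where the
statistic requires it) raise instead of propagating NaN.  Normality is
not tested before the parametric tests; that mirrors common practice and
is documented as a caveat.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "correlate_diversity_composition"]

DESIGNS = ("anova_tukey", "paired_t", "twoway_sidak", "pearson")


@dataclass(frozen=True)
class ComparisonResult:
    method: str
    statistic: float
    pvalue: float
    group_means: dict
    group_sizes: dict
    pairwise: Optional[pd.DataFrame] = None  # columns: contrast, p_raw, p_adj
    extra: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value {self.pvalue} outside [0,1]")


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def _check_group(name, arr: np.ndarray, min_n: int = 2) -> None:
    if len(arr) < min_n:
        raise ValueError(f"group {name!r} has fewer than {min_n} observations")


def _anova_tukey(groups: dict) -> ComparisonResult:
    cleaned = {}
    dropped = 0
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        dropped += int(np.isnan(arr).sum())
        cleaned[name] = arr[~np.isnan(arr)]
    if len(cleaned) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for name, arr in cleaned.items():
        _check_group(name, arr)
    pooled = np.concatenate(list(cleaned.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: zero variance")
    f_stat, p = sps.f_oneway(*cleaned.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(cleaned.values()))
    labels = np.concatenate(
        [np.repeat(name, len(arr)) for name, arr in cleaned.items()]
    )
    tk = pairwise_tukeyhsd(values, labels)
    # statsmodels orders contrasts as combinations of the sorted group names
    combos = list(itertools.combinations(sorted(cleaned), 2))
    raw = [float(sps.ttest_ind(cleaned[g1], cleaned[g2])[1]) for g1, g2 in combos]
    pairwise = pd.DataFrame(
        {
            "contrast": [f"{g1} vs {g2}" for g1, g2 in combos],
            "p_raw": raw,
            "p_adj": np.asarray(tk.pvalues, dtype=float),
        }
    )
    return ComparisonResult(
        method="anova_tukey",
        statistic=float(f_stat),
        pvalue=float(p),
        group_means={k: float(v.mean()) for k, v in cleaned.items()},
        group_sizes={k: int(len(v)) for k, v in cleaned.items()},
        pairwise=pairwise,
        n_dropped=dropped,
    )


def _paired_t(x, y) -> ComparisonResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired t-test needs equal-length paired vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    _check_group("pairs", x)
    diff = x - y
    if np.all(diff == 0):
        stat, p = 0.0, 1.0  # identical pairs: no effect, no evidence
    elif diff.std(ddof=1) == 0:
        raise ValueError("constant nonzero pair differences: zero variance")
    else:
        stat, p = sps.ttest_rel(x, y)
    return ComparisonResult(
        method="paired_t",
        statistic=float(stat),
        pvalue=float(p),
        group_means={"x": float(x.mean()), "y": float(y.mean())},
        group_sizes={"x": int(len(x)), "y": int(len(y))},
        extra={"mean_difference": float(diff.mean())},
        n_dropped=dropped,
    )


def _sidak(p: float, m: int) -> float:
    return float(1.0 - (1.0 - p) ** m)


def _twoway_sidak(df: pd.DataFrame) -> ComparisonResult:
    required = {"value", "factor_a", "factor_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"two-way design needs columns {sorted(required)}")
    data = df.dropna(subset=["value"]).copy()
    dropped = len(df) - len(data)
    if data["factor_a"].nunique() < 2 or data["factor_b"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = data.groupby(["factor_a", "factor_b"])["value"].count()
    if (counts < 2).any():
        raise ValueError("every factor cell needs at least 2 observations")
    if np.ptp(data["value"].to_numpy()) == 0:
        raise ValueError("all observations identical: zero variance")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=data).fit()
    table = anova_lm(model, typ=2)
    p_a = float(table.loc["C(factor_a)", "PR(>F)"])
    f_a = float(table.loc["C(factor_a)", "F"])

    # Sidak follow-up: factor_a contrasts within each level of factor_b
    contrasts = []
    levels_a = sorted(data["factor_a"].unique())
    levels_b = sorted(data["factor_b"].unique())
    for lb in levels_b:
        sub = data[data["factor_b"] == lb]
        for g1, g2 in itertools.combinations(levels_a, 2):
            x = sub[sub["factor_a"] == g1]["value"].to_numpy()
            y = sub[sub["factor_a"] == g2]["value"].to_numpy()
            p_raw = float(sps.ttest_ind(x, y)[1])
            contrasts.append({"contrast": f"{g1} vs {g2} | {lb}", "p_raw": p_raw})
    m = len(contrasts)
    pairwise = pd.DataFrame(contrasts)
    pairwise["p_adj"] = [min(1.0, _sidak(p, m)) for p in pairwise["p_raw"]]

    means = data.groupby(["factor_a", "factor_b"])["value"].mean()
    return ComparisonResult(
        method="twoway_sidak",
        statistic=f_a,
        pvalue=p_a,
        group_means={f"{a}|{b}": float(v) for (a, b), v in means.items()},
        group_sizes={f"{a}|{b}": int(v) for (a, b), v in counts.items()},
        pairwise=pairwise,
        extra={
            "anova_table": table,
            "p_factor_b": float(table.loc["C(factor_b)", "PR(>F)"]),
            "p_interaction": float(table.loc["C(factor_a):C(factor_b)", "PR(>F)"]),
        },
        n_dropped=dropped,
    )


def _pearson(x, y) -> ComparisonResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("pearson needs two equal-length vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("pearson needs at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlate")
    r, p = sps.pearsonr(x, y)
    return ComparisonResult(
        method="pearson",
        statistic=float(r),
        pvalue=float(p),
        group_means={"x": float(x.mean()), "y": float(y.mean())},
        group_sizes={"x": int(len(x)), "y": int(len(y))},
        n_dropped=dropped,
    )


def compare_groups(data, design: str) -> ComparisonResult:
    """Dispatch a group comparison.

    ``data`` by design: ``anova_tukey`` — mapping group -> values;
    ``paired_t``/``pearson`` — (x, y) pair of equal-length vectors;
    ``twoway_sidak`` — DataFrame with columns value/factor_a/factor_b.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    if design == "anova_tukey":
        return _anova_tukey(dict(data))
    if design == "paired_t":
        return _paired_t(*data)
    if design == "twoway_sidak":
        return _twoway_sidak(data)
    return _pearson(*data)


def correlate_diversity_composition(table: pd.DataFrame) -> dict:
    """Pearson correlation of per-sample diversity with subset composition.

    ``table`` needs columns ``nsw``, ``pct_cd4``, ``pct_cd8``.  Returns
    ``{"cd4": ComparisonResult, "cd8": ComparisonResult}`` reported
    separately, as in the composition-vs-diversity panel.
    """
    required = {"nsw", "pct_cd4", "pct_cd8"}
    if not required.issubset(table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    return {
        "cd4": compare_groups((table["nsw"], table["pct_cd4"]), "pearson"),
        "cd8": compare_groups((table["nsw"], table["pct_cd8"]), "pearson"),
    }
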