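"""Study-scale synthetic experiments: the full analysis analogue.

These routines assemble the synthetic cohorts at the conditions the
comparative analysis emulates (CD4-like vs CD8-like compartments, 8
patients per group, 2 biopsy slices of 2000 clonotypes each, compared on
patient-merged samples) and measure how reliably the pipeline recovers
the planted group structure.  They back both the acceptance checks and
the numbered analysis drivers.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .compare import compare_groups
from .features import length_summary, repertoire_property_profile
from .io import collapse_by_aa, merge_samples
from .motifs import cluster_by_motifs, enumerate_motifs, _fisher
from .stats import convergence, normalized_shannon_wiener
from .synthetic import (
    RepertoireSpec,
    cd4_til_spec,
    cd8_til_spec,
    generate_repertoire,
    reference_spec,
)

__all__ = [
    "paired_group_metrics",
    "parameter_recovery",
    "motif_recovery",
    "motif_null_false_positive_rate",
    "type_i_error",
]


def _patient_sample(preset_fn, n_clonotypes, n_slices, rng) -> tuple:
    slices = [
        generate_repertoire(
            preset_fn(n_clonotypes, seed=int(rng.integers(2**31))),
            f"s{j}",
            patient_id="p",
        )
        for j in range(n_slices)
    ]
    merged = merge_samples(slices)
    aa = collapse_by_aa(merged)
    ls = length_summary(merged)
    return (
        ls.ndn_mean,
        repertoire_property_profile(aa, "charge"),
        normalized_shannon_wiener(merged).nsw,
        convergence(aa).cr_level,
    )


def paired_group_metrics(
    seed: int,
    n_patients: int = 8,
    n_slices: int = 2,
    n_clonotypes: int = 2000,
) -> pd.DataFrame:
    """Per-patient paired CD4-like / CD8-like metrics for one cohort."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        m4 = _patient_sample(cd4_til_spec, n_clonotypes, n_slices, rng)
        m8 = _patient_sample(cd8_til_spec, n_clonotypes, n_slices, rng)
        rows.append(
            {
                "patient": f"P{p + 1:02d}",
                "ndn_cd4": m4[0],
                "ndn_cd8": m8[0],
                "charge_cd4": m4[1],
                "charge_cd8": m8[1],
                "nsw_cd4": m4[2],
                "nsw_cd8": m8[2],
                "cr_cd4": m4[3],
                "cr_cd8": m8[3],
            }
        )
    return pd.DataFrame(rows)


def parameter_recovery(
    seed: int,
    n_replicates: int = 20,
    n_patients: int = 8,
    n_slices: int = 2,
    n_clonotypes: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicate cohorts recovering each planted group ordering
    (CD4 longer junctions, more positive charge, lower diversity) with a
    paired t-test at the given alpha."""
    rng = np.random.default_rng(seed)
    wins = {"ndn": 0, "charge": 0, "nsw": 0}
    last = None
    for _ in range(n_replicates):
        df = paired_group_metrics(
            int(rng.integers(2**31)), n_patients, n_slices, n_clonotypes
        )
        last = df
        for metric in wins:
            res = compare_groups(
                (df[f"{metric}_cd4"], df[f"{metric}_cd8"]), "paired_t"
            )
            diff = df[f"{metric}_cd4"].mean() - df[f"{metric}_cd8"].mean()
            planted_sign = -1.0 if metric == "nsw" else 1.0
            if res.pvalue < alpha and diff * planted_sign > 0:
                wins[metric] += 1
    return {
        "rates": {k: v / n_replicates for k, v in wins.items()},
        "n_replicates": n_replicates,
        "last_cohort": last,
    }


def motif_recovery(
    seed: int,
    n_seeds: int = 20,
    motif: str = "SLGG%GE",
    n_sample: int = 200,
    n_carriers: int = 30,
    n_reference: int = 2000,
    ref_carrier_frac: float = 0.01,
) -> float:
    """Fraction of seeds in which a motif planted in ``n_carriers`` of
    ``n_sample`` sequences (vs ~1% background) comes back as a passing
    cluster under the default score thresholds."""
    rng = np.random.default_rng(seed)
    hits = 0
    n_ref_carriers = max(1, int(round(ref_carrier_frac * n_reference)))
    for _ in range(n_seeds):
        sample = generate_repertoire(
            RepertoireSpec(
                n_clonotypes=n_sample,
                seed=int(rng.integers(2**31)),
                planted_motifs=((motif, n_carriers),),
                clone_size_law=("geometric", 0.3),
            ),
            "sample",
        )
        ref = generate_repertoire(
            reference_spec(
                n_reference,
                seed=int(rng.integers(2**31)),
                planted_motifs=((motif, n_ref_carriers),),
            ),
            "ref",
        )
        clusters = cluster_by_motifs(
            collapse_by_aa(sample),
            collapse_by_aa(ref),
            b=500,
            seed=int(rng.integers(2**31)),
        )
        if any(cl.motif == motif for cl in clusters):
            hits += 1
    return hits / n_seeds


def motif_null_false_positive_rate(
    seed: int,
    fisher_max: float = 0.05,
    n_sample: int = 200,
    n_reference: int = 2000,
    min_carriers: int = 1,
) -> tuple[float, int]:
    """Under a pure null (sample and reference from the same process), the
    fraction of tested motifs whose Fisher score passes ``fisher_max``.

    The tested universe is every motif scoreable in the sample (>= 1
    carrier, the scoring precondition); conditioning on higher carrier
    counts would itself select upward-fluctuated motifs and no longer be a
    calibration of the test.  Returns (rate, number of motifs tested).
    """
    rng = np.random.default_rng(seed)
    sample = generate_repertoire(
        reference_spec(n_sample, seed=int(rng.integers(2**31))), "sample"
    )
    ref = generate_repertoire(
        reference_spec(n_reference, seed=int(rng.integers(2**31))), "ref"
    )
    sample_aa = collapse_by_aa(sample)
    ref_aa = collapse_by_aa(ref)
    sample_motifs = enumerate_motifs(sample_aa.sequences)
    ref_motifs = enumerate_motifs(ref_aa.sequences)
    n_s, n_r = sample_aa.richness, ref_aa.richness
    tested = passed = 0
    for motif, carriers in sample_motifs.items():
        if len(carriers) < min_carriers:
            continue
        tested += 1
        p = _fisher(len(carriers), n_s, len(ref_motifs.get(motif, ())), n_r)
        if p <= fisher_max:
            passed += 1
    return (passed / tested if tested else 0.0, tested)


def type_i_error(seed: int, n_replicates: int = 1000, alpha: float = 0.05) -> dict:
    """Null rejection rate of each comparison design over seeded replicates
    of pure-noise data."""
    rng = np.random.default_rng(seed)
    rejections = {d: 0 for d in ("anova_tukey", "paired_t", "twoway_sidak", "pearson")}
    for _ in range(n_replicates):
        groups = {g: rng.normal(size=30) for g in ("a", "b", "c")}
        if compare_groups(groups, "anova_tukey").pvalue < alpha:
            rejections["anova_tukey"] += 1
        if compare_groups((rng.normal(size=15), rng.normal(size=15)), "paired_t").pvalue < alpha:
            rejections["paired_t"] += 1
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                for v in rng.normal(size=5):
                    rows.append({"value": v, "factor_a": a, "factor_b": b})
        if compare_groups(pd.DataFrame(rows), "twoway_sidak").pvalue < alpha:
            rejections["twoway_sidak"] += 1
        if compare_groups((rng.normal(size=20), rng.normal(size=20)), "pearson").pvalue < alpha:
            rejections["pearson"] += 1
    return {k: v / n_replicates for k, v in rejections.items()}
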