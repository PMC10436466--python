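#!/usr/bin/env python
"""Diversity (normalized Shannon-Wiener), convergent recombination and
publicity, including the publicity x convergence cross-tabulation."""

import pandas as pd

from _common import run_stage

cfg = run_stage("stats")

stats = pd.read_csv(f"{cfg.output_dir}/stats.tsv", sep="\t")
print("per-compartment diversity and convergence (mean over patients):")
print(stats.groupby("compartment")[["S", "nsw", "cr_level"]].mean().round(3).to_string())

pub = pd.read_csv(f"{cfg.output_dir}/publicity.tsv", sep="\t")
print("\npublicity (patient-merged, share >= 2 biopsies):")
cols = ["compartment", "n_public", "percent_public",
        "pct_public_given_convergent", "pct_public_given_nonconvergent"]
print(pub[cols].round(3).to_string(index=False))
print("\npublic sequences concentrate among convergent CDR3aa.")
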