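#!/usr/bin/env python
"""Preprocess the clonotype tables: exclude non-productive clonotypes,
decontaminate across samples, merge biopsy slices per patient and
collapse nucleotide variants onto CDR3aa clonotypes."""

import pandas as pd

from _common import run_stage

cfg = run_stage("preprocess")

log = pd.read_csv(f"{cfg.output_dir}/preprocess/log.tsv", sep="\t")
for step in ("filter_productive", "decontaminate"):
    sub = log[log["step"] == step]
    removed = (sub["before"] - sub["after"]).sum()
    print(f"{step}: removed {removed} clonotypes across {len(sub)} samples")
merged = log[log["step"] == "merge+collapse"]
print(f"merged {len(merged)} patient/compartment samples; "
      f"median CDR3aa richness {int(merged['after'].median())}")
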