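#!/usr/bin/env python
"""Candidate sequence sets (frequency > 0.1%, public, motif-clustered)
matched against the specificity database at Levenshtein distance <= 1,
with cancer annotations propagated across motif clusters."""

import pandas as pd

from _common import run_stage

cfg = run_stage("annotate")

for comp in ("CD4", "CD8"):
    cand = pd.read_csv(f"{cfg.output_dir}/annotate/candidates_{comp}.csv")
    counts = pd.read_csv(f"{cfg.output_dir}/annotate/category_counts_{comp}.csv")
    print(
        f"{comp}: candidates high_freq={int(cand['high_freq'].sum())} "
        f"public={int(cand['public'].sum())} clustered={int(cand['clustered'].sum())}"
    )
    print(counts.to_string(index=False))
    print()
print("propagation only ever adds sequences (grey-cell effect): direct <= direct+propagated.")
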