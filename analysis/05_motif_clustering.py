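#!/usr/bin/env python
"""Enrichment-based CDR3aa motif discovery per biopsy and compartment,
with cross-biopsy sharing tables."""

import pandas as pd

from _common import run_stage

cfg = run_stage("motifs")

for comp in ("CD4", "CD8"):
    clusters = pd.read_csv(f"{cfg.output_dir}/motifs/clusters_{comp}.tsv", sep="\t")
    sharing = pd.read_csv(f"{cfg.output_dir}/motifs/sharing_{comp}.tsv", sep="\t")
    shared = int((sharing["n_biopsies"] >= 2).sum())
    print(
        f"{comp}: {sharing.shape[0]} distinct passing motifs "
        f"({len(clusters)} biopsy-level clusters), {shared} shared by >= 2 biopsies"
    )
    planted = sharing[sharing["motif"].str.contains("%", regex=False)]
    if not planted.empty:
        print(planted.head(10).to_string(index=False))
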