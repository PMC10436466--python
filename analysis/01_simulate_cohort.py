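#!/usr/bin/env python
"""Generate the synthetic study cohort and specificity database.

8 patients x 2 biopsy slices, three compartments per slice: an unsorted
initial culture (a CD4/CD8 mixture at a per-patient composition) and
sorted CD4-like / CD8-like repertoires carrying the planted group
differences (N(D)N length, central charge, diversity, motifs, public
clones).  Writes clonotype tables, the background reference and the
database under results/study/ingest/.
"""

import pandas as pd

from _common import load_config, run_stage

cfg = run_stage("ingest")

sheet = pd.read_csv(f"{cfg.output_dir}/ingest/sample_sheet.csv")
print(f"wrote {len(sheet)} samples to {cfg.output_dir}/ingest/")
print(sheet.groupby("compartment")["sample_id"].count().to_string())
print("\nper-patient CD4%% of initial cultures:")
init = sheet[sheet["compartment"] == "initial"]
print(init.groupby("patient_id")["pct_cd4"].first().round(1).to_string())
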