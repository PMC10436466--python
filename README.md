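# tilrep

Comparative analysis of CD4+ and CD8+ tumor-infiltrating T-cell (TIL)
receptor repertoires from clonotype tables: CDR3 physicochemistry,
diversity, convergent recombination, publicity, motif clustering and
specificity-database annotation — plus a synthetic V(D)J cohort
generator so the whole pipeline is testable without deposited
sequencing data.

## The problem

TCR repertoires of CD4+ and CD8+ TILs differ in ways that may reflect
antigen recognition in the tumor: CD4+ TILs tend to carry longer
non-germline N(D)N junction regions, more positively charged residues
in the center of the CDR3β loop, and a more restricted (clonal)
repertoire enriched for shared amino-acid motifs. `tilrep` implements
the full comparison as a reusable pipeline for anyone working with
bulk TCR clonotype tables (VDJTools-style or AIRR Rearrangement TSV):

- **Preprocessing** — productive filter, cross-sample decontamination
  (a clonotype is removed from a sample when another sample carries it
  at ≥ 20× the frequency), per-patient merging of biopsy slices, and
  collapse of nucleotide variants onto CDR3aa clonotypes.
- **CDR3 features** — CDR3nt and N(D)Nnt length statistics
  (N(D)N = `j_start − v_end` within the CDR3), and frequency-weighted
  physicochemical profiles of the central CDR3 5-mer,
  `P = Σᵢ fᵢ · (Σ_{a∈5-mer} s(a))/5`, for charge, Kyte–Doolittle
  hydropathy and polarity scales.
- **Repertoire statistics** — normalized Shannon–Wiener diversity
  `nS-W = H/ln S` with `H = −Σ fᵢ ln fᵢ`; convergent-recombination
  level `CR = (#distinct CDR3nt)/(#distinct CDR3aa)`; publicity
  (CDR3aa shared by ≥ 2 patient-merged biopsies) and the publicity ×
  convergence cross-tabulation.
- **Motif clustering** — GLIPH-style enumeration of 3–5-mer exact and
  single-wildcard (`%`) motifs from the CDR3 interior, scored against a
  reference repertoire by a one-sided Fisher exact p-value and a
  permutation *expansion score* (do the motif's carriers hold more
  clonal frequency than random same-size sets?); motifs passing both
  thresholds become clusters, with cross-biopsy sharing tables.
- **Annotation** — candidate sets (frequency > 0.1%, public,
  clustered) matched against a specificity database (CDR3aa +
  category ∈ {allergy, autoimmunity, cancer, pathogens}) at
  Levenshtein distance ≤ 1, with cancer annotations propagated to all
  members of a matching motif cluster.
- **Statistics** — one-way ANOVA + Tukey, paired t, two-way ANOVA +
  Šidák, Pearson correlation, with degenerate-input errors instead of
  NaNs.

## Worked example

The numbered drivers under `analysis/` run the full study analogue on
a synthetic cohort (8 patients × 2 biopsy slices × {initial, CD4,
CD8}; config in `configs/study.yaml`):

```bash
cd analysis
python 01_simulate_cohort.py   # generate cohort + specificity DB
python 02_preprocess.py        # filter / decontaminate / merge / collapse
python 03_cdr3_features.py
python 04_repertoire_stats.py
python 07_group_comparisons.py # (05/06: motifs and annotation)
```

`03_cdr3_features.py` prints the per-compartment feature means:

```
             cdr3nt_mean  ndn_mean  charge  hydropathy  polarity
CD4               46.749    14.247   0.071      -0.547     0.558
CD8               43.802    11.302  -0.004      -0.762     0.662
initial           45.300    12.803   0.052      -0.633     0.631
```

CD4-like repertoires carry ~3 nt longer N(D)N junctions and a more
positive central-5-mer charge than CD8-like ones — the planted group
structure, recovered by the downstream statistics
(`07_group_comparisons.py`):

```
               panel      method  statistic      p
    diversity_paired    paired_t    -3.3621 0.0120
        charge_anova anova_tukey     4.0622 0.0323
           ndn_anova anova_tukey   218.4428 0.0000
diversity_vs_pct_cd4     pearson    -0.9913 0.0000
```

The paired test finds CD8-like repertoires significantly more diverse,
and diversity correlates inversely with the CD4+ fraction of the
unsorted initial cultures, because a higher CD4 content plants more
clonality.

The same pipeline runs from a single command on any config (or on real
tables via a sample sheet):

```bash
tilrep run-all -c configs/demo.yaml
```

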