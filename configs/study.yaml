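# Study-analogue synthetic cohort: 8 patients, 2 biopsy slices each,
# unsorted initial cultures (CD4/CD8 mixtures) plus sorted compartments.
mode: synthetic
seed: 20230804
output_dir: results/study
dialect: vdjtools

cohort:
  n_patients: 8
  slices_per_patient: 2
  n_clonotypes: 800
  reference_size: 4000
  compartments:
    - {label: initial, preset: initial, mixture: true}
    - {label: CD4, preset: cd4, planted_motifs: [["SLGG%GE", 40], ["SQGA%GE", 25]]}
    - {label: CD8, preset: cd8, planted_motifs: [["%NYSNQP", 20]]}
  public_injection:
    - ["CASSLAPGATNEKLFF", 2]
    - ["CASSQDRGHYGYTF", 3]
    - ["CASSPDRVGQETQYF", 2]
    - ["CASSFDRGEYGYTF", 2]

decontamination_ratio: 20
diversity_level: nt
scales: [charge, hydropathy, polarity]

motifs:
  fisher_max: 0.5
  expansion_max: 0.5
  k_exact: [3, 4, 5]
  k_wild: [5, 6, 7]
  min_carriers: 3
  b: 300

freq_threshold: 0.001

db:
  synthetic: {allergy: 20, autoimmunity: 25, cancer: 30, pathogens: 40}
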