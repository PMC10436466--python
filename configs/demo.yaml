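# Demo synthetic study analogue: 3 patients, 2 biopsy slices each,
# unsorted initial cultures plus sorted CD4/CD8 compartments.
mode: synthetic
seed: 1
output_dir: results/demo
dialect: vdjtools

cohort:
  n_patients: 3
  slices_per_patient: 2
  n_clonotypes: 300
  reference_size: 1500
  compartments:
    - {label: initial, preset: initial, mixture: true}
    - {label: CD4, preset: cd4, planted_motifs: [["SLGG%GE", 15]]}
    - {label: CD8, preset: cd8, planted_motifs: [["%NYSNQP", 8]]}
  public_injection:
    - ["CASSLAPGATNEKLFF", 2]
    - ["CASSQDRGHYGYTF", 3]

decontamination_ratio: 20
diversity_level: nt
scales: [charge, hydropathy, polarity]

motifs:
  fisher_max: 0.5
  expansion_max: 0.5
  k_exact: [3, 4, 5]
  k_wild: [5, 6, 7]
  min_carriers: 2
  b: 200

freq_threshold: 0.001

db:
  synthetic: {allergy: 10, autoimmunity: 10, cancer: 15, pathogens: 20}
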