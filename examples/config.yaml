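# One config drives both cohort simulation and analysis.
simulation:
  seed: 42
  n_proteins: 120
  protein_length: [150, 450]
  n_patients: 60
  mutation_rate: 0.0025
  synonymous_rate: 0.0025
  fraction_undetected: 0.25
  survival: {D1: 0.9, D2: 0.77}   # immune survival of expressed displayed mutations

analysis:
  mode: patient
  variant_class: missense
  strong_binder_threshold: 50
  peptide_length: 9
  bootstrap_reps: 500
  rng_seed: 42
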