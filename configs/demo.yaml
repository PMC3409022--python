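# Demo: three simulated multi-case families (5+3, 3+4, 3+6 individuals,
# three technical replicates each -> 144 arrays from 24 cell lines) with a
# PTC gene planted in every affected member of family B.
seed: 7
simulation:
  families:
    - [A, 5, 3]
    - [B, 3, 4]
    - [C, 3, 6]
  replicates: 3
  n_probes: 2000
  probes_per_gene: 2
  planted:
    - gene: GENE00010
      family: B
      log2_fold: 0.585   # ~1.5-fold stabilisation at full NMD inhibition
      carriers: all_affected
policy:
  alpha: 0.05
  require_positive_B: true
  direction: up
  affected_rule: all
  unaffected_exclusion: same_family
  fold_report_thresholds: [1.5, 2.0]
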