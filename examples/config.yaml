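# Demo pipeline configuration: six simulated cohorts sharing three modules,
# with nine module-1 genes driving survival (hazard ratio 2.5 per unit score).
seed: 42

simulation:
  cancers: [BRCA, COAD, GBM, LUAD, OVCA, READ]
  samples_per_cancer: [200, 200, 200, 200, 200, 200]
  n_genes: 330
  modules:
    - {name: mod1, size: 40, member_cancers: [BRCA, COAD, GBM, LUAD, OVCA, READ], within_correlation: 0.8}
    - {name: mod2, size: 35, member_cancers: [BRCA, COAD, GBM, LUAD, OVCA, READ], within_correlation: 0.7}
    - {name: mod3, size: 30, member_cancers: [BRCA, COAD, GBM, LUAD, OVCA, READ], within_correlation: 0.7}
  risk:
    risk_genes: [G0001, G0002, G0003, G0004, G0005, G0006, G0007, G0008, G0009]
    log_hazard_per_unit: 0.9162907318741551  # ln 2.5
    baseline_hazard: 0.0011111111111111111   # 1/900 per day
    censoring_rate: 0.2

parameters:
  min_module_size: 30
  power: 6
  n_perm: 100
  risk_p_threshold: 0.01
  risk_threshold_years: 2.0
  n_rd: 100
  rd_size: 100
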