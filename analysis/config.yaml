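# Demo-scale study configuration: 2,000 participants, 1,000 variants,
# 6 GWAS-like sources (3 disease, 3 risk-factor), guideline thresholds.
output_dir: scratch/pipeline
seed: 7
simulate:
  n_samples: 2000
  n_variants: 1000
  n_causal: 100
  n_sources: 6
  n_risk_factor_sources: 3
  n_pcs: 4
  seed: 7
split:
  tune_frac: 0.15
  train_frac: 0.45
meta:
  alphas: [0, 0.1, 0.25, 0.5, 0.75, 0.9, 1]
  n_folds: 10
  n_lambda: 30
evaluate:
  n_boot_auc: 500
  n_boot_delta: 200
  n_boot_nri: 200
  n_boot_screen: 100
  stage1_threshold: 0.056
  nri_threshold: 0.10
  stage2_threshold: 0.143
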