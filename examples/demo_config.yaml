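# Demo pipeline configuration: a 37-study synthetic cohort under the
# default degradation conditions.  Run with:
#   cectfidelity report --config examples/demo_config.yaml --out results/demo
mode: phantom
n_studies: 37
seed: 1
output_dir: results/demo
bootstrap_reps: 2000
simulate_raters: true
phantom:
  p_malignant: 0.89
  noise_sigma: 7.0
  blur_range: [0.5, 1.5]
  bias_sd: 15.0
  damping_range: [0.0, 0.3]
  residual_noise_range: [2.0, 8.0]
proxy:
  cv_cutoff: 0.25
  solidity_cutoff: 0.95
  sharpness_cutoff: 0.75
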