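# Demo pipeline configuration for `biofilm-mech run --config pipeline_demo.yaml`.
# Generates synthetic inputs, analyses them, and runs the stability scan + fit.
stages: [synth, metrics, theory]
seed: 0
units: Pa
theory:
  gr_over_gf: 0.1
  hr_over_hf: 0.3
  ratio_start: 0.05
  ratio_stop: 1000.0
  ratio_num: 40
  slope_window: [10.0, 1000.0]
synth:
  lambda_mm: 1.0
  colony_radius_mm: 6.0
  noise_sigma: 0.02
  petal_count: 6
  t_c_hr: 40.0
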