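# Demo analysis: synthetic control vs pre-neoplastic cohort.
# Run with:  chromatex run --config configs/demo.yaml
seed: 7
output_dir: results/demo
simulate:
  n_control: 12
  n_case: 12
  image_size: 256
  pixel_size_nm: 15.0
  resolution_nm: 30.0
  ellipse_axes_nm: [1700, 1300]
  control:
    d_true: 2.5            # fractal chromatin correlations
    lc_true_nm: 120.0
    hetero_fraction_true: 0.342
    peripheral_bias: 1.5   # peripheral heterochromatin border present
  case:
    d_true: 3.5            # stretched-exponential regime
    lc_true_nm: 200.0      # larger clumps
    hetero_fraction_true: 0.429
    peripheral_bias: 0.0   # border lost
analysis:
  ribbon_width_nm: 30.0
  threshold: otsu
  cutoff: 0.02
  d_step: 0.05
  alpha: 0.05
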