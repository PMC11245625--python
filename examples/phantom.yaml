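# Three-ring cylinder at brain-like SNR with a synthetic cohort.
# Run: helmept run --config examples/phantom.yaml --seed 17 --out out/
phantom:
  geometry:
    shape: [48, 48, 48]
    spacing_mm: [2.0, 2.0, 2.0]
    layout: concentric_cylinders
    outer_diameter_mm: 80.0
    ring_widths_mm: [14.0, 13.0, 13.0]
    height_mm: 80.0
  compartments:
    - {label: 1, sigma: 0.7, eps_r: 50.0, i0: 1.0, fvf: 0.05}
    - {label: 2, sigma: 0.3, eps_r: 50.0, i0: 1.3, fvf: 0.30}
    - {label: 3, sigma: 1.1, eps_r: 50.0, i0: 0.8, fvf: 0.10}
  field:
    frequency_hz: 123.0e6
  snr_db: 30.0
  dixon:
    noise_sd: 0.02

kernel:
  window: 15

organs:
  1: inner
  2: middle
  3: outer

cohort:
  n_subjects: 17
  organs:
    wm: {sigma0: 0.59, age_slope: 0.0017, residual_sd: 0.03}
    liver: {sigma0: 0.90, fvf_slope: -1.0, residual_sd: 0.06}
    heart: {sigma0: 0.62, sex_offset: 0.05, residual_sd: 0.05}

alpha: 0.05
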