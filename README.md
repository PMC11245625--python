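# helmept

Helmholtz MR electrical properties tomography (MR-EPT) at desk scale:
synthetic admittivity phantoms with analytic ground truth, conductivity
reconstruction from complex UTE-like signals via the square-root Helmholtz
formulation with a segmentation-constrained bi-adaptive Savitzky–Golay
Laplacian, eroded-ROI statistics, and cohort-level regression analysis.

## Who this is for

MR physicists and image-analysis researchers who want a tested, reproducible
implementation of simple Helmholtz conductivity mapping — to benchmark kernel
strategies, to study noise propagation into ROI statistics, or to plan
cohort studies of in vivo conductivity against biological covariates (age,
sex, BMI, fat fraction) — without access to scanner data: every component
can be exercised end to end on synthetic volumes whose true admittivity is
known in closed form.

## The model

For a small-flip-angle UTE acquisition the complex signal is
S = I0·B1+·B1−. Where electrical properties and I0 are piecewise constant,
the admittivity κ = σ + iωε follows from the homogeneous Helmholtz equation
as

σ = Re(κ) = Re[ (1/(iμ0ω)) · Δ√S / √S ]

with √S taken as the magnitude root and half the (constant-shift unwrapped)
phase. The Laplacian Δ√S is estimated per voxel by a second-order 3-D
Savitzky–Golay fit over a *bi-adaptive* neighbourhood: all voxels of the
centre's segmentation class within a large N³ window, then the n nearest in
physical distance. Restricting each fit to one tissue class keeps boundary
bias confined while the fixed neighbour count keeps the fit overdetermined
against noise. Organ values are reported as mean/median/SD over
single-voxel-eroded ROIs (the median is the preferred, outlier-robust
estimate), and cohort tables are analysed by univariate Pearson/OLS
regression with multivariate follow-up. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from helmept import (PhantomGeometry, CompartmentSpec, FieldModel,
                     make_label_volume, make_field, apply_contrast,
                     add_noise, reconstruct, KernelConfig, summarize_roi)

geo = PhantomGeometry(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                      outer_diameter_mm=80.0, ring_widths_mm=(14.0, 13.0, 13.0),
                      height_mm=80.0)
comps = [CompartmentSpec(label=1, sigma=0.7, eps_r=50.0),
         CompartmentSpec(label=2, sigma=0.3, eps_r=50.0),
         CompartmentSpec(label=3, sigma=1.1, eps_r=50.0)]
labels = make_label_volume(geo, comps)
signal = apply_contrast(make_field(labels, comps), labels, comps)
noisy = add_noise(signal, snr_db=30.0, seed=7)          # brain-like SNR
amap = reconstruct(noisy, labels, KernelConfig(window=15), 123e6)
for c in comps:
    s = summarize_roi(amap, labels, c.label)
    print(f"ring {c.label}: true {c.sigma:.2f}  median {s.median_sigma:.3f} "
          f"mean {s.mean_sigma:.3f}  sd {s.sd_sigma:.3f}  n={s.n_voxels}")
```

prints

```
ring 1: true 0.70  median 0.716 mean 0.721  sd 0.143  n=4560
ring 2: true 0.30  median 0.323 mean 0.319  sd 0.100  n=10944
ring 3: true 1.10  median 1.063 mean 1.081  sd 0.186  n=19456
```

The ROI medians sit within a few percent of the programmed conductivities at
30 dB SNR (over repeated noise seeds the median's absolute error beats the
mean's in ~80% of runs, which is why the median is the reported estimator).
The SD column is the per-voxel spread inside each eroded ROI, largest where
the local signal is faintest.

The same pipeline runs from the shell:

```
helmept samplesize --sd 0.3 --margin 0.16 --confidence 0.95 --dropout 0.15
helmept run --config examples/phantom.yaml --seed 17 --out out/
```

`run` writes `sigma.nii.gz`, `valid.nii.gz`, `roi_summary.csv`,
`regressions.csv` (when a cohort is configured) and a `log.json` with every
seed and kernel setting; a rerun with the same config and seed is
bit-identical for the deterministic stages.

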