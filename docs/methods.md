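# Methods

## The reconstruction model

`helmept` estimates tissue electrical conductivity from the complex signal of
a small-flip-angle ultrashort echo-time (UTE) acquisition. In that regime the
signal is, up to a non-RF contrast term,

    S = I0 · B1+ · B1−,

the product of the transmit and receive radiofrequency fields. Where the
electrical properties and I0 are piecewise constant, each RF field component
satisfies the homogeneous Helmholtz equation, and combining the two equations
gives the square-root formulation

    κ = σ + iωε = (1 / (i μ0 ω)) · Δ√S / √S,

with μ0 the vacuum permeability (tissue is non-magnetic at RF), ω = 2πf the
Larmor angular frequency, and Δ the Laplacian. The conductivity map is the
real part of κ. The square root of S takes the magnitude square root and
half the phase; because the method uses the full transceive phase it does not
rely on the transceive-phase assumption, but it does require the phase to be
unwrapped first.

Model assumptions, and hence failure modes:

- **Piecewise-constant electrical properties and I0.** Violations appear as
  bias in extended, slowly varying structures.
- **Phase span below 2π.** Phase is unwrapped by a constant branch shift
  only (see below); signals whose true phase spans more than 2π per
  segmentation class are out of scope.
- **Adequate SNR.** The ratio of a second derivative to the signal is noise
  hungry; low-signal voxels produce heavy-tailed, occasionally negative
  conductivity estimates. Negative values are deliberately preserved — they
  are a diagnostic, not an artifact to be clipped.

## Phase handling

`unwrap_phase_constant` histograms the wrapped foreground phase and looks
for the widest circular gap. If that gap excludes the ±π branch point — the
occupied arc crosses ±π while some interior arc of at least π/4 is empty —
the branch below the gap centre is shifted up by 2π; otherwise the phase is
returned unchanged. This is a constant-shift unwrap: it never alters phase
differences mod 2π and is safe to apply unconditionally, but it can only fix
distributions whose true span is below 2π.

## The bi-adaptive Savitzky–Golay Laplacian

The Laplacian at each voxel comes from a least-squares fit of the full 3-D
quadratic (10 monomials) to complex √S over a neighbourhood chosen in two
stages:

1. **Class constraint.** All voxels inside an N³ selection window (clipped
   at the volume border, never padded) that share the centre's segmentation
   label. This confines every fit to one tissue class, which is what keeps
   boundary bias local instead of smearing across interfaces.
2. **Nearest-neighbour cut.** Of those candidates, the n nearest in
   *physical* Euclidean distance (honouring anisotropic spacing), ties at
   the cutoff broken by lexicographic voxel index so results are independent
   of traversal order. The centre voxel is always retained.

The fit runs in physical coordinates (metres) centred on the target voxel,
internally rescaled by the mean voxel size to keep the normal equations well
conditioned. The Laplacian is 2(c_xx + c_yy + c_zz) and the reported
quantity is its ratio to the *fitted constant term* rather than the raw
centre voxel: numerator and denominator then share the same smoothing, which
is markedly more stable under noise. No other pre- or post-filtering is
applied anywhere.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `window` (N) | 15 | selection window per axis, odd voxels; 15 suits ~1.2 mm grids, 23 coarser ~2 mm torso grids |
| `n_neighbors` | ⌈0.3 N³⌉ (1013 for N = 15) | voxels kept for the fit; keeps the 10-term fit ~100× overdetermined |
| `min_voxels` | 20 | below this many same-class candidates the voxel is marked invalid |
| polynomial order | 2 (fixed) | quadratic basis is the minimum that carries a Laplacian and the accepted optimum against noise amplification |

Voxels whose candidate set is starved (thin structures) or degenerate
(coplanar, detected by an eigenvalue ratio below 1e-10 on the normal
matrix) are marked invalid (NaN) rather than extrapolated.

Two execution paths produce identical output: a per-voxel reference path
used directly by the tests, and a vectorised path that exploits the shared
window-offset geometry (per-offset gathers, one large matrix product for all
normal matrices, batched 10×10 solves). A 64³ phantom reconstructs in
roughly 10 s on one CPU.

## Synthetic phantoms

Because the formulation is exact for piecewise Helmholtz fields, the
generator fills each compartment with an analytic plane wave

    B(r) = exp(−i k d·(r − r0)),   k² = μ0 ε ω² − i μ0 σ ω,

so that Δ√S/√S = −k² holds in the continuum and the whole pipeline has a
closed-form ground truth — no electromagnetic solver is involved. The
signal is S = I0(label)·B², with complex Gaussian noise added at a
prescribed SNR (convention: 20·log10(mean foreground |S| / per-channel noise
SD); brain-like ≈ 30 dB, torso-like ≈ 15 dB).

A physical constraint shapes the geometry: any Helmholtz solution satisfies
(phase rate)·(decay rate) ≥ μ0σω/2, so at 123 MHz and σ = 1.5 S/m the
squared-signal phase advances ~60 rad/m along the propagation direction.
The concentric-cylinder layout therefore has a finite height (e.g. 96 mm on
the 64³ acceptance phantom) so arg(S) stays inside (−π, π];
`make_field` raises if a compartment would wrap. Compartment permittivity
defaults to ε_r = 50 (mid-range soft tissue at 123 MHz); conductivities are
configurable, with study phantoms spanning 0.2–1.5 S/m.

What the phantoms do **not** emulate: birdcage coil field curvature and
standing-wave magnitude profiles, receive-array combination, k-space
trajectories and Gibbs ringing, relaxation contrast within a compartment,
registration and segmentation error (labels are exact). Passing tests
therefore validate the estimator and its noise behaviour under the stated
model, not the full in vivo error budget. Notably the plane-wave magnitude
decays ~3–10× across a compartment, so the faint end of each compartment
sees a locally *worse* SNR than the nominal figure — a harsher condition
than a typical birdcage field.

## ROI statistics

Organ masks are eroded by one voxel (face-connected, 6-neighbour
structuring element; 26-connectivity available) before statistics, because
reconstruction quality degrades at interfaces. Mean, median, sample SD
(n−1) and voxel count are computed over the eroded mask intersected with the
validity mask. The median is the preferred location estimate: per-voxel
errors are heavy-tailed and the simulation studies show the median's
absolute error beats the mean's in the large majority of noise realisations.
Fat volume fraction is the mean of F/(W+F) over the eroded ROI, excluding
(and counting) voxels with W+F = 0. Being a mean of voxelwise ratios, this
estimator carries a second-order noise bias E[FVF] − f ≈ s²(2f − 1)/T²
(s the channel noise SD, T = W+F): about −0.001 at f = 0.3 with s/T = 5%,
vanishing at f = 0.5. The magnitude is negligible for reporting but is
resolved by a sufficiently powerful Monte-Carlo, and the tests account for
it explicitly.

## Cohort statistics

Univariate analysis is an OLS line fit with the two-tailed Pearson test
(t = r√((n−2)/(1−r²)) on n−2 df); sex is coded M = 1, F = 0 so positive
coefficients read male-minus-female. Confidence bands are for the mean
prediction. Multivariate follow-up (when two or more predictors are
significant) is a Gaussian linear model via statsmodels with per-coefficient
t-tests and an explicit collinearity check. Significance is a strict
p < 0.05 screen without multiple-testing correction — deliberate for a small
exploratory cohort; a Benjamini–Hochberg option exists but is off by
default. Missing organ values are deleted pairwise, so n can differ per
organ.

Study design uses the normal-quantile sample-size formula
n = ⌈(z·sd/margin)²⌉ (e.g. sd 0.3 S/m, margin 0.16 S/m, 95% → 14 subjects)
and recruitment inflation ⌈n/(1−dropout)⌉ (15% → 17).

The synthetic cohort generator samples age uniformly over 25–73 y, BMI over
19.6–32.6 kg/m², sex Bernoulli (10/17 male), and per-organ fat fractions
uniformly over configurable ranges, then builds organ median conductivity as
a programmed linear model plus Gaussian residual. Defaults emulate the kind
of structure this pipeline is meant to detect: white-matter conductivity
rising ~0.0017 S/m per year around 0.66 S/m, liver conductivity falling with
fat fraction, a small male–female heart offset — magnitudes consistent with
reported in vivo spreads, not fitted to any dataset.

## Study problem sizes

Desk-scale studies are sized for a single CPU: the noiseless accuracy study
uses a 64³, 2 mm, five-ring cylinder (σ ∈ {0.2, 0.5, 0.7, 1.0, 1.5} S/m)
with a 9³ kernel — the same ~18 mm physical extent as the 15³ brain kernel
at 1.2 mm; the repeated-noise study uses a 40³, 2.4 mm three-ring cylinder
with the brain-default 15³ kernel (≈1000 neighbours, matching the noise
averaging of the in vivo configuration), 50 noise seeds at 30 dB and 8
matched seeds at 15 dB; cohort calibration uses 1000 null replicates and 500
synthetic cohorts at n = 15.

## Numerical choices

- Normal-equation solve with coordinates rescaled by the mean voxel size;
  degeneracy threshold 1e-10 on the eigenvalue ratio.
- Savitzky–Golay fit is unweighted (no window taper).
- Noise is complex Gaussian, equal SD per channel; the same seed gives
  bit-identical volumes.
- Window clipped (not padded) at volume borders; periphery quality degrades
  accordingly and is left visible.
- Negative conductivity is preserved and flagged by the validity mask only
  when the fit itself failed, never for the sign of the estimate.

## Known limitations

- Constant-shift unwrapping limits the admissible phase span; spatial
  unwrapping is not implemented.
- Permittivity (imaginary part of κ) is carried through but its accuracy is
  not studied; Helmholtz EPT permittivity is substantially noisier than
  conductivity.
- The plane-wave phantom exercises edge behaviour via discontinuities, but
  cannot reproduce coil-specific spatial bias patterns.
- Runtime scales linearly in foreground voxels × window volume; very large
  windows (23³) on large volumes are minutes, not seconds.
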