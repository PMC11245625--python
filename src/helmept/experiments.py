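"""Desk-scale simulation studies exercising the full pipeline.

These are the package's equivalents of a proof-of-concept simulation: small
cylindrical phantoms with analytically known admittivity, reconstructed and
summarised end to end.  They are shared by the test suite and the acceptance
script so both measure exactly the same computation.

Problem sizes are chosen for single-CPU desk runs: a 64^3 grid (2 mm voxels,
five 12 mm rings, 96 mm cylinder height) for the noiseless accuracy study and
a 48^3 grid (three rings, 80 mm height) for the repeated-noise study.  The
cylinder heights keep the squared-signal phase of the most conductive ring
inside a single branch (see :mod:`helmept.phantom`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import (
    CohortSpec,
    CompartmentSpec,
    FieldModel,
    OrganEffect,
    PhantomGeometry,
    add_noise,
    apply_contrast,
    make_cohort,
    make_field,
    make_label_volume,
)
from .recon import KernelConfig, reconstruct
from .roi import summarize_roi
from .stats import univariate

__all__ = [
    "five_ring_phantom",
    "three_ring_phantom",
    "noiseless_accuracy_study",
    "noise_robustness_study",
    "cohort_recovery_study",
    "null_calibration_study",
]

BRAIN_SNR_DB = 30.0
TORSO_SNR_DB = 15.0


def five_ring_phantom():
    """64^3, 2 mm five-ring cylinder spanning sigma 0.2-1.5 S/m at 123 MHz."""
    geometry = PhantomGeometry(
        shape=(64, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        outer_diameter_mm=120.0,
        ring_widths_mm=(12.0, 12.0, 12.0, 12.0, 12.0),
        height_mm=96.0,
    )
    sigmas = (0.2, 0.5, 0.7, 1.0, 1.5)
    i0s = (1.0, 0.8, 1.2, 0.9, 1.1)  # piecewise contrast, exercised downstream
    compartments = [
        CompartmentSpec(label=i + 1, sigma=s, eps_r=50.0, i0=a)
        for i, (s, a) in enumerate(zip(sigmas, i0s))
    ]
    return geometry, compartments, FieldModel()


def three_ring_phantom():
    """40^3, 2.4 mm three-ring cylinder for repeated noisy reconstructions."""
    geometry = PhantomGeometry(
        shape=(40, 40, 40),
        spacing=(2.4, 2.4, 2.4),
        outer_diameter_mm=80.0,
        ring_widths_mm=(14.0, 13.0, 13.0),
        height_mm=80.0,
    )
    sigmas = (0.7, 0.3, 1.1)
    i0s = (1.0, 1.3, 0.8)
    compartments = [
        CompartmentSpec(label=i + 1, sigma=s, eps_r=50.0, i0=a)
        for i, (s, a) in enumerate(zip(sigmas, i0s))
    ]
    return geometry, compartments, FieldModel()


def _clean_signal(geometry, compartments, model):
    labels = make_label_volume(geometry, compartments)
    field = make_field(labels, compartments, model)
    return labels, apply_contrast(field, labels, compartments)


def noiseless_accuracy_study(kernel: KernelConfig = KernelConfig(window=9)) -> pd.DataFrame:
    """Noiseless five-ring reconstruction: ROI medians vs programmed truth.

    Returns one row per compartment with the programmed conductivity, the
    eroded-ROI median/mean/SD of the reconstruction and the relative error of
    the median.
    """
    geometry, compartments, model = five_ring_phantom()
    labels, signal = _clean_signal(geometry, compartments, model)
    amap = reconstruct(signal, labels, kernel, model.frequency_hz)
    rows = []
    for comp in compartments:
        s = summarize_roi(amap, labels, comp.label)
        rows.append(
            {
                "label": comp.label,
                "sigma_true": comp.sigma,
                "median_sigma": s.median_sigma,
                "mean_sigma": s.mean_sigma,
                "sd_sigma": s.sd_sigma,
                "n_voxels": s.n_voxels,
                "median_rel_err": abs(s.median_sigma - comp.sigma) / comp.sigma,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NoiseStudyResult:
    """Repeated noisy reconstructions of the three-ring phantom."""

    sigma_true: float  # programmed central-compartment conductivity
    medians_30db: np.ndarray  # per-seed eroded-ROI medians at 30 dB
    means_30db: np.ndarray
    sds_30db: np.ndarray
    sds_15db: np.ndarray  # matched-seed ROI SDs at 15 dB
    median_beats_mean: float  # fraction of seeds with |med-truth| <= |mean-truth|

    @property
    def median_rel_errs(self) -> np.ndarray:
        return np.abs(self.medians_30db - self.sigma_true) / self.sigma_true


def noise_robustness_study(
    n_seeds: int = 50,
    n_seeds_15db: int = 8,
    seed: int = 0,
    kernel: KernelConfig = KernelConfig(window=15),
) -> NoiseStudyResult:
    """Noise behaviour of the central compartment over repeated seeds.

    Reconstructs the three-ring phantom at brain-like 30 dB SNR for
    ``n_seeds`` noise realisations (and at torso-like 15 dB for the first
    ``n_seeds_15db`` matched seeds) and summarises the central compartment.
    The selection window is the brain default N = 15, which keeps the
    neighbour count (~1000) of the in vivo configuration and hence its
    noise-averaging behaviour.
    """
    geometry, compartments, model = three_ring_phantom()
    labels, signal = _clean_signal(geometry, compartments, model)
    central = compartments[0]
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=n_seeds)

    medians, means, sds, sds15 = [], [], [], []
    for i, sub in enumerate(subseeds):
        noisy = add_noise(signal, BRAIN_SNR_DB, int(sub))
        amap = reconstruct(noisy, labels, kernel, model.frequency_hz)
        s = summarize_roi(amap, labels, central.label)
        medians.append(s.median_sigma)
        means.append(s.mean_sigma)
        sds.append(s.sd_sigma)
        if i < n_seeds_15db:
            noisy15 = add_noise(signal, TORSO_SNR_DB, int(sub))
            amap15 = reconstruct(noisy15, labels, kernel, model.frequency_hz)
            sds15.append(summarize_roi(amap15, labels, central.label).sd_sigma)

    medians = np.asarray(medians)
    means = np.asarray(means)
    beats = np.abs(medians - central.sigma) <= np.abs(means - central.sigma)
    return NoiseStudyResult(
        sigma_true=central.sigma,
        medians_30db=medians,
        means_30db=means,
        sds_30db=np.asarray(sds),
        sds_15db=np.asarray(sds15),
        median_beats_mean=float(np.mean(beats)),
    )


def cohort_recovery_study(
    n_seeds: int = 500,
    n_subjects: int = 15,
    residual_sd: float = 0.05,
    effect_to_noise: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power and bias of the univariate age regression on synthetic cohorts.

    The programmed age slope is sized so that slope x age-range equals
    ``effect_to_noise`` times the residual SD.  Returns the empirical power
    (fraction of seeds with p < alpha), the mean slope bias and the mean
    standard error of the slope estimates.
    """
    age_lo, age_hi = 25.0, 73.0
    slope = effect_to_noise * residual_sd / (age_hi - age_lo)
    organs = {
        "organ": OrganEffect(sigma0=0.6, age_slope=slope, residual_sd=residual_sd)
    }
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    slopes, ses, pvals = [], [], []
    for sub in subseeds:
        spec = CohortSpec(
            n_subjects=n_subjects,
            organs=organs,
            age_range=(age_lo, age_hi),
            seed=int(sub),
        )
        table = make_cohort(spec)
        res = univariate(table["organ_sigma"], table["age"], "organ", "age")
        slopes.append(res.slope)
        ses.append(np.sqrt(res.resid_var / res.sxx))
        pvals.append(res.p)
    slopes = np.asarray(slopes)
    return {
        "slope_true": slope,
        "power": float(np.mean(np.asarray(pvals) < alpha)),
        "mean_bias": float(np.mean(slopes - slope)),
        "mean_se": float(np.mean(ses)),
    }


def null_calibration_study(
    n_reps: int = 1000, n_subjects: int = 15, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I rate of the univariate test under a simulated null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x = rng.uniform(25.0, 73.0, n_subjects)
        y = rng.normal(0.6, 0.05, n_subjects)
        if univariate(y, x).p < alpha:
            hits += 1
    return hits / n_reps
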