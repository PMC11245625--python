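"""Synthetic MR-EPT phantoms with analytic Helmholtz ground truth.

This module stands in for acquired data.  It builds multi-compartment label
volumes (concentric cylinders or spherical blobs), fills each compartment with
an exact plane-wave solution of the homogeneous Helmholtz equation for the
programmed admittivity, applies piecewise-constant signal contrast, adds
complex Gaussian noise at a prescribed SNR, generates Dixon-style water/fat
magnitude pairs, and samples synthetic subject cohorts with programmed linear
conductivity dependencies.

The field inside a compartment with conductivity sigma (S/m) and relative
permittivity eps_r is

    B(r) = exp(-i k d.(r - r0)),   k^2 = mu0*eps*omega^2 - i*mu0*sigma*omega,

with d a unit wave direction and r0 the volume centre, so the continuum ratio
Laplacian(B)/B equals -k^2 exactly and the square-root Helmholtz formula
recovers kappa = sigma + i*omega*eps without discretisation bias.  Because
the phase rate Re(k) of any Helmholtz solution is bounded below by the
conduction term, compartment extent along the wave direction is limited (via
the cylinder height) so that arg(S) of the squared signal stays inside
(-pi, pi]; :func:`make_field` enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0, mu_0

from .volumes import ComplexVolume, LabelVolume, ScalarVolume, check_aligned

__all__ = [
    "CompartmentSpec",
    "PhantomGeometry",
    "FieldModel",
    "OrganEffect",
    "CohortSpec",
    "make_label_volume",
    "make_field",
    "apply_contrast",
    "add_noise",
    "make_dixon",
    "make_cohort",
    "wavenumber",
    "COHORT_PREDICTORS",
]


@dataclass(frozen=True)
class CompartmentSpec:
    """Electromagnetic and contrast properties of one phantom compartment."""

    label: int
    sigma: float  # conductivity, S/m
    eps_r: float = 50.0  # relative permittivity (soft tissue ~40-80 at 123 MHz)
    i0: float = 1.0  # proton-density/relaxation contrast scale, > 0
    fvf: float = 0.0  # fat volume fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("compartment label must be a positive integer")
        if self.eps_r < 1:
            raise ValueError("relative permittivity must be >= 1")
        if self.i0 <= 0:
            raise ValueError("contrast scale i0 must be > 0")
        if not 0.0 <= self.fvf <= 1.0:
            raise ValueError("fat volume fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid and layout description of a phantom.

    ``concentric_cylinders`` builds nested annuli about one grid axis:
    section 1 is the central disk of radial width ``ring_widths_mm[0]``,
    section i the annulus of width ``ring_widths_mm[i-1]``.  ``height_mm``
    limits the cylinder extent along the axis (None = full grid), which keeps
    the squared-signal phase within a single branch for conductive media.
    ``blobs`` paints spheres (centres relative to the volume centre, mm) in
    order.  ``fit="strict"`` raises when the layout exceeds the grid;
    ``fit="clip"`` silently clips (useful for a compartment filling the grid).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    layout: str = "concentric_cylinders"
    outer_diameter_mm: float = 300.0
    ring_widths_mm: tuple[float, ...] = (30.0, 30.0, 30.0, 30.0, 30.0)
    height_mm: Optional[float] = None
    axis: int = 2
    blob_centers_mm: tuple[tuple[float, float, float], ...] = ()
    blob_radii_mm: tuple[float, ...] = ()
    fit: str = "strict"

    def __post_init__(self) -> None:
        if self.layout not in ("concentric_cylinders", "blobs"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.layout == "concentric_cylinders":
            widths = tuple(self.ring_widths_mm)
            if abs(sum(widths) - self.outer_diameter_mm / 2) > 1e-6:
                raise ValueError(
                    "ring widths must sum to the outer radius: "
                    f"sum={sum(widths)} mm vs radius={self.outer_diameter_mm / 2} mm"
                )
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.fit not in ("strict", "clip"):
            raise ValueError("fit must be 'strict' or 'clip'")

    @property
    def n_compartments(self) -> int:
        if self.layout == "concentric_cylinders":
            return len(self.ring_widths_mm)
        return len(self.blob_radii_mm)

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class FieldModel:
    """RF field model: operating frequency and plane-wave directions.

    ``direction`` is the default unit wave vector (the cylinder axis by
    default); ``directions`` overrides it per compartment label.
    """

    frequency_hz: float = 123e6
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    directions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        for d in [self.direction, *self.directions.values()]:
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ValueError(f"wave direction must be a unit vector, got {d}")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency_hz

    def direction_for(self, label: int) -> np.ndarray:
        return np.asarray(self.directions.get(label, self.direction), dtype=float)


def wavenumber(sigma: float, eps_r: float, omega: float) -> complex:
    """Principal complex wavenumber k with k^2 = mu0*eps*omega^2 - i*mu0*sigma*omega."""
    k2 = mu_0 * eps_r * epsilon_0 * omega**2 - 1j * mu_0 * sigma * omega
    return complex(np.sqrt(complex(k2)))


def _centered_coords_mm(shape, spacing):
    """Per-axis physical coordinates (mm) centred on the volume centre."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def make_label_volume(
    geometry: PhantomGeometry, compartments: Sequence[CompartmentSpec]
) -> LabelVolume:
    """Paint the phantom layout into an integer label volume (0 = background)."""
    if len(compartments) != geometry.n_compartments:
        raise ValueError(
            f"layout defines {geometry.n_compartments} compartments but "
            f"{len(compartments)} specs were given"
        )
    labels_list = [c.label for c in compartments]
    if len(set(labels_list)) != len(labels_list):
        raise ValueError(f"compartment labels must be unique, got {labels_list}")

    shape, spacing = geometry.shape, geometry.spacing
    coords = _centered_coords_mm(shape, spacing)
    out = np.zeros(shape, dtype=np.int32)

    if geometry.layout == "concentric_cylinders":
        ax = geometry.axis
        cross = [i for i in range(3) if i != ax]
        radius = geometry.outer_diameter_mm / 2.0
        if geometry.fit == "strict":
            for i in cross:
                if 2 * radius > shape[i] * spacing[i] + 1e-9:
                    raise ValueError(
                        f"outer diameter {2 * radius} mm exceeds grid extent "
                        f"{shape[i] * spacing[i]} mm along dimension {i}"
                    )
            if geometry.height_mm is not None and (
                geometry.height_mm > shape[ax] * spacing[ax] + 1e-9
            ):
                raise ValueError(
                    f"cylinder height {geometry.height_mm} mm exceeds grid extent "
                    f"{shape[ax] * spacing[ax]} mm along dimension {ax}"
                )
        grids = np.meshgrid(*coords, indexing="ij")
        r = np.sqrt(grids[cross[0]] ** 2 + grids[cross[1]] ** 2)
        edges = np.cumsum(geometry.ring_widths_mm)
        # section index: searchsorted over the outer edges; beyond the last -> 0
        idx = np.searchsorted(edges, r, side="left")
        inside = idx < len(edges)
        for i, comp in enumerate(compartments):
            out[inside & (idx == i)] = comp.label
        if geometry.height_mm is not None:
            out[np.abs(grids[ax]) > geometry.height_mm / 2.0] = 0
    else:  # blobs
        if len(geometry.blob_centers_mm) != len(geometry.blob_radii_mm):
            raise ValueError("blob centres and radii must have equal length")
        extent = geometry.extent_mm()
        grids = np.meshgrid(*coords, indexing="ij")
        for comp, centre, rad in zip(
            compartments, geometry.blob_centers_mm, geometry.blob_radii_mm
        ):
            if geometry.fit == "strict":
                for i in range(3):
                    if abs(centre[i]) + rad > extent[i] / 2.0 + 1e-9:
                        raise ValueError(
                            f"blob (centre {centre}, radius {rad} mm) exceeds the "
                            f"grid along dimension {i} (half-extent {extent[i] / 2} mm)"
                        )
            d2 = sum((grids[i] - centre[i]) ** 2 for i in range(3))
            out[d2 <= rad**2] = comp.label
    return LabelVolume(out, spacing)


def _compartment_map(compartments: Sequence[CompartmentSpec]) -> dict:
    return {c.label: c for c in compartments}


def _require_specs(labels: LabelVolume, comp_map: dict) -> np.ndarray:
    present = labels.labels()
    missing = [int(l) for l in present if int(l) not in comp_map]
    if missing:
        raise ValueError(f"no CompartmentSpec for labels present in volume: {missing}")
    return present


def make_field(
    labels: LabelVolume,
    compartments: Sequence[CompartmentSpec],
    model: FieldModel = FieldModel(),
    check_phase: bool = True,
) -> ComplexVolume:
    """Exact piecewise plane-wave Helmholtz field B(r) for the programmed media.

    Within compartment c, B = exp(-i k_c d_c.(r - r0)) with r0 the volume
    centre, so Laplacian(B)/B = -k_c^2 exactly in the continuum.  With
    ``check_phase`` the predicted phase span of the squared signal B^2 is
    verified to stay inside (-pi, pi]; a violation raises with the offending
    label (reduce the cylinder height or compartment extent to fix).
    """
    comp_map = _compartment_map(compartments)
    present = _require_specs(labels, comp_map)
    coords = _centered_coords_mm(labels.shape, labels.spacing)
    grids = np.meshgrid(*coords, indexing="ij")
    out = np.zeros(labels.shape, dtype=np.complex128)
    omega = model.omega
    for lab in present:
        comp = comp_map[int(lab)]
        k = wavenumber(comp.sigma, comp.eps_r, omega)
        d = model.direction_for(int(lab))
        mask = labels.data == lab
        # projection along the wave direction, in metres
        proj = (
            grids[0][mask] * d[0] + grids[1][mask] * d[1] + grids[2][mask] * d[2]
        ) * 1e-3
        if check_phase and proj.size:
            max_phase = 2.0 * abs(k.real) * float(np.max(np.abs(proj)))
            if max_phase >= math.pi:
                raise ValueError(
                    f"squared-signal phase of compartment {int(lab)} spans "
                    f"+/-{max_phase:.2f} rad and would wrap beyond (-pi, pi]; "
                    "shorten the compartment along its wave direction"
                )
        out[mask] = np.exp(-1j * k * proj)
    return ComplexVolume(out, labels.spacing)


def apply_contrast(
    field_vol: ComplexVolume,
    labels: LabelVolume,
    compartments: Sequence[CompartmentSpec],
) -> ComplexVolume:
    """Signal S = I0(label) * B^2, the UTE-like transceive-product signal."""
    check_aligned(field_vol, labels, "field and labels")
    comp_map = _compartment_map(compartments)
    present = _require_specs(labels, comp_map)
    out = np.zeros(labels.shape, dtype=np.complex128)
    for lab in present:
        mask = labels.data == lab
        out[mask] = comp_map[int(lab)].i0 * field_vol.data[mask] ** 2
    return ComplexVolume(out, labels.spacing)


def add_noise(
    signal: ComplexVolume,
    snr_db: float,
    seed,
    foreground: Optional[np.ndarray] = None,
) -> ComplexVolume:
    """Add complex Gaussian noise at a prescribed SNR.

    SNR convention: ``snr_db = 20*log10(mean |S| over foreground / per-channel
    noise SD)``; independent zero-mean Gaussian noise of that SD is added to
    the real and imaginary channels everywhere.  ``snr_db = inf`` returns a
    copy.  ``foreground`` defaults to voxels with nonzero signal.
    """
    if np.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    if np.isposinf(snr_db):
        return signal.copy()
    if foreground is None:
        foreground = np.abs(signal.data) > 0
    if not np.any(foreground):
        raise ValueError("cannot calibrate noise: empty foreground")
    sd = float(np.mean(np.abs(signal.data[foreground]))) / 10.0 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, signal.shape) + 1j * rng.normal(0.0, sd, signal.shape)
    return ComplexVolume(signal.data + noise, signal.spacing)


def make_dixon(
    labels: LabelVolume,
    compartments: Sequence[CompartmentSpec],
    noise_sd: float = 0.0,
    seed=None,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Water/fat magnitude pair: fat = fvf*i0, water = (1-fvf)*i0 per voxel.

    Optional Gaussian magnitude noise (SD in the same arbitrary units as i0)
    is added independently to both channels and clipped at zero.
    """
    comp_map = _compartment_map(compartments)
    present = _require_specs(labels, comp_map)
    water = np.zeros(labels.shape, dtype=np.float64)
    fat = np.zeros(labels.shape, dtype=np.float64)
    for lab in present:
        comp = comp_map[int(lab)]
        mask = labels.data == lab
        fat[mask] = comp.fvf * comp.i0
        water[mask] = (1.0 - comp.fvf) * comp.i0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        water = np.clip(water + rng.normal(0.0, noise_sd, water.shape), 0.0, None)
        fat = np.clip(fat + rng.normal(0.0, noise_sd, fat.shape), 0.0, None)
    return ScalarVolume(water, labels.spacing), ScalarVolume(fat, labels.spacing)


# ---------------------------------------------------------------------------
# Synthetic cohorts

COHORT_PREDICTORS = ("age", "sex", "bmi", "fvf")


@dataclass(frozen=True)
class OrganEffect:
    """Programmed linear conductivity model for one organ.

    median sigma = sigma0 + age_slope*age + sex_offset*[male] + bmi_slope*BMI
                   + fvf_slope*FVF + N(0, residual_sd).
    """

    sigma0: float  # S/m intercept
    age_slope: float = 0.0  # S/m per year
    sex_offset: float = 0.0  # S/m, male minus female
    bmi_slope: float = 0.0  # S/m per kg/m^2
    fvf_slope: float = 0.0  # S/m per unit fat fraction
    residual_sd: float = 0.0  # S/m
    fvf_range: tuple[float, float] = (0.02, 0.30)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual SD must be >= 0")
        lo, hi = self.fvf_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("fvf_range must be within [0, 1] with lo <= hi")


def _default_organs() -> dict:
    # Emulates the cohort structure this pipeline is meant to analyse: white
    # matter conductivity rising with age, liver falling with fat fraction,
    # heart higher in males; magnitudes in line with in vivo spreads.
    return {
        "wm": OrganEffect(sigma0=0.59, age_slope=0.0017, residual_sd=0.03),
        "liver": OrganEffect(sigma0=0.90, fvf_slope=-1.0, residual_sd=0.06),
        "heart": OrganEffect(sigma0=0.62, sex_offset=0.05, residual_sd=0.05),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic subject table."""

    n_subjects: int = 17
    organs: dict = field(default_factory=_default_organs)
    age_range: tuple[float, float] = (25.0, 73.0)
    bmi_range: tuple[float, float] = (19.6, 32.6)
    p_male: float = 10.0 / 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < len(COHORT_PREDICTORS) + 2:
            raise ValueError(
                f"n_subjects={self.n_subjects} cannot identify "
                f"{len(COHORT_PREDICTORS)} predictors (need >= "
                f"{len(COHORT_PREDICTORS) + 2})"
            )
        if not self.organs:
            raise ValueError("at least one organ effect is required")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a subject table with programmed per-organ linear structure.

    Columns: ``subject, age, sex, bmi, <organ>_sigma, <organ>_fvf`` with sex
    coded M/F.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, n)
    male = rng.random(n) < spec.p_male
    bmi = rng.uniform(*spec.bmi_range, n)
    table = {
        "subject": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": age,
        "sex": np.where(male, "M", "F"),
        "bmi": bmi,
    }
    for organ, eff in spec.organs.items():
        fvf = rng.uniform(*eff.fvf_range, n)
        sigma = (
            eff.sigma0
            + eff.age_slope * age
            + eff.sex_offset * male.astype(float)
            + eff.bmi_slope * bmi
            + eff.fvf_slope * fvf
        )
        if eff.residual_sd > 0:
            sigma = sigma + rng.normal(0.0, eff.residual_sd, n)
        table[f"{organ}_sigma"] = sigma
        table[f"{organ}_fvf"] = fvf
    return pd.DataFrame(table)
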