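"""Readers and writers: NIfTI volumes, sidecar JSON, cohort CSV, YAML config.

Complex volumes are stored as a pair of NIfTI files (real/imaginary or
magnitude/phase) plus a small JSON sidecar naming the convention, since NIfTI
itself has no universally supported complex dtype.  Voxel spacing lives in
the NIfTI header (mm); the affine is diagonal in that spacing.  Phase inputs
are radians in (-pi, pi].
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volumes import ComplexVolume, LabelVolume, ScalarVolume

__all__ = [
    "read_scalar_volume",
    "write_scalar_volume",
    "read_label_volume",
    "write_label_volume",
    "read_complex_volume",
    "write_complex_volume",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_config",
]

_PHASE_TOL = 1e-6


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def _check_pair(a_path, a, a_sp, b_path, b, b_sp) -> None:
    if a.shape != b.shape or not np.allclose(a_sp, b_sp, rtol=1e-5):
        raise ValueError(
            f"volume headers disagree: {a_path} (shape {a.shape}, spacing {a_sp}) "
            f"vs {b_path} (shape {b.shape}, spacing {b_sp})"
        )


def read_scalar_volume(path) -> ScalarVolume:
    data, spacing = _load(path)
    return ScalarVolume(data.astype(np.float64), spacing)


def write_scalar_volume(vol: ScalarVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.spacing)), path)
    return path


def read_label_volume(path) -> LabelVolume:
    data, spacing = _load(path)
    if not np.all(data == np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    return LabelVolume(data.astype(np.int32), spacing)


def write_label_volume(vol: LabelVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.int32), _affine(vol.spacing)), path)
    return path


def read_complex_volume(
    real=None,
    imaginary=None,
    magnitude=None,
    phase=None,
) -> ComplexVolume:
    """Assemble a complex volume from a real/imaginary or magnitude/phase pair."""
    if (real is None) != (imaginary is None) or (magnitude is None) != (phase is None):
        raise ValueError("provide both files of one convention")
    if (real is None) == (magnitude is None):
        raise ValueError("provide either a real/imaginary or a magnitude/phase pair")
    if real is not None:
        re, sp_a = _load(real)
        im, sp_b = _load(imaginary)
        _check_pair(real, re, sp_a, imaginary, im, sp_b)
        return ComplexVolume(re.astype(np.float64) + 1j * im.astype(np.float64), sp_a)
    mag, sp_a = _load(magnitude)
    ph, sp_b = _load(phase)
    _check_pair(magnitude, mag, sp_a, phase, ph, sp_b)
    if ph.min() < -math.pi - _PHASE_TOL or ph.max() > math.pi + _PHASE_TOL:
        raise ValueError(
            f"{phase}: phase must be radians in (-pi, pi], got range "
            f"[{ph.min():.3f}, {ph.max():.3f}]"
        )
    return ComplexVolume(mag.astype(np.float64) * np.exp(1j * ph.astype(np.float64)), sp_a)


def write_complex_volume(
    vol: ComplexVolume, prefix, convention: str = "real_imaginary"
) -> dict:
    """Write a complex volume as a NIfTI pair plus a JSON sidecar.

    Returns the mapping of component name to file path (also recorded in
    ``<prefix>.json``).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol.spacing)
    if convention == "real_imaginary":
        parts = {
            "real": vol.data.real.astype(np.float64),
            "imaginary": vol.data.imag.astype(np.float64),
        }
    elif convention == "magnitude_phase":
        parts = {
            "magnitude": np.abs(vol.data).astype(np.float64),
            "phase": np.angle(vol.data).astype(np.float64),
        }
    else:
        raise ValueError(f"unknown convention {convention!r}")
    files = {}
    for name, arr in parts.items():
        path = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, aff), path)
        files[name] = str(path)
    sidecar = {
        "convention": convention,
        "spacing_mm": list(vol.spacing),
        "files": files,
        "phase_units": "radians in (-pi, pi]",
    }
    with open(prefix.parent / f"{prefix.name}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return files


def read_complex_volume_sidecar(sidecar_path) -> ComplexVolume:
    """Read a complex volume via its JSON sidecar."""
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    files = meta["files"]
    if meta["convention"] == "real_imaginary":
        return read_complex_volume(real=files["real"], imaginary=files["imaginary"])
    return read_complex_volume(magnitude=files["magnitude"], phase=files["phase"])


_COHORT_REQUIRED = ("subject", "age", "sex", "bmi")


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in _COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    if table["subject"].duplicated().any():
        dupes = table.loc[table["subject"].duplicated(), "subject"].tolist()
        raise ValueError(f"{path}: duplicated subject identifiers {dupes}")
    bad = set(table["sex"].unique()) - {"M", "F"}
    if bad:
        raise ValueError(f"{path}: sex must be coded M/F, got {sorted(bad)}")
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    """Load a YAML pipeline/phantom configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg
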