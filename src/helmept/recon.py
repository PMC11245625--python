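"""Conductivity reconstruction via the square-root Helmholtz formulation.

The admittivity kappa = sigma + i*omega*eps of a voxel is estimated from the
complex transceive-product signal S as

    kappa = (1 / (i*mu0*omega)) * Laplacian(sqrt(S)) / sqrt(S),

valid where electrical properties and the non-RF contrast I0 are piecewise
constant.  sqrt(S) takes the magnitude square root and half the (constant-
shift unwrapped) phase.  The Laplacian is obtained from a second-order 3-D
Savitzky-Golay fit over a *bi-adaptive* neighbourhood: all voxels of the
centre's segmentation class inside a large N^3 selection window, reduced to
the n nearest in physical Euclidean distance.  Restricting the fit to one
class confines boundary bias, while the fixed neighbour count keeps the
least-squares problem strongly overdetermined against noise.

Two execution paths are provided: a per-voxel reference implementation
(`biadaptive_neighborhood` + `sg_laplacian_ratio`, used directly in tests)
and a vectorised path used by :func:`reconstruct` that exploits the fact that
window offsets, their distances and the quadratic design matrix are shared by
every centre voxel.  Both produce identical neighbourhoods and fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.constants import mu_0

from .volumes import ComplexVolume, LabelVolume, check_aligned

__all__ = [
    "KernelConfig",
    "SqrtSignal",
    "AdmittivityMap",
    "unwrap_phase_constant",
    "complex_sqrt_signal",
    "biadaptive_neighborhood",
    "sg_laplacian_ratio",
    "reconstruct",
]

_N_BASIS = 10  # 1, x, y, z, x^2, y^2, z^2, xy, xz, yz


@dataclass(frozen=True)
class KernelConfig:
    """Bi-adaptive Savitzky-Golay kernel settings.

    ``window``: odd selection-window size N per axis (15 suits ~1.2 mm
    brain-like grids, 23 the coarser torso-like grids).  ``n_neighbors``:
    voxels kept for the fit; defaults to ceil(0.3 * N^3), which keeps the
    10-term quadratic fit roughly 100x overdetermined.  ``min_voxels``:
    below this many same-class voxels the centre is marked invalid.
    """

    window: int = 15
    n_neighbors: Optional[int] = None
    min_voxels: int = 20
    order: int = 2  # fixed; only the full 3-D quadratic basis is supported

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("selection window must be odd and >= 5")
        if self.order != 2:
            raise ValueError("only second-order (quadratic) fits are supported")
        n = self.resolved_neighbors
        if n < 2 * _N_BASIS:
            raise ValueError(
                f"n_neighbors={n} must be at least twice the {_N_BASIS} quadratic "
                "basis terms"
            )
        if self.min_voxels > n:
            raise ValueError("min_voxels must not exceed n_neighbors")

    @property
    def resolved_neighbors(self) -> int:
        if self.n_neighbors is not None:
            return int(self.n_neighbors)
        return math.ceil(0.3 * self.window**3)


@dataclass
class SqrtSignal:
    """sqrt of a complex signal: magnitude root, half unwrapped phase."""

    data: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AdmittivityMap:
    """Complex admittivity map kappa = sigma + i*omega*eps (S/m real part).

    Invalid voxels (background, starved or degenerate neighbourhoods) carry
    NaN.  Negative conductivities are preserved, never clipped: they are a
    real failure mode of Helmholtz EPT in low-SNR regions and should stay
    visible.
    """

    kappa: np.ndarray
    sigma: np.ndarray
    valid: np.ndarray
    frequency_hz: float
    spacing: tuple[float, float, float]

    @property
    def shape(self):
        return self.kappa.shape


# ---------------------------------------------------------------------------
# Phase handling


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phase))


def unwrap_phase_constant(
    phase: np.ndarray,
    mask: Optional[np.ndarray] = None,
    bins: int = 256,
    min_gap: float = math.pi / 4,
) -> np.ndarray:
    """Constant-shift phase unwrapping.

    If the foreground phase histogram occupies both tails at the +/-pi branch
    cut while leaving an interior gap of at least ``min_gap`` empty, the
    branch below the gap centre is shifted up by 2*pi so the distribution
    becomes continuous; otherwise the input is returned unchanged.  Phase
    differences are never altered mod 2*pi.  Suitable when the true phase
    span is below 2*pi, as for the transceive-product signals targeted here.
    """
    phase = np.asarray(phase, dtype=np.float64)
    w = _wrap(phase)
    sample = w[mask] if mask is not None else w.ravel()
    if sample.size == 0:
        return phase.copy()
    hist, _ = np.histogram(sample, bins=bins, range=(-math.pi, math.pi))
    empty = hist == 0
    if not empty.any():
        return phase.copy()
    # longest circular run of empty bins; scanning the doubled array covers
    # runs that straddle the +/-pi edge
    empty2 = np.concatenate([empty, empty])
    best_len, best_start, run_len = 0, -1, 0
    for i, e in enumerate(empty2):
        run_len = run_len + 1 if e else 0
        if run_len > best_len and i - run_len + 1 < bins:
            best_len, best_start = min(run_len, bins), i - run_len + 1
    if best_len * (2 * math.pi / bins) < min_gap:
        return phase.copy()
    if best_start + best_len > bins:
        # the widest gap contains the +/-pi branch point: the occupied arc
        # does not cross it, so the phase is already continuous
        return phase.copy()
    bin_width = 2 * math.pi / bins
    cut = -math.pi + (best_start + best_len / 2.0) * bin_width
    return phase + 2 * math.pi * (w < cut)


def complex_sqrt_signal(
    signal: ComplexVolume, mask: Optional[np.ndarray] = None
) -> SqrtSignal:
    """sqrt(S): magnitude = sqrt|S|, phase = unwrapped arg(S) / 2."""
    if mask is None:
        mask = np.abs(signal.data) > 0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no voxels to take the signal root over")
    valid = mask & (np.abs(signal.data) > 0) & np.isfinite(signal.data)
    phase = unwrap_phase_constant(np.angle(signal.data), valid)
    out = np.zeros(signal.shape, dtype=np.complex128)
    out[valid] = np.sqrt(np.abs(signal.data[valid])) * np.exp(
        0.5j * phase[valid]
    )
    return SqrtSignal(out, valid, signal.spacing)


# ---------------------------------------------------------------------------
# Neighbourhood selection and Savitzky-Golay fitting (reference path)


def _sorted_offsets(window: int, spacing) -> tuple[np.ndarray, np.ndarray]:
    """All window offsets sorted by (physical distance, dx, dy, dz).

    The lexicographic tie-break over the offset triple equals a tie-break
    over absolute voxel indices for any fixed centre, so reference and
    vectorised paths agree bit-for-bit on which neighbours are kept.
    """
    r = window // 2
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    dist = np.sqrt(((offs * np.asarray(spacing)) ** 2).sum(axis=1))
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], dist))
    return offs[order], dist[order]


def biadaptive_neighborhood(
    labels: LabelVolume,
    center: tuple[int, int, int],
    cfg: KernelConfig,
    valid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Voxel indices of the bi-adaptive neighbourhood of ``center``.

    Step 1 collects every voxel of the centre's segmentation class inside the
    N^3 window (clipped at the volume border); step 2 keeps the n nearest in
    physical Euclidean distance, ties at the cutoff broken by lexicographic
    voxel index.  Returns an (m, 3) index array including the centre, or an
    empty (0, 3) array when fewer than ``min_voxels`` candidates exist.
    """
    cx, cy, cz = (int(c) for c in center)
    lab = labels.data[cx, cy, cz]
    if lab == 0:
        raise ValueError(f"centre voxel {center} has background label 0")
    offs, _ = _sorted_offsets(cfg.window, labels.spacing)
    pts = offs + np.array([cx, cy, cz])
    shape = labels.shape
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
        & (pts[:, 2] >= 0)
        & (pts[:, 2] < shape[2])
    )
    pts = pts[inside]
    same = labels.data[pts[:, 0], pts[:, 1], pts[:, 2]] == lab
    if valid is not None:
        same &= valid[pts[:, 0], pts[:, 1], pts[:, 2]]
    pts = pts[same]
    if pts.shape[0] < max(cfg.min_voxels, _N_BASIS):
        return np.empty((0, 3), dtype=int)
    return pts[: cfg.resolved_neighbors]


def _design(coords_m: np.ndarray) -> np.ndarray:
    """Quadratic design matrix over centred physical coordinates (metres)."""
    x, y, z = coords_m[:, 0], coords_m[:, 1], coords_m[:, 2]
    return np.stack(
        [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z],
        axis=1,
    )


def sg_laplacian_ratio(
    sqrt_signal: SqrtSignal,
    voxels: np.ndarray,
    center: tuple[int, int, int],
    spacing=None,
) -> complex:
    """Savitzky-Golay estimate of Laplacian(sqrt S)/sqrt S at ``center``.

    Fits the full 3-D quadratic to complex sqrt(S) over ``voxels`` in
    physical coordinates (metres) centred on the target voxel and returns
    2*(c_xx + c_yy + c_zz) divided by the fitted constant term, in 1/m^2.
    The fitted constant, not the raw centre voxel, is used as denominator so
    numerator and denominator share the same smoothing.  Returns NaN for
    starved or rank-deficient (e.g. coplanar) neighbourhoods.
    """
    if spacing is None:
        spacing = sqrt_signal.spacing
    voxels = np.asarray(voxels, dtype=int)
    if voxels.shape[0] < _N_BASIS:
        return complex(np.nan, np.nan)
    # scaled coordinates keep the normal equations well conditioned
    scale_m = float(np.mean(spacing)) * 1e-3
    rel = (voxels - np.asarray(center)) * (np.asarray(spacing) * 1e-3) / scale_m
    A = _design(rel)
    y = sqrt_signal.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    M = A.T @ A
    eig = np.linalg.eigvalsh(M)
    if eig[0] <= 1e-10 * eig[-1]:
        return complex(np.nan, np.nan)
    c = np.linalg.solve(M, A.T @ y)
    if c[0] == 0:
        return complex(np.nan, np.nan)
    lap = 2.0 * (c[4] + c[5] + c[6]) / scale_m**2
    return complex(lap / c[0])


# ---------------------------------------------------------------------------
# Full-volume reconstruction (vectorised path)


def _reconstruct_arrays(
    sqrtS: SqrtSignal,
    labels: LabelVolume,
    cfg: KernelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ratio Laplacian(sqrt S)/sqrt S for every foreground voxel.

    Window offsets are shared by all centres, so class membership, neighbour
    ranking and the design rows reduce to per-offset gathers followed by two
    large matrix products (normal matrices and right-hand sides), solved as a
    batch of 10x10 systems.
    """
    window = cfg.window
    n_keep = cfg.resolved_neighbors
    min_keep = max(cfg.min_voxels, _N_BASIS)
    r = window // 2
    spacing = np.asarray(labels.spacing)
    offs, _ = _sorted_offsets(window, spacing)
    n_off = offs.shape[0]

    scale_m = float(np.mean(spacing)) * 1e-3
    A = _design(offs * (spacing * 1e-3) / scale_m)  # (n_off, 10), shared
    outer = np.einsum("ji,jk->jik", A, A).reshape(n_off, _N_BASIS * _N_BASIS)

    lab_pad = np.pad(labels.data, r, mode="constant", constant_values=0)
    y_pad = np.pad(sqrtS.data, r, mode="constant", constant_values=0)
    ok_pad = np.pad(sqrtS.valid, r, mode="constant", constant_values=False)

    fg = labels.data > 0
    xs, ys, zs = np.nonzero(fg)
    n_vox = xs.size
    ratio = np.full(n_vox, np.nan + 1j * np.nan, dtype=np.complex128)
    valid = np.zeros(n_vox, dtype=bool)
    if n_vox == 0:
        return ratio, valid

    center_lab = labels.data[xs, ys, zs]
    chunk = max(256, int(6e6 / n_off))
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        v = hi - lo
        cx, cy, cz = xs[lo:hi] + r, ys[lo:hi] + r, zs[lo:hi] + r
        clab = center_lab[lo:hi]
        same = np.empty((v, n_off), dtype=bool)
        yv = np.empty((v, n_off), dtype=np.complex128)
        for j in range(n_off):
            dx, dy, dz = offs[j]
            px, py, pz = cx + dx, cy + dy, cz + dz
            same[:, j] = (lab_pad[px, py, pz] == clab) & ok_pad[px, py, pz]
            yv[:, j] = y_pad[px, py, pz]
        counts = np.cumsum(same, axis=1)
        kept = same & (counts <= n_keep)
        n_kept = np.minimum(counts[:, -1], n_keep)
        cand = n_kept >= min_keep

        kf = kept.astype(np.float64)
        M = (kf @ outer).reshape(v, _N_BASIS, _N_BASIS)
        b = (kept * yv) @ A.astype(np.complex128)

        if cand.any():
            Mc = M[cand]
            eig = np.linalg.eigvalsh(Mc)
            nondegen = eig[:, 0] > 1e-10 * eig[:, -1]
            idx = np.nonzero(cand)[0][nondegen]
            if idx.size:
                c = np.linalg.solve(
                    M[idx].astype(np.complex128), b[idx][..., None]
                )[..., 0]
                c0 = c[:, 0]
                good = c0 != 0
                lap = 2.0 * (c[:, 4] + c[:, 5] + c[:, 6]) / scale_m**2
                res = np.full(idx.size, np.nan + 1j * np.nan, np.complex128)
                res[good] = lap[good] / c0[good]
                ratio[lo + idx] = res
                valid[lo + idx] = good
    return ratio, valid


def reconstruct(
    signal: ComplexVolume,
    labels: LabelVolume,
    cfg: KernelConfig = KernelConfig(),
    frequency_hz: float = 123e6,
    method: str = "fast",
) -> AdmittivityMap:
    """Reconstruct the admittivity map kappa = sigma + i*omega*eps from S.

    Per foreground voxel, kappa = (Laplacian(sqrt S)/sqrt S) / (i*mu0*omega);
    sigma is its real part.  Background and voxels with starved or degenerate
    neighbourhoods are invalid (NaN).  ``method="reference"`` runs the
    per-voxel path (slow; small volumes only).
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    check_aligned(signal, labels, "signal and labels")
    sqrtS = complex_sqrt_signal(signal, labels.foreground())
    omega = 2.0 * math.pi * frequency_hz
    shape = labels.shape

    if method == "fast":
        ratio_flat, valid_flat = _reconstruct_arrays(sqrtS, labels, cfg)
        xs, ys, zs = np.nonzero(labels.data > 0)
        ratio = np.full(shape, np.nan + 1j * np.nan, dtype=np.complex128)
        valid = np.zeros(shape, dtype=bool)
        ratio[xs, ys, zs] = ratio_flat
        valid[xs, ys, zs] = valid_flat
    elif method == "reference":
        ratio = np.full(shape, np.nan + 1j * np.nan, dtype=np.complex128)
        valid = np.zeros(shape, dtype=bool)
        for center in zip(*np.nonzero(labels.data > 0)):
            hood = biadaptive_neighborhood(labels, center, cfg, valid=sqrtS.valid)
            if hood.shape[0] == 0:
                continue
            val = sg_laplacian_ratio(sqrtS, hood, center)
            if not np.isnan(val.real):
                ratio[center] = val
                valid[center] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    kappa = ratio / (1j * mu_0 * omega)
    sigma = np.where(valid, kappa.real, np.nan)
    kappa = np.where(valid, kappa, np.nan + 1j * np.nan)
    return AdmittivityMap(kappa, sigma, valid, frequency_hz, labels.spacing)
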