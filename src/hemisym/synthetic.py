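"""Synthetic inputs with known ground truth.

Generates mirror-symmetric templates, polynomially distorted templates,
4D series in which homotopic voxel pairs share a common signal yielding a
target correlation, group datasets with localised planted effects, and
callosal-volume tables.

The homotopic mixing rule builds each pair from standardised AR(1) series as
``sqrt(rho) * shared + sqrt(1 - rho) * unique``, which gives population
correlation exactly ``rho`` for any temporal autocorrelation.  Optional
spatial Gaussian smoothing is applied per timepoint *after* pair
construction, so the per-pair target holds pre-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.signal import lfilter

from .grids import SeriesVolume, VolumeGrid, flip_lr, require_even_x
from .warp import WarpParameters, apply_polynomial_warp  # re-export  # noqa: F401

__all__ = [
    "FWHM_TO_SIGMA",
    "SimulationConfig",
    "GroupSpec",
    "CallosalRecord",
    "CALLOSAL_COLUMNS",
    "generate_symmetric_template",
    "apply_polynomial_warp",
    "generate_homotopic_series",
    "generate_group_dataset",
    "generate_callosal_table",
]

#: FWHM = sigma * sqrt(8 ln 2)
FWHM_TO_SIGMA = sqrt(8.0 * log(2.0))

CALLOSAL_COLUMNS = [
    "subject_id",
    "group",
    "cc_posterior",
    "cc_midposterior",
    "cc_central",
    "cc_midanterior",
    "cc_anterior",
    "brain_volume",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic 4D series.

    ``rho_map`` may be a scalar in [0, 1) or a full-grid array that must be
    mirror-symmetric (one rho per homotopic pair).
    """

    grid_shape: tuple[int, int, int]
    n_timepoints: int
    voxel_size_mm: float = 1.0
    tr_s: float = 2.0
    ar_coefficient: float = 0.0
    rho_map: float | np.ndarray = 0.0
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0
    dtype: type = np.float64

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        require_even_x(self.grid_shape)
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be positive")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be non-negative")
        rho = np.asarray(self.rho_map)
        if np.any(rho < 0) or np.any(rho >= 1):
            raise ValueError("target homotopic correlation must lie in [0, 1)")
        if rho.ndim == 3:
            if rho.shape != self.grid_shape:
                raise ValueError("rho_map shape must match grid_shape")
            if not np.array_equal(rho, flip_lr(rho)):
                raise ValueError("rho_map must be mirror-symmetric (one rho per pair)")
        elif rho.ndim != 0:
            raise ValueError("rho_map must be a scalar or a full-grid array")

    def resolved_rho(self) -> np.ndarray:
        """Full-grid mirror-symmetric rho array."""
        rho = np.asarray(self.rho_map, dtype=float)
        if rho.ndim == 0:
            return np.full(self.grid_shape, float(rho))
        return rho


def generate_symmetric_template(config: SimulationConfig) -> VolumeGrid:
    """Smooth random field, exactly mirror-symmetric about the midsagittal plane.

    Symmetry is enforced by averaging the field with its own x-flip, which is
    bitwise exact; deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    field_ = rng.standard_normal(config.grid_shape)
    if config.smoothing_fwhm_mm > 0:
        sigma = config.smoothing_fwhm_mm / FWHM_TO_SIGMA / config.voxel_size_mm
    else:
        sigma = 1.5  # default smoothness in voxels
    field_ = ndimage.gaussian_filter(field_, sigma=sigma)
    field_ = (field_ - field_.mean()) / field_.std()
    sym = 0.5 * (field_ + flip_lr(field_))
    return VolumeGrid(data=sym, voxel_size=config.voxel_size_mm)


def _ar1(rng: np.random.Generator, shape: tuple, nt: int, phi: float, dtype) -> np.ndarray:
    """Stationary unit-variance AR(1) innovations, shape ``shape + (nt,)``."""
    eps = rng.standard_normal(shape + (nt,)).astype(dtype, copy=False)
    if phi == 0.0:
        return eps
    innov_sd = sqrt(1.0 - phi * phi)
    x0 = rng.standard_normal(shape).astype(dtype, copy=False)
    zi = (phi * x0)[..., None]
    out, _ = lfilter([1.0], [1.0, -phi], innov_sd * eps, axis=-1, zi=zi)
    return out.astype(dtype, copy=False)


def generate_homotopic_series(config: SimulationConfig) -> SeriesVolume:
    """4D series whose homotopic pairs have population correlation ``rho_map``.

    Each pair mixes a shared and a unique standardised AR(1) series; optional
    3D Gaussian smoothing is applied per timepoint afterwards.
    """
    nx, ny, nz = config.grid_shape
    half = nx // 2
    nt = config.n_timepoints
    phi = config.ar_coefficient
    rho = config.resolved_rho()[:half]  # one rho per pair, indexed by left voxel
    rng = np.random.default_rng(config.seed)

    shared = _ar1(rng, (half, ny, nz), nt, phi, config.dtype)
    unique_l = _ar1(rng, (half, ny, nz), nt, phi, config.dtype)
    unique_r = _ar1(rng, (half, ny, nz), nt, phi, config.dtype)

    a = np.sqrt(rho)[..., None].astype(config.dtype, copy=False)
    b = np.sqrt(1.0 - rho)[..., None].astype(config.dtype, copy=False)
    data = np.empty((nx, ny, nz, nt), dtype=config.dtype)
    data[:half] = a * shared + b * unique_l
    right = a * shared + b * unique_r
    data[half:] = right[::-1]  # voxel i pairs with nx - 1 - i

    if config.smoothing_fwhm_mm > 0:
        sigma = config.smoothing_fwhm_mm / FWHM_TO_SIGMA / config.voxel_size_mm
        data = ndimage.gaussian_filter(data, sigma=(sigma, sigma, sigma, 0.0))
    return SeriesVolume(data=data, voxel_size=config.voxel_size_mm, tr=config.tr_s)


@dataclass
class GroupSpec:
    """Two-group design: a localised homotopic-correlation increase in group A."""

    n_subjects_per_group: int
    baseline_rho: float
    effect_region: np.ndarray  # boolean mask over the grid, mirror-symmetric
    effect_delta_rho: float
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if not 0 <= self.baseline_rho < 1:
            raise ValueError("baseline_rho must lie in [0, 1)")
        total = self.baseline_rho + self.effect_delta_rho
        if not 0 <= total < 1:
            raise ValueError("baseline_rho + effect_delta_rho must lie in [0, 1)")


def generate_group_dataset(
    group_spec: GroupSpec, config: SimulationConfig
) -> tuple[list[SeriesVolume], list[SeriesVolume]]:
    """Two collections of series: group A carries the planted effect.

    Per-subject seeds are derived deterministically as master seed + subject
    index (group A first).
    """
    region = np.asarray(group_spec.effect_region)
    if region.dtype != bool:
        # allow index tuples/arrays; convert to a mask, validating bounds
        mask = np.zeros(config.grid_shape, dtype=bool)
        try:
            mask[tuple(np.asarray(region).T) if region.ndim == 2 else tuple(region)] = True
        except IndexError as exc:
            raise ValueError("effect_region indices fall outside the grid") from exc
        region = mask
    if region.shape != tuple(config.grid_shape):
        raise ValueError("effect_region mask shape must match grid_shape")
    if not np.array_equal(region, flip_lr(region)):
        raise ValueError("effect_region must be mirror-symmetric")

    rho_a = np.full(config.grid_shape, group_spec.baseline_rho)
    rho_a[region] += group_spec.effect_delta_rho
    rho_b = np.full(config.grid_shape, group_spec.baseline_rho)

    n = group_spec.n_subjects_per_group
    group_a = [
        generate_homotopic_series(
            replace(config, rho_map=rho_a, seed=group_spec.seed + i)
        )
        for i in range(n)
    ]
    group_b = [
        generate_homotopic_series(
            replace(config, rho_map=rho_b, seed=group_spec.seed + n + i)
        )
        for i in range(n)
    ]
    return group_a, group_b


@dataclass
class CallosalRecord:
    """Per-subject callosal segment volumes and total brain volume (mm^3)."""

    subject_id: str
    group: str
    cc_posterior: float
    cc_midposterior: float
    cc_central: float
    cc_midanterior: float
    cc_anterior: float
    brain_volume: float

    def __post_init__(self):
        vols = [
            self.cc_posterior,
            self.cc_midposterior,
            self.cc_central,
            self.cc_midanterior,
            self.cc_anterior,
            self.brain_volume,
        ]
        if any(v <= 0 for v in vols):
            raise ValueError("all volumes must be strictly positive")


def _shared_factor_weight(target_r: float, seg_sds: np.ndarray) -> float:
    """Loading weight w such that corr(total CC, brain) == target_r.

    Every segment and the brain volume load on one latent factor with weight
    sqrt(w); corr(total, brain) = w*S / sqrt(w*S**2 + (1-w)*Q) with
    S = sum(sd), Q = sum(sd**2).
    """
    s = float(np.sum(seg_sds))
    q = float(np.sum(seg_sds**2))

    def f(w):
        return w * s / sqrt(w * s * s + (1 - w) * q) - target_r

    if target_r <= 0:
        return 0.0
    return brentq(f, 1e-12, 1.0 - 1e-12)


def generate_callosal_table(
    n_per_group: int,
    group_means: Mapping[str, Sequence[float]],
    group_sds: Mapping[str, Sequence[float]],
    seed: int = 0,
    brain_mean: float = 1.2e6,
    brain_sd: float = 1.2e5,
    cc_brain_r: float = 0.46,
) -> pd.DataFrame:
    """Callosal-volume table with a shared factor tying CC and brain volume.

    Segment volumes follow normal distributions truncated at 0 (redrawn);
    deterministic and byte-identical for a fixed seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    for g, means in group_means.items():
        if len(means) != 5 or len(group_sds[g]) != 5:
            raise ValueError("five segment means and sds are required per group")
        if any(m <= 0 for m in means) or any(s <= 0 for s in group_sds[g]):
            raise ValueError("means and sds must be positive")

    rng = np.random.default_rng(seed)
    pooled_sds = np.mean([np.asarray(group_sds[g], float) for g in group_means], axis=0)
    w = _shared_factor_weight(cc_brain_r, pooled_sds)
    rows = []
    for g in group_means:
        means = np.asarray(group_means[g], float)
        sds = np.asarray(group_sds[g], float)
        for i in range(n_per_group):
            while True:
                factor = rng.standard_normal()
                segs = means + sds * (
                    sqrt(w) * factor + sqrt(1 - w) * rng.standard_normal(5)
                )
                brain = brain_mean + brain_sd * (
                    sqrt(w) * factor + sqrt(1 - w) * rng.standard_normal()
                )
                if np.all(segs > 0) and brain > 0:
                    break
            rows.append(
                {
                    "subject_id": f"{g}_{i:03d}",
                    "group": g,
                    "cc_posterior": segs[0],
                    "cc_midposterior": segs[1],
                    "cc_central": segs[2],
                    "cc_midanterior": segs[3],
                    "cc_anterior": segs[4],
                    "brain_volume": brain,
                }
            )
    return pd.DataFrame(rows, columns=CALLOSAL_COLUMNS)
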