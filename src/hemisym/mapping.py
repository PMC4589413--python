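"""Per-subject symmetry maps: homotopic correlation, Fisher z, corrected z.

The symmetry index of a voxel is the Pearson correlation between its time
series and that of its homotopic partner (the brain correlated with its own
x-flipped image).  Fisher's r-to-z transform (arctanh) stabilises the
variance, and significance is corrected for temporal autocorrelation through
an effective-degrees-of-freedom estimate

    1/df  =  1/N + (2/N) * sum_j ((N - j)/N) * acf_x(j) * acf_y(j)

evaluated over randomly sampled homotopic voxel pairs and averaged.  The
corrected statistic is ``z = z_f * sqrt(df - 3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .grids import SeriesVolume, flip_lr, require_even_x
from .synthetic import FWHM_TO_SIGMA

__all__ = [
    "SymmetryMap",
    "EffectiveDf",
    "concatenate_runs",
    "detrend_series",
    "temporal_filter",
    "nuisance_regress",
    "homotopic_correlation_map",
    "fisher_z",
    "effective_df_pair",
    "estimate_effective_df",
    "corrected_z",
    "compute_symmetry_map",
]

_DF_FLOOR = 3.0 + 1e-9  # df is clipped to (3, N]


@dataclass
class SymmetryMap:
    """Per-voxel homotopic correlation r, Fisher z, and df-corrected z."""

    r: np.ndarray
    mask: np.ndarray
    z_f: np.ndarray | None = None
    z: np.ndarray | None = None
    df: float | None = None
    effective_df: "EffectiveDf | None" = None
    voxel_size: float = 1.0


@dataclass
class EffectiveDf:
    """Study/subject-level effective degrees of freedom estimate."""

    df: float
    per_pair: np.ndarray
    n_pairs: int
    seed: int
    n_timepoints: int
    used_all_pairs: bool = False


def concatenate_runs(runs: list[SeriesVolume], n_discard_per_run: int = 4) -> SeriesVolume:
    """Time-concatenate runs after dropping the first volumes of each run.

    All runs must share grid, voxel size, and repetition interval, and each
    must be longer than ``n_discard_per_run``.
    """
    if not runs:
        raise ValueError("at least one run is required")
    first = runs[0]
    for run in runs:
        if run.spatial_shape != first.spatial_shape:
            raise ValueError("runs must share the same spatial grid")
        if not np.isclose(run.voxel_size, first.voxel_size):
            raise ValueError("runs must share the same voxel size")
        if not np.isclose(run.tr, first.tr):
            raise ValueError("runs must share the same repetition interval")
        if run.n_timepoints <= n_discard_per_run:
            raise ValueError(
                f"run of length {run.n_timepoints} is not longer than the "
                f"discard count {n_discard_per_run}"
            )
    data = np.concatenate([run.data[..., n_discard_per_run:] for run in runs], axis=-1)
    return SeriesVolume(data, first.voxel_size, first.tr)


def detrend_series(series: SeriesVolume, knot_spacing: int) -> SeriesVolume:
    """Subtract a per-voxel cubic-spline trend with knots at a fixed spacing."""
    from scipy.interpolate import BSpline

    nt = series.n_timepoints
    if nt < 4:
        raise ValueError("detrending requires at least 4 timepoints")
    if knot_spacing >= nt:
        raise ValueError("knot spacing must be smaller than the series length")
    x = np.arange(nt, dtype=float)
    interior = np.arange(knot_spacing, nt - 1, knot_spacing, dtype=float)
    knots = np.concatenate([np.zeros(4), interior, np.full(4, nt - 1.0)])
    basis = BSpline.design_matrix(x, knots, 3).toarray()
    y = series.data.reshape(-1, nt).T.astype(float)  # (nt, nvox)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    out = resid.T.reshape(series.data.shape)
    return SeriesVolume(out, series.voxel_size, series.tr)


def temporal_filter(
    series: SeriesVolume,
    kernel_width_s: float = 4.0,
    repetition_s: float | None = None,
    interpret: str = "fwhm",
) -> SeriesVolume:
    """Per-voxel temporal Gaussian smoothing.

    ``kernel_width_s`` is interpreted as the FWHM of the Gaussian by default
    (``interpret='sigma'`` for the literal standard deviation).  Edges are
    handled by kernel renormalisation, so constant series pass unchanged.
    """
    if kernel_width_s <= 0:
        raise ValueError("kernel width must be positive")
    tr = series.tr if repetition_s is None else repetition_s
    if interpret == "fwhm":
        sigma = kernel_width_s / FWHM_TO_SIGMA / tr
    elif interpret == "sigma":
        sigma = kernel_width_s / tr
    else:
        raise ValueError("interpret must be 'fwhm' or 'sigma'")
    radius = max(1, int(np.ceil(4.0 * sigma)))
    offsets = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    data = np.asarray(series.data, dtype=float)
    num = ndimage.convolve1d(data, kernel, axis=-1, mode="constant", cval=0.0)
    den = ndimage.convolve1d(
        np.ones(series.n_timepoints), kernel, mode="constant", cval=0.0
    )
    return SeriesVolume(num / den, series.voxel_size, series.tr)


def nuisance_regress(series: SeriesVolume, regressors: np.ndarray | None) -> SeriesVolume:
    """Per-voxel least-squares residual after projecting out regressors + intercept."""
    nt = series.n_timepoints
    if regressors is None:
        x = np.ones((nt, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != nt:
            raise ValueError("regressor rows must equal the number of timepoints")
        x = np.column_stack([np.ones(nt), regressors])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("regressor matrix is rank deficient")
    y = series.data.reshape(-1, nt).T.astype(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return SeriesVolume(resid.T.reshape(series.data.shape), series.voxel_size, series.tr)


def homotopic_correlation_map(series: SeriesVolume) -> SymmetryMap:
    """Pearson correlation of every voxel series with its mirror partner.

    Zero-variance voxels (and their partners) are masked out.  The resulting
    r map equals its own x-flip bit for bit.
    """
    require_even_x(series.spatial_shape)
    if series.n_timepoints < 3:
        raise ValueError("at least 3 timepoints are required")
    d = np.asarray(series.data, dtype=float)
    centred = d - d.mean(axis=-1, keepdims=True)
    sd = np.sqrt(np.mean(centred**2, axis=-1))
    valid = sd > 0
    if not valid.any():
        warnings.warn("all-constant volume: empty symmetry mask")
    zs = np.zeros_like(centred)
    np.divide(centred, sd[..., None], out=zs, where=valid[..., None])
    r = np.mean(zs * flip_lr(zs), axis=-1)
    mask = valid & flip_lr(valid)
    r = np.where(mask, np.clip(r, -1.0, 1.0), np.nan)
    return SymmetryMap(r=r, mask=mask, voxel_size=series.voxel_size)


def fisher_z(r, method: str = "arctanh"):
    """Fisher r-to-z transform of a correlation coefficient.

    ``|r| >= 1`` yields NaN (flagged for masking) rather than infinity.  The
    ``arctan`` variant is selectable for literal replication but is not the
    standard variance-stabilising transform.
    """
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, np.nan)
    ok = np.abs(r) < 1
    if method == "arctanh":
        out[ok] = np.arctanh(r[ok])
    elif method == "arctan":
        out[ok] = np.arctan(r[ok])
    else:
        raise ValueError("method must be 'arctanh' or 'arctan'")
    if out.ndim == 0:
        return float(out)
    return out


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    """Biased (divisor-N) sample autocorrelations of each row, lags 0..N-1."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    nfft = sp_fft.next_fast_len(2 * n)
    f = sp_fft.rfft(xc, nfft, axis=-1)
    acov = sp_fft.irfft(f * np.conj(f), nfft, axis=-1)[..., :n]
    var0 = acov[..., :1]
    if np.any(var0 <= 0):
        raise ValueError("constant series: autocorrelation is undefined")
    return acov / var0


def _df_from_acfs(rx: np.ndarray, ry: np.ndarray, n: int, max_lag: int) -> np.ndarray:
    j = np.arange(1, max_lag + 1)
    weights = (n - j) / n
    s = np.sum(weights * rx[..., 1 : max_lag + 1] * ry[..., 1 : max_lag + 1], axis=-1)
    inv = 1.0 / n + (2.0 / n) * s
    df = np.where(inv <= 1.0 / n, float(n), 1.0 / np.where(inv > 0, inv, 1.0))
    return np.clip(df, _DF_FLOOR, float(n))


def effective_df_pair(
    x_series: np.ndarray, y_series: np.ndarray, max_lag: int | None = None
) -> float:
    """Effective degrees of freedom of one pair of autocorrelated series.

    Uses biased sample autocorrelations up to ``max_lag`` (default N - 1);
    the result is clipped to (3, N].
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    n = x.size
    if n < 10:
        raise ValueError("at least 10 timepoints are required")
    if max_lag is None:
        max_lag = n - 1
    rx = _autocorrelations(x[None, :])
    ry = _autocorrelations(y[None, :])
    return float(_df_from_acfs(rx, ry, n, max_lag)[0])


def estimate_effective_df(
    series: SeriesVolume,
    n_pairs: int = 1000,
    seed: int = 0,
    max_lag: int | None = None,
    mask: np.ndarray | None = None,
) -> EffectiveDf:
    """Average pairwise effective df over randomly sampled homotopic pairs.

    Pairs are drawn uniformly without replacement from voxels that are valid
    (non-constant, and inside ``mask`` if given) on both sides of the mirror
    plane.  If fewer than ``n_pairs`` pairs exist, all are used and the
    result is flagged.  Deterministic for a given seed.
    """
    require_even_x(series.spatial_shape)
    d = np.asarray(series.data, dtype=float)
    nx = d.shape[0]
    half = nx // 2
    n = series.n_timepoints
    sd = d.std(axis=-1)
    valid = sd > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    pair_ok = (valid & flip_lr(valid))[:half]
    idx = np.argwhere(pair_ok)
    if idx.shape[0] == 0:
        raise ValueError("empty mask: no valid homotopic pairs")
    rng = np.random.default_rng(seed)
    used_all = idx.shape[0] <= n_pairs
    if used_all:
        chosen = idx
    else:
        chosen = idx[rng.choice(idx.shape[0], size=n_pairs, replace=False)]
    xi, yi, zi = chosen[:, 0], chosen[:, 1], chosen[:, 2]
    x = d[xi, yi, zi, :]
    y = d[nx - 1 - xi, yi, zi, :]
    if max_lag is None:
        max_lag = n - 1
    rx = _autocorrelations(x)
    ry = _autocorrelations(y)
    per_pair = _df_from_acfs(rx, ry, n, max_lag)
    return EffectiveDf(
        df=float(per_pair.mean()),
        per_pair=per_pair,
        n_pairs=int(chosen.shape[0]),
        seed=seed,
        n_timepoints=n,
        used_all_pairs=used_all,
    )


def corrected_z(z_f, df: float):
    """Divide Fisher z by its standard error: ``z = z_f * sqrt(df - 3)``."""
    if df <= 3:
        raise ValueError("df must exceed 3")
    return np.asarray(z_f, dtype=float) * np.sqrt(df - 3.0)


def compute_symmetry_map(
    series: SeriesVolume,
    n_pairs: int = 1000,
    seed: int = 0,
    method: str = "arctanh",
    df: float | None = None,
) -> SymmetryMap:
    """Full per-subject symmetry map: r, Fisher z, and df-corrected z.

    A study-level ``df`` may be supplied; otherwise it is estimated from this
    series over ``n_pairs`` homotopic pairs.
    """
    smap = homotopic_correlation_map(series)
    eff = None
    if df is None:
        eff = estimate_effective_df(series, n_pairs=n_pairs, seed=seed, mask=smap.mask)
        df = eff.df
    z_f = fisher_z(smap.r, method=method)
    z = np.where(np.isfinite(z_f), z_f * np.sqrt(df - 3.0), np.nan)
    smap.z_f = z_f
    smap.z = z
    smap.df = float(df)
    smap.effective_df = eff
    return smap
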