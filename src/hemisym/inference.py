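"""Group contrasts with Monte-Carlo cluster-extent correction.

Directional two-sample t-maps of corrected symmetry maps are thresholded at a
voxel-forming z level; the cluster-size null distribution is calibrated by
(a) building surrogate symmetry maps from phase-scrambled flipped series,
(b) estimating the spatial autocorrelation function (ACF) kernel of the
resulting null t-maps, and (c) generating smoothness-matched Gaussian noise
images from that kernel and recording their supra-threshold cluster sizes.
Surviving clusters can additionally be masked by the significance of the
favoured group's mean corrected z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage, stats

from .grids import SeriesVolume, VolumeGrid, axis_coords, flip_lr
from .mapping import (
    estimate_effective_df,
    fisher_z,
    homotopic_correlation_map,
)

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterReport",
    "ClusterNull",
    "EffectSizeResult",
    "GroupParams",
    "GroupAnalysisResult",
    "two_sample_tmap",
    "t_to_z",
    "phase_scramble",
    "scramble_flipped_series",
    "null_symmetry_corrected_z",
    "null_symmetry_tmap",
    "estimate_acf_kernel",
    "simulate_cluster_null",
    "extract_clusters",
    "apply_cluster_correction",
    "mask_by_group_mean",
    "cohens_d_map",
    "label_clusters",
    "run_group_analysis",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """A per-voxel statistic image (t or z) with its contrast metadata."""

    values: np.ndarray
    df: float
    tail: str = "greater"
    threshold: float | None = None
    kind: str = "t"
    voxel_size: float = 1.0


@dataclass
class Cluster:
    """One supra-threshold connected component."""

    k: int
    peak_value: float
    peak_index: tuple[int, int, int]
    peak_coords_mm: tuple[float, float, float]
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    values: np.ndarray
    regions: list = field(default_factory=list)  # (label_name, k, peak, coords)


@dataclass
class ClusterReport:
    """Extracted clusters with size, peak statistic, and peak coordinates."""

    clusters: list[Cluster]
    threshold: float
    connectivity: int
    voxel_size: float
    grid_shape: tuple[int, int, int]

    @property
    def sizes(self) -> list[int]:
        return [c.k for c in self.clusters]

    def to_rows(self) -> list[dict]:
        rows = []
        for i, c in enumerate(self.clusters, start=1):
            if c.regions:
                for name, k, peak, coords in c.regions:
                    rows.append(
                        {
                            "cluster": i,
                            "region": name,
                            "k": k,
                            "max_stat": peak,
                            "x": coords[0],
                            "y": coords[1],
                            "z": coords[2],
                        }
                    )
            else:
                rows.append(
                    {
                        "cluster": i,
                        "region": "",
                        "k": c.k,
                        "max_stat": c.peak_value,
                        "x": c.peak_coords_mm[0],
                        "y": c.peak_coords_mm[1],
                        "z": c.peak_coords_mm[2],
                    }
                )
        return rows


@dataclass
class ClusterNull:
    """Cluster-size null distribution from simulated smoothness-matched images."""

    sizes: np.ndarray  # all supra-threshold cluster sizes pooled across images
    max_sizes: np.ndarray  # per-image maximum cluster size (0 if none)
    n_images: int
    threshold: float
    cluster_p: float
    connectivity: int
    k_crit: int
    tail: str = "image"
    no_clusters: bool = False


@dataclass
class EffectSizeResult:
    """Cohen's d map plus the physical volume exceeding the threshold per tail."""

    d: np.ndarray
    volume_pos_cm3: float
    volume_neg_cm3: float
    threshold: float = 0.8


def two_sample_tmap(
    maps_a: Sequence[np.ndarray], maps_b: Sequence[np.ndarray], tail: str = "greater"
) -> StatMap:
    """Pooled-variance two-sample t statistic per voxel, direction A > B.

    Voxels with zero pooled variance are masked (NaN).
    """
    a = np.stack([np.asarray(m, float) for m in maps_a])
    b = np.stack([np.asarray(m, float) for m in maps_b])
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("at least 2 subjects per group are required")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the same grid")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    df = na + nb - 2
    pooled = (ss_a + ss_b) / df
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    t = np.where(denom > 0, t, np.nan)
    return StatMap(values=t, df=float(df), tail=tail, kind="t")


def t_to_z(tmap: StatMap) -> StatMap:
    """Convert a t map to its standard-normal z equivalent (tail-preserving)."""
    with np.errstate(invalid="ignore"):
        z = stats.norm.isf(stats.t.sf(tmap.values, tmap.df))
    return StatMap(
        values=z,
        df=tmap.df,
        tail=tmap.tail,
        threshold=tmap.threshold,
        kind="z",
        voxel_size=tmap.voxel_size,
    )


def _random_phase_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus Hermitian-symmetric phase field in rfftn layout.

    Built as the phase of the rFFT of a white real field, which enforces the
    Hermitian symmetry required for a real inverse transform; the DC bin is
    pinned to 1 so the mean is preserved, and self-conjugate (Nyquist) bins
    come out real (+-1) automatically.
    """
    noise = rng.standard_normal(shape)
    f = sp_fft.rfftn(noise)
    mag = np.abs(f)
    mag[mag == 0] = 1.0
    unit = f / mag
    unit[(0,) * unit.ndim] = 1.0
    return unit


def phase_scramble(volume, seed: int | None = None, rng: np.random.Generator | None = None):
    """Randomise Fourier phases of a real 3D volume, preserving amplitudes.

    Fourier magnitudes are preserved exactly, Hermitian symmetry is enforced
    so the output is real, and the DC bin keeps its phase (mean preserved).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    is_grid = isinstance(volume, VolumeGrid)
    data = np.asarray(volume.data if is_grid else volume, dtype=float)
    if data.ndim != 3:
        raise ValueError("phase_scramble expects a 3D volume")
    unit = _random_phase_field(data.shape, rng)
    out = sp_fft.irfftn(sp_fft.rfftn(data) * unit, s=data.shape)
    if is_grid:
        return VolumeGrid(out, volume.voxel_size)
    return out


def scramble_flipped_series(
    series: SeriesVolume,
    rng: np.random.Generator,
    per_timepoint: bool = False,
) -> SeriesVolume:
    """Flip a series across the mirror plane and phase-scramble it spatially.

    By default a single phase draw is applied to every timepoint, destroying
    homotopic spatial alignment while preserving the temporal autocorrelation
    that the effective-df correction accounts for.  ``per_timepoint=True``
    draws independent phases per volume instead.
    """
    data = np.asarray(flip_lr(series.data), dtype=float)
    shape3 = data.shape[:3]
    f = sp_fft.rfftn(data, axes=(0, 1, 2))
    if per_timepoint:
        out = np.empty_like(data)
        for t in range(data.shape[-1]):
            unit = _random_phase_field(shape3, rng)
            out[..., t] = sp_fft.irfftn(f[..., t] * unit, s=shape3)
    else:
        unit = _random_phase_field(shape3, rng)
        out = sp_fft.irfftn(f * unit[..., None], s=shape3, axes=(0, 1, 2))
    return SeriesVolume(out, series.voxel_size, series.tr)


def null_symmetry_corrected_z(
    series: SeriesVolume,
    df: float,
    rng: np.random.Generator,
    method: str = "arctanh",
    per_timepoint: bool = False,
) -> np.ndarray:
    """Corrected-z symmetry map against the subject's phase-scrambled flip."""
    scrambled = scramble_flipped_series(series, rng, per_timepoint=per_timepoint)
    d = np.asarray(series.data, dtype=float)
    s = np.asarray(scrambled.data, dtype=float)
    dc = d - d.mean(axis=-1, keepdims=True)
    sc = s - s.mean(axis=-1, keepdims=True)
    denom = np.sqrt(np.mean(dc**2, axis=-1) * np.mean(sc**2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.mean(dc * sc, axis=-1) / denom
    r = np.where(denom > 0, np.clip(r, -1.0, 1.0), np.nan)
    # real symmetry maps carry one value per homotopic pair, duplicated on
    # both sides of the mirror plane; give the surrogate the same structure
    half = r.shape[0] // 2
    r[half:] = r[:half][::-1]
    z_f = fisher_z(r, method=method)
    return np.where(np.isfinite(z_f), z_f * np.sqrt(df - 3.0), np.nan)


def null_symmetry_tmap(
    series_a: Sequence[SeriesVolume],
    series_b: Sequence[SeriesVolume],
    df: float,
    seed: int | np.random.Generator = 0,
    method: str = "arctanh",
    per_timepoint: bool = False,
) -> StatMap:
    """Between-group t-map of phase-scrambled null symmetry maps (z scale)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_a = [
        null_symmetry_corrected_z(s, df, rng, method, per_timepoint) for s in series_a
    ]
    null_b = [
        null_symmetry_corrected_z(s, df, rng, method, per_timepoint) for s in series_b
    ]
    return t_to_z(two_sample_tmap(null_a, null_b))


def estimate_acf_kernel(
    stat_maps: Sequence[np.ndarray], floor: float = 0.02
) -> np.ndarray:
    """Average spatial autocorrelation function of statistic images.

    Each map's ACF is computed via its power spectrum, normalised to 1 at
    zero lag, averaged over maps, and truncated to the compact support where
    ``|ACF| >= floor``.  Returns an odd-shaped kernel centred on zero lag.
    """
    if len(stat_maps) < 1:
        raise ValueError("at least one statistic map is required")
    acc = None
    for m in stat_maps:
        m = np.asarray(m, dtype=float)
        m = np.nan_to_num(m - np.nanmean(m))
        if not np.any(m):
            raise ValueError("degenerate constant statistic map")
        f = sp_fft.fftn(m)
        acf = np.real(sp_fft.ifftn(f * np.conj(f)))
        acf /= acf.flat[0]
        acc = acf if acc is None else acc + acf
    acf = sp_fft.fftshift(acc / len(stat_maps))
    center = np.array([s // 2 for s in acf.shape])
    # contiguous central support per axis: scan outward until |ACF| first
    # drops below the floor (robust to estimation noise at distant lags)
    half = np.zeros(3, dtype=int)
    for a in range(3):
        profile = np.abs(
            acf[tuple(center[b] if b != a else slice(None) for b in range(3))]
        )
        h = 0
        while (
            center[a] + h + 1 < acf.shape[a]
            and center[a] - h - 1 >= 0
            and profile[center[a] + h + 1] >= floor
            and profile[center[a] - h - 1] >= floor
        ):
            h += 1
        half[a] = h
    slices = tuple(slice(c - h, c + h + 1) for c, h in zip(center, half))
    return acf[slices]


def _spectral_filter(kernel: np.ndarray, grid_shape: tuple) -> np.ndarray:
    """rFFT-layout filter whose output noise has the kernel as its ACF.

    The kernel (an ACF) is embedded at the origin; the filter is the square
    root of its non-negative spectrum, so filtered white noise has matching
    spatial spectral properties.
    """
    if any(k > g for k, g in zip(kernel.shape, grid_shape)):
        # centre-crop an oversized kernel to (odd) supports that fit the grid
        slices = []
        for k, g in zip(kernel.shape, grid_shape):
            h = min(k // 2, (g - 1) // 2)
            c = k // 2
            slices.append(slice(c - h, c + h + 1))
        kernel = kernel[tuple(slices)]
    emb = np.zeros(grid_shape)
    emb[tuple(slice(0, k) for k in kernel.shape)] = kernel
    emb = np.roll(emb, [-(k // 2) for k in kernel.shape], axis=(0, 1, 2))
    power = sp_fft.rfftn(emb).real
    return np.sqrt(np.clip(power, 0.0, None))


def _cluster_sizes(binary: np.ndarray, connectivity: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.empty(0, dtype=int)
    return np.bincount(labels.ravel())[1:]


def _critical_size(
    sizes: np.ndarray, max_sizes: np.ndarray, n_images: int, p: float, tail: str
) -> tuple[int, bool]:
    if sizes.size == 0:
        return 1, True
    if tail == "image":
        ref = max_sizes
        denom = n_images
    elif tail == "cluster":
        ref = sizes
        denom = sizes.size
    else:
        raise ValueError("tail must be 'image' or 'cluster'")
    for k in range(1, int(ref.max()) + 2):
        if np.count_nonzero(ref >= k) / denom < p:
            return k, False
    return int(ref.max()) + 1, False


def simulate_cluster_null(
    kernel: np.ndarray,
    grid_shape: tuple,
    threshold: float,
    n_images: int,
    seed: int = 0,
    cluster_p: float = 0.001,
    connectivity: int = 18,
    tail: str = "image",
    batch: int = 64,
    mirror_symmetric: bool = False,
) -> ClusterNull:
    """Monte-Carlo null distribution of supra-threshold cluster sizes.

    Each image is white noise convolved with the smoothness-matched filter
    derived from ``kernel``, standardised to zero mean / unit variance, and
    thresholded at the voxel-forming level.  ``k_crit`` is the smallest size
    whose tail probability falls below ``cluster_p``; with ``tail='image'``
    the tail is taken over per-image maximum cluster sizes (family-wise
    calibration), with ``tail='cluster'`` over the pooled size distribution.

    ``mirror_symmetric=True`` duplicates the left half of each image onto the
    right, matching the pairwise duplication structure of symmetry maps
    (clusters straddling the mirror plane then merge, as they do in real
    maps).
    """
    if n_images < 100:
        raise ValueError("n_images must be at least 100")
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 3:
        raise ValueError("kernel must be 3D")
    filt = _spectral_filter(kernel, tuple(grid_shape))
    rng = np.random.default_rng(seed)
    all_sizes: list[np.ndarray] = []
    max_sizes = np.zeros(n_images, dtype=int)
    done = 0
    while done < n_images:
        nb = min(batch, n_images - done)
        noise = rng.standard_normal((nb,) + tuple(grid_shape))
        f = sp_fft.rfftn(noise, axes=(1, 2, 3))
        imgs = sp_fft.irfftn(f * filt[None], s=tuple(grid_shape), axes=(1, 2, 3))
        for i in range(nb):
            img = imgs[i]
            img = (img - img.mean()) / img.std()
            if mirror_symmetric:
                half = img.shape[0] // 2
                img[half:] = img[:half][::-1]
            sizes = _cluster_sizes(img > threshold, connectivity)
            if sizes.size:
                all_sizes.append(sizes)
                max_sizes[done + i] = sizes.max()
        done += nb
    sizes = np.concatenate(all_sizes) if all_sizes else np.empty(0, dtype=int)
    k_crit, empty = _critical_size(sizes, max_sizes, n_images, cluster_p, tail)
    return ClusterNull(
        sizes=sizes,
        max_sizes=max_sizes,
        n_images=n_images,
        threshold=float(threshold),
        cluster_p=cluster_p,
        connectivity=connectivity,
        k_crit=int(k_crit),
        tail=tail,
        no_clusters=empty,
    )


def extract_clusters(
    stat_map,
    threshold: float,
    connectivity: int = 18,
    voxel_size: float | None = None,
) -> ClusterReport:
    """Maximal connected components of supra-threshold voxels.

    ``connectivity`` is 6 (faces), 18 (faces + edges, the default) or 26.
    Clusters are returned in decreasing size order with peak value and peak
    location in centred physical coordinates (mirror plane at x = 0).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if isinstance(stat_map, StatMap):
        values = np.asarray(stat_map.values, dtype=float)
        voxel = stat_map.voxel_size if voxel_size is None else voxel_size
    else:
        values = np.asarray(stat_map, dtype=float)
        voxel = 1.0 if voxel_size is None else voxel_size
    with np.errstate(invalid="ignore"):
        binary = values > threshold
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    coords = [axis_coords(s, voxel) for s in values.shape]
    clusters = []
    for lab in range(1, n + 1):
        vox = np.nonzero(labels == lab)
        vals = values[vox]
        peak = int(np.argmax(vals))
        pidx = (int(vox[0][peak]), int(vox[1][peak]), int(vox[2][peak]))
        clusters.append(
            Cluster(
                k=int(vals.size),
                peak_value=float(vals[peak]),
                peak_index=pidx,
                peak_coords_mm=tuple(float(coords[a][pidx[a]]) for a in range(3)),
                voxels=vox,
                values=vals,
            )
        )
    clusters.sort(key=lambda c: c.k, reverse=True)
    return ClusterReport(
        clusters=clusters,
        threshold=float(threshold),
        connectivity=connectivity,
        voxel_size=voxel,
        grid_shape=tuple(values.shape),
    )


def apply_cluster_correction(report: ClusterReport, cluster_null: ClusterNull) -> ClusterReport:
    """Remove clusters smaller than the critical size of the null distribution."""
    if not np.isclose(report.threshold, cluster_null.threshold):
        raise ValueError(
            "voxel-forming threshold mismatch between report "
            f"({report.threshold}) and null ({cluster_null.threshold})"
        )
    kept = [c for c in report.clusters if c.k >= cluster_null.k_crit]
    return ClusterReport(
        clusters=kept,
        threshold=report.threshold,
        connectivity=report.connectivity,
        voxel_size=report.voxel_size,
        grid_shape=report.grid_shape,
    )


def _group_mean_pass_mask(group_maps: Sequence[np.ndarray], p_threshold: float) -> np.ndarray:
    g = np.stack([np.asarray(m, float) for m in group_maps])
    n = g.shape[0]
    if n < 2:
        raise ValueError("at least 2 subject maps are required")
    mean = g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, n - 1)
    p = np.where(sd > 0, p, np.where(mean > 0, 0.0, 1.0))
    return p < p_threshold


def mask_by_group_mean(report_or_map, group_maps: Sequence[np.ndarray], p_threshold: float = 0.0005):
    """Keep only voxels where the favoured group's mean corrected z is significant.

    A right-tailed one-sample t-test is applied per voxel at ``p_threshold``;
    failing voxels are removed from clusters and clusters are re-measured
    (empty clusters are dropped).  A :class:`StatMap` input is masked to NaN
    instead.
    """
    passed = _group_mean_pass_mask(group_maps, p_threshold)
    if isinstance(report_or_map, StatMap):
        values = np.where(passed, report_or_map.values, np.nan)
        return StatMap(
            values=values,
            df=report_or_map.df,
            tail=report_or_map.tail,
            threshold=report_or_map.threshold,
            kind=report_or_map.kind,
            voxel_size=report_or_map.voxel_size,
        )
    report: ClusterReport = report_or_map
    coords = [axis_coords(s, report.voxel_size) for s in report.grid_shape]
    kept = []
    for c in report.clusters:
        ok = passed[c.voxels]
        if not ok.any():
            continue
        vox = tuple(v[ok] for v in c.voxels)
        vals = c.values[ok]
        peak = int(np.argmax(vals))
        pidx = (int(vox[0][peak]), int(vox[1][peak]), int(vox[2][peak]))
        kept.append(
            Cluster(
                k=int(vals.size),
                peak_value=float(vals[peak]),
                peak_index=pidx,
                peak_coords_mm=tuple(float(coords[a][pidx[a]]) for a in range(3)),
                voxels=vox,
                values=vals,
            )
        )
    kept.sort(key=lambda c: c.k, reverse=True)
    return ClusterReport(
        clusters=kept,
        threshold=report.threshold,
        connectivity=report.connectivity,
        voxel_size=report.voxel_size,
        grid_shape=report.grid_shape,
    )


def cohens_d_map(
    maps_a: Sequence[np.ndarray],
    maps_b: Sequence[np.ndarray],
    voxel_size: float = 1.0,
    threshold: float = 0.8,
) -> EffectSizeResult:
    """Pooled-SD standardised mean difference per voxel and supra-threshold volume.

    Reports the physical volume (cm^3) where ``d > threshold`` (A over B) and
    where ``d < -threshold``; zero-pooled-SD voxels are masked.
    """
    a = np.stack([np.asarray(m, float) for m in maps_a])
    b = np.stack([np.asarray(m, float) for m in maps_b])
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("at least 2 subjects per group are required")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(ss / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean_a - mean_b) / pooled_sd
    d = np.where(pooled_sd > 0, d, np.nan)
    vox_cm3 = (voxel_size**3) / 1000.0
    with np.errstate(invalid="ignore"):
        vol_pos = float(np.count_nonzero(d > threshold) * vox_cm3)
        vol_neg = float(np.count_nonzero(d < -threshold) * vox_cm3)
    return EffectSizeResult(d=d, volume_pos_cm3=vol_pos, volume_neg_cm3=vol_neg, threshold=threshold)


def label_clusters(
    report: ClusterReport,
    label_volume: np.ndarray | None,
    label_names: dict | None = None,
    min_region_size: int = 5,
) -> ClusterReport:
    """Attach per-region voxel counts and peaks from a user-supplied label volume.

    Sub-regions smaller than ``min_region_size`` voxels are dropped; label 0
    is treated as unlabeled background.  Without a label volume the report is
    passed through unchanged.
    """
    if label_volume is None:
        return report
    labels = np.asarray(label_volume)
    if labels.shape != report.grid_shape:
        raise ValueError("label volume grid does not match the statistic grid")
    coords = [axis_coords(s, report.voxel_size) for s in report.grid_shape]
    out = []
    for c in report.clusters:
        lab_vals = labels[c.voxels]
        regions = []
        for lab in np.unique(lab_vals):
            if lab == 0:
                continue
            sel = lab_vals == lab
            k = int(np.count_nonzero(sel))
            if k < min_region_size:
                continue
            vals = c.values[sel]
            vox = tuple(v[sel] for v in c.voxels)
            peak = int(np.argmax(vals))
            pidx = (int(vox[0][peak]), int(vox[1][peak]), int(vox[2][peak]))
            name = label_names.get(int(lab), str(int(lab))) if label_names else str(int(lab))
            regions.append(
                (
                    name,
                    k,
                    float(vals[peak]),
                    tuple(float(coords[a][pidx[a]]) for a in range(3)),
                )
            )
        regions.sort(key=lambda r: r[1], reverse=True)
        out.append(
            Cluster(
                k=c.k,
                peak_value=c.peak_value,
                peak_index=c.peak_index,
                peak_coords_mm=c.peak_coords_mm,
                voxels=c.voxels,
                values=c.values,
                regions=regions,
            )
        )
    return ClusterReport(
        clusters=out,
        threshold=report.threshold,
        connectivity=report.connectivity,
        voxel_size=report.voxel_size,
        grid_shape=report.grid_shape,
    )


@dataclass
class GroupParams:
    """Knobs of the group stage; defaults follow the reference analysis."""

    alpha: float = 0.01
    voxel_z: float | None = None  # default: one-sided z quantile of alpha
    cluster_p: float = 0.001
    n_null: int = 10000
    acf_runs: int = 10
    mask_p: float = 0.0005
    connectivity: int = 18
    n_pairs: int = 1000
    null_tail: str = "image"
    fisher_method: str = "arctanh"
    acf_floor: float = 0.02
    apply_mask: bool = True

    def resolved_voxel_z(self) -> float:
        if self.voxel_z is not None:
            return float(self.voxel_z)
        return float(stats.norm.isf(self.alpha))


@dataclass
class GroupAnalysisResult:
    zmap: StatMap
    clusters: ClusterReport
    clusters_corrected: ClusterReport
    clusters_masked: ClusterReport
    null: ClusterNull
    acf_kernel: np.ndarray
    effect_size: EffectSizeResult
    study_df: float
    subject_z_a: list
    subject_z_b: list


def run_group_analysis(
    series_a: Sequence[SeriesVolume],
    series_b: Sequence[SeriesVolume],
    params: GroupParams | None = None,
    seed: int = 0,
) -> GroupAnalysisResult:
    """End-to-end group contrast from per-subject series.

    Estimates a study-level effective df (per-subject means averaged again),
    builds corrected-z symmetry maps, contrasts the groups, calibrates the
    cluster-size null from phase-scrambled surrogates, and applies cluster
    correction, group-mean masking, and effect-size mapping.
    """
    params = params or GroupParams()
    all_series = list(series_a) + list(series_b)
    if not all_series:
        raise ValueError("no input series")
    voxel = all_series[0].voxel_size

    dfs = [
        estimate_effective_df(s, n_pairs=params.n_pairs, seed=seed + i).df
        for i, s in enumerate(all_series)
    ]
    study_df = float(np.mean(dfs))

    def _zmap(series):
        smap = homotopic_correlation_map(series)
        z_f = fisher_z(smap.r, method=params.fisher_method)
        return np.where(np.isfinite(z_f), z_f * np.sqrt(study_df - 3.0), np.nan)

    z_a = [_zmap(s) for s in series_a]
    z_b = [_zmap(s) for s in series_b]

    zstat = t_to_z(two_sample_tmap(z_a, z_b))
    zstat.voxel_size = voxel
    voxel_z = params.resolved_voxel_z()
    zstat.threshold = voxel_z

    rng = np.random.default_rng(seed)
    null_maps = [
        null_symmetry_tmap(series_a, series_b, study_df, rng, params.fisher_method).values
        for _ in range(params.acf_runs)
    ]
    kernel = estimate_acf_kernel(null_maps, floor=params.acf_floor)
    null = simulate_cluster_null(
        kernel,
        all_series[0].spatial_shape,
        voxel_z,
        params.n_null,
        seed=seed + 10_000,
        cluster_p=params.cluster_p,
        connectivity=params.connectivity,
        tail=params.null_tail,
        mirror_symmetric=True,
    )
    report = extract_clusters(zstat, voxel_z, params.connectivity, voxel)
    corrected = apply_cluster_correction(report, null)
    if params.apply_mask:
        masked = mask_by_group_mean(corrected, z_a, params.mask_p)
    else:
        masked = corrected
    effect = cohens_d_map(z_a, z_b, voxel_size=voxel)
    return GroupAnalysisResult(
        zmap=zstat,
        clusters=report,
        clusters_corrected=corrected,
        clusters_masked=masked,
        null=null,
        acf_kernel=kernel,
        effect_size=effect,
        study_df=study_df,
        subject_z_a=z_a,
        subject_z_b=z_b,
    )
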