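import numpy as np
import pytest
from scipy import fft as sp_fft
from scipy import ndimage, stats

from hemisym.grids import SeriesVolume, flip_lr
from hemisym.inference import (
    Cluster,
    ClusterNull,
    ClusterReport,
    GroupParams,
    _cluster_sizes,
    _critical_size,
    apply_cluster_correction,
    cohens_d_map,
    estimate_acf_kernel,
    extract_clusters,
    label_clusters,
    mask_by_group_mean,
    null_symmetry_tmap,
    phase_scramble,
    run_group_analysis,
    simulate_cluster_null,
    t_to_z,
    two_sample_tmap,
)

from conftest import make_series


def brute_force_cluster_sizes(binary, connectivity):
    """Independent flood-fill oracle for connected components."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manh = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manh != 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(binary.shape, dtype=bool)
    sizes = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        count = 0
        while stack:
            p = stack.pop()
            count += 1
            for o in offsets:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if (
                    all(0 <= q[a] < binary.shape[a] for a in range(3))
                    and binary[q]
                    and not seen[q]
                ):
                    seen[q] = True
                    stack.append(q)
        sizes.append(count)
    return sorted(sizes, reverse=True)


class TestTwoSampleTmap:
    def test_identical_groups_zero(self, rng):
        maps = [rng.standard_normal((6, 6, 6)) for _ in range(4)]
        t = two_sample_tmap(maps, [m.copy() for m in maps])
        np.testing.assert_allclose(np.nan_to_num(t.values), 0.0, atol=1e-10)

    def test_hand_computed_toy(self):
        # long-hand pooled t at a single voxel: A=(3,4,5), B=(1,2,3)
        a_vals, b_vals = [3.0, 4.0, 5.0], [1.0, 2.0, 3.0]
        maps_a = [np.full((2, 2, 2), v) for v in a_vals]
        maps_b = [np.full((2, 2, 2), v) for v in b_vals]
        t = two_sample_tmap(maps_a, maps_b)
        ma, mb = np.mean(a_vals), np.mean(b_vals)
        sp2 = (np.var(a_vals, ddof=1) * 2 + np.var(b_vals, ddof=1) * 2) / 4
        expected = (ma - mb) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert t.df == 4

    def test_null_calibration(self, rng):
        maps_a = [rng.standard_normal((24, 24, 24)) for _ in range(12)]
        maps_b = [rng.standard_normal((24, 24, 24)) for _ in range(12)]
        z = t_to_z(two_sample_tmap(maps_a, maps_b))
        frac = np.mean(z.values > stats.norm.isf(0.01))
        se = np.sqrt(0.01 * 0.99 / z.values.size)
        assert abs(frac - 0.01) < 4 * se

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            two_sample_tmap([rng.standard_normal((2, 2, 2))], [rng.standard_normal((2, 2, 2))] * 2)


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self, rng):
        v = rng.standard_normal((12, 14, 10))
        out = phase_scramble(v, seed=1)
        a0 = np.abs(sp_fft.rfftn(v))
        a1 = np.abs(sp_fft.rfftn(out))
        np.testing.assert_allclose(a1, a0, rtol=1e-10, atol=1e-10)

    def test_mean_preserved_and_real(self, rng):
        v = rng.standard_normal((8, 8, 8)) + 3.0
        out = phase_scramble(v, seed=2)
        assert out.dtype.kind == "f"
        assert out.mean() == pytest.approx(v.mean(), abs=1e-10)

    def test_circular_acf_preserved(self, rng):
        # Wiener-Khinchin: the circular ACF depends only on the amplitude
        # spectrum, so it is preserved for every draw
        v = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), 1.5)

        def circ_acf(m):
            m = m - m.mean()
            f = sp_fft.fftn(m)
            a = np.real(sp_fft.ifftn(f * np.conj(f)))
            return a / a.flat[0]

        ref = circ_acf(v)
        for seed in range(5):
            np.testing.assert_allclose(circ_acf(phase_scramble(v, seed=seed)), ref, atol=1e-10)

    def test_deterministic(self, rng):
        v = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(phase_scramble(v, seed=3), phase_scramble(v, seed=3))


class TestAcfKernel:
    def test_white_noise_delta(self, rng):
        maps = [rng.standard_normal((32, 32, 32)) for _ in range(4)]
        k = estimate_acf_kernel(maps, floor=0.05)
        center = tuple(s // 2 for s in k.shape)
        assert k[center] == pytest.approx(1.0)
        off = k.sum() - k[center]
        assert abs(off) < 0.05

    def test_gaussian_smoothed_fwhm(self, rng):
        # ACF of a Gaussian-smoothed white field is Gaussian with
        # FWHM = sqrt(2) x image FWHM
        sigma = 2.0
        maps = [ndimage.gaussian_filter(rng.standard_normal((48, 48, 48)), sigma) for _ in range(10)]
        k = estimate_acf_kernel(maps, floor=0.02)
        c = np.array(k.shape) // 2
        prof = k[:, c[1], c[2]]
        x = np.arange(len(prof)) - c[0]
        half = np.interp(0.5, prof[c[0] :][::-1], x[c[0] :][::-1])
        expected = np.sqrt(2) * sigma * np.sqrt(8 * np.log(2))
        assert abs(2 * half - expected) / expected < 0.15

    def test_averaging_reduces_variance(self, rng):
        def kernel_stat(n_maps, seed):
            r = np.random.default_rng(seed)
            maps = [ndimage.gaussian_filter(r.standard_normal((24, 24, 24)), 1.5) for _ in range(n_maps)]
            k = estimate_acf_kernel(maps, floor=0.01)
            c = tuple(s // 2 for s in k.shape)
            return k[c[0] + 1, c[1], c[2]]

        singles = [kernel_stat(1, s) for s in range(8)]
        tens = [kernel_stat(10, 100 + s) for s in range(8)]
        assert np.var(tens) < np.var(singles)

    def test_degenerate_map_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_acf_kernel([np.ones((8, 8, 8))])


class TestSimulateClusterNull:
    def test_delta_kernel_matches_independent_voxel_oracle(self):
        # oracle: direct simulation of independent standard-normal images
        thr = stats.norm.isf(0.01)
        null = simulate_cluster_null(
            np.ones((1, 1, 1)), (24, 24, 24), thr, 1000, seed=1, cluster_p=0.001, tail="cluster"
        )
        rng = np.random.default_rng(99)
        sizes, maxs = [], np.zeros(1000, dtype=int)
        for i in range(1000):
            s = _cluster_sizes(rng.standard_normal((24, 24, 24)) > thr, 18)
            if s.size:
                sizes.append(s)
                maxs[i] = s.max()
        oracle_k, _ = _critical_size(np.concatenate(sizes), maxs, 1000, 0.001, "cluster")
        assert np.mean(null.sizes == 1) > 0.85  # overwhelmingly singletons
        assert abs(null.k_crit - oracle_k) <= 1

    def test_wider_kernel_larger_clusters(self, rng):
        thr = 2.326
        maps_narrow = [ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 1.0) for _ in range(4)]
        maps_wide = [ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 2.5) for _ in range(4)]
        k_narrow = estimate_acf_kernel(maps_narrow)
        k_wide = estimate_acf_kernel(maps_wide)
        null_n = simulate_cluster_null(k_narrow, (24, 24, 24), thr, 400, seed=2, cluster_p=0.01)
        null_w = simulate_cluster_null(k_wide, (24, 24, 24), thr, 400, seed=2, cluster_p=0.01)
        q = 0.99
        assert np.quantile(null_w.sizes, q) > np.quantile(null_n.sizes, q)

    def test_deterministic(self):
        a = simulate_cluster_null(np.ones((1, 1, 1)), (16, 16, 16), 2.3, 200, seed=5)
        b = simulate_cluster_null(np.ones((1, 1, 1)), (16, 16, 16), 2.3, 200, seed=5)
        np.testing.assert_array_equal(a.sizes, b.sizes)
        assert a.k_crit == b.k_crit

    def test_impossible_threshold_flagged(self):
        null = simulate_cluster_null(np.ones((1, 1, 1)), (8, 8, 8), 50.0, 100, seed=0)
        assert null.no_clusters and null.k_crit == 1


class TestExtractClusters:
    def test_edge_pair_connectivity(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = 1.0
        vol[0, 1, 1] = 1.0  # shares only an edge
        r18 = extract_clusters(vol, 0.5, connectivity=18)
        r6 = extract_clusters(vol, 0.5, connectivity=6)
        assert len(r18.clusters) == 1
        assert len(r6.clusters) == 2

    def test_two_blobs_hand_drawn(self):
        vol = np.zeros((5, 5, 5))
        vol[0, 0:2, 0:2] = 1.0  # 4 voxels
        vol[3:4, 2:5, 3:5] = 2.0  # 6 voxels
        vol[4, 2, 3] = 2.0  # face-attached -> 7 voxels
        report = extract_clusters(vol, 0.5, connectivity=6)
        assert report.sizes == brute_force_cluster_sizes(vol > 0.5, 6) == [7, 4]

    def test_above_global_max_empty(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        assert extract_clusters(vol, vol.max() + 1.0).clusters == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(20):
            binary = rng.random((8, 8, 8)) < 0.25
            report = extract_clusters(binary.astype(float), 0.5, connectivity=connectivity)
            assert report.sizes == brute_force_cluster_sizes(binary, connectivity)

    def test_peak_metadata(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 2, 3] = 5.0
        vol[1, 2, 2] = 3.0
        report = extract_clusters(vol, 1.0, voxel_size=2.0)
        c = report.clusters[0]
        assert c.k == 2 and c.peak_value == 5.0 and c.peak_index == (1, 2, 3)
        assert c.peak_coords_mm == (-1.0, 1.0, 3.0)


def _toy_report(sizes, threshold=2.32):
    clusters = []
    for s in sizes:
        vox = (np.arange(s), np.zeros(s, int), np.zeros(s, int))
        clusters.append(
            Cluster(
                k=s,
                peak_value=3.0,
                peak_index=(0, 0, 0),
                peak_coords_mm=(0.0, 0.0, 0.0),
                voxels=vox,
                values=np.full(s, 3.0),
            )
        )
    return ClusterReport(clusters, threshold, 18, 1.0, (max(sizes) + 1, 1, 1))


def _toy_null(k_crit, threshold=2.32):
    return ClusterNull(
        sizes=np.array([1]),
        max_sizes=np.array([1]),
        n_images=100,
        threshold=threshold,
        cluster_p=0.001,
        connectivity=18,
        k_crit=k_crit,
    )


class TestClusterCorrection:
    def test_printed_rule(self):
        # critical size "> 55" means k_crit = 56: of (217, 55, 12) only 217 survives
        out = apply_cluster_correction(_toy_report([217, 55, 12]), _toy_null(56))
        assert out.sizes == [217]

    def test_kcrit_one_is_identity(self):
        out = apply_cluster_correction(_toy_report([5, 3, 1]), _toy_null(1))
        assert out.sizes == [5, 3, 1]

    def test_empty_report(self):
        report = ClusterReport([], 2.32, 18, 1.0, (4, 4, 4))
        assert apply_cluster_correction(report, _toy_null(10)).clusters == []

    def test_threshold_mismatch_flagged(self):
        with pytest.raises(ValueError, match="threshold mismatch"):
            apply_cluster_correction(_toy_report([5]), _toy_null(1, threshold=3.1))


class TestMaskByGroupMean:
    def test_huge_positive_identity(self, rng):
        report = _toy_report([10, 4])
        maps = [np.full(report.grid_shape, 5.0) + 0.01 * rng.standard_normal(report.grid_shape) for _ in range(6)]
        out = mask_by_group_mean(report, maps, 0.0005)
        assert out.sizes == [10, 4]

    def test_noise_pass_fraction(self, rng):
        maps = [rng.standard_normal((40, 40, 40)) for _ in range(8)]
        from hemisym.inference import _group_mean_pass_mask

        frac = _group_mean_pass_mask(maps, 0.0005).mean()
        se = np.sqrt(0.0005 / 40**3)
        assert abs(frac - 0.0005) < 4 * se

    def test_half_nulled_region(self, rng):
        # favoured group active only in the first half of the cluster
        grid = (8, 8, 8)
        vox = (np.arange(8), np.zeros(8, int), np.zeros(8, int))
        cluster = Cluster(8, 3.0, (0, 0, 0), (0.0, 0.0, 0.0), vox, np.full(8, 3.0))
        report = ClusterReport([cluster], 2.32, 18, 1.0, grid)
        maps = []
        for _ in range(8):
            m = 0.5 * rng.standard_normal(grid)
            m[0:4, 0, 0] += 10.0
            maps.append(m)
        out = mask_by_group_mean(report, maps, 0.0005)
        assert out.sizes == [4]
        assert set(out.clusters[0].voxels[0]) == {0, 1, 2, 3}


class TestCohensD:
    def test_identical_groups(self, rng):
        maps = [rng.standard_normal((4, 4, 4)) for _ in range(4)]
        res = cohens_d_map(maps, [m.copy() for m in maps])
        np.testing.assert_allclose(np.nan_to_num(res.d), 0.0, atol=1e-12)
        assert res.volume_pos_cm3 == 0.0

    def test_boundary_excluded_by_strict_inequality(self):
        # pooled SD exactly 1, mean difference exactly 0.8 -> d = 0.8, excluded
        c = 2**-0.5
        maps_a = [np.full((1, 1, 1), 1.8 - c), np.full((1, 1, 1), 1.8 + c)]
        maps_b = [np.full((1, 1, 1), 1.0 - c), np.full((1, 1, 1), 1.0 + c)]
        res = cohens_d_map(maps_a, maps_b, voxel_size=10.0)
        assert res.d[0, 0, 0] == pytest.approx(0.8, abs=1e-12)
        assert res.volume_pos_cm3 == 0.0

    def test_volume_units(self, rng):
        maps_a = [np.full((2, 2, 2), 5.0) + 0.1 * rng.standard_normal((2, 2, 2)) for _ in range(4)]
        maps_b = [0.1 * rng.standard_normal((2, 2, 2)) for _ in range(4)]
        res = cohens_d_map(maps_a, maps_b, voxel_size=10.0)  # 1 cm3 per voxel
        assert res.volume_pos_cm3 == pytest.approx(8.0)


class TestLabelClusters:
    def test_uniform_label(self):
        report = _toy_report([6])
        labels = np.full(report.grid_shape, 3)
        out = label_clusters(report, labels, {3: "region"})
        assert out.clusters[0].regions == [
            ("region", 6, 3.0, out.clusters[0].regions[0][3])
        ]

    def test_small_region_dropped(self):
        # 9-voxel cluster straddling labels 7 (7 voxels) and 2 (2 voxels)
        report = _toy_report([9])
        labels = np.zeros(report.grid_shape, dtype=int)
        labels[0:7, 0, 0] = 7
        labels[7:9, 0, 0] = 2
        out = label_clusters(report, labels, {7: "big", 2: "small"})
        names = [r[0] for r in out.clusters[0].regions]
        assert names == ["big"]
        assert out.clusters[0].regions[0][1] == 7

    def test_passthrough_without_labels(self):
        report = _toy_report([4])
        assert label_clusters(report, None) is report

    def test_grid_mismatch(self):
        report = _toy_report([4])
        with pytest.raises(ValueError, match="grid"):
            label_clusters(report, np.zeros((2, 2, 2), dtype=int))


class TestNullSymmetryTmap:
    def test_null_properties(self):
        series_a = [make_series(shape=(10, 10, 10), nt=80, rho=0.3, seed=40 + i) for i in range(4)]
        series_b = [make_series(shape=(10, 10, 10), nt=80, rho=0.3, seed=50 + i) for i in range(4)]
        # average over several phase draws; spatial correlation leaves far
        # fewer independent voxels than the raw count, so bound loosely
        means, fracs = [], []
        for seed in range(4):
            tmap = null_symmetry_tmap(series_a, series_b, df=80.0, seed=seed)
            vals = tmap.values[np.isfinite(tmap.values)]
            means.append(vals.mean())
            fracs.append(np.mean(vals > stats.norm.isf(0.01)))
        assert abs(np.mean(means)) < 0.2
        assert np.mean(fracs) < 0.05

    def test_reproducible(self):
        series_a = [make_series(shape=(8, 8, 8), nt=60, seed=60 + i) for i in range(2)]
        series_b = [make_series(shape=(8, 8, 8), nt=60, seed=70 + i) for i in range(2)]
        a = null_symmetry_tmap(series_a, series_b, df=60.0, seed=4)
        b = null_symmetry_tmap(series_a, series_b, df=60.0, seed=4)
        np.testing.assert_array_equal(a.values, b.values)


class TestRunGroupAnalysis:
    def test_end_to_end_recovers_planted_effect(self):
        from hemisym.synthetic import GroupSpec, SimulationConfig, generate_group_dataset

        shape = (12, 12, 12)
        region = np.zeros(shape, dtype=bool)
        region[1:5, 4:8, 4:8] = True
        region |= flip_lr(region)
        cfg = SimulationConfig(
            grid_shape=shape, n_timepoints=400, smoothing_fwhm_mm=2.0, seed=3, dtype=np.float32
        )
        spec = GroupSpec(6, 0.1, region, 0.5, seed=3)
        ga, gb = generate_group_dataset(spec, cfg)
        params = GroupParams(cluster_p=0.05, n_null=200, acf_runs=1, n_pairs=100)
        res = run_group_analysis(ga, gb, params, seed=3)
        found = np.zeros(shape, dtype=bool)
        for c in res.clusters_masked.clusters:
            found[c.voxels] = True
        assert (found & region).sum() > 0
        assert np.count_nonzero((res.effect_size.d > 0.8) & region) > 0
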