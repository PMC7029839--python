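import numpy as np
import pytest
from scipy import ndimage

from crossnet.seedfc import (
    FisherZMap,
    apply_cluster_threshold,
    estimate_smoothness,
    make_sphere_roi,
    mc_cluster_threshold,
    seed_fc_map,
    two_sample_tmap,
)
from crossnet.synthetic import CohortSpec, SyntheticVolumeSpec, generate_volume_cohort

VOX = 3.0
SHAPE = (24, 24, 24)


def centered_affine(voxel=VOX, shape=SHAPE):
    aff = np.diag([voxel] * 3 + [1.0])
    aff[:3, 3] = -np.array(shape) / 2.0 * voxel
    return aff


class TestSphereROI:
    def test_tiny_diameter_falls_back_to_nearest_voxel(self):
        roi = make_sphere_roi((0.1, 0.2, -0.1), 0.5, centered_affine(), SHAPE)
        assert roi.n_voxels == 1

    def test_voxel_count_matches_brute_force_lattice_scan(self):
        # radius 5 mm sphere on a 1 mm isotropic grid
        shape = (21, 21, 21)
        aff = np.eye(4)
        aff[:3, 3] = -10.0
        roi = make_sphere_roi((0.0, 0.0, 0.0), 10.0, aff, shape)
        count = sum(
            1
            for i in range(-10, 11)
            for j in range(-10, 11)
            for k in range(-10, 11)
            if i * i + j * j + k * k <= 25
        )
        assert roi.n_voxels == count

    def test_all_voxels_within_radius(self):
        aff = centered_affine()
        roi = make_sphere_roi((1.0, -5.0, 4.0), 9.0, aff, SHAPE)
        centers = (np.column_stack([roi.voxels, np.ones(roi.n_voxels)]) @ aff.T)[:, :3]
        assert np.all(np.linalg.norm(centers - [1.0, -5.0, 4.0], axis=1) <= 4.5)

    def test_default_midbrain_seed_resolves_inside_standard_shaped_grid(self):
        roi = make_sphere_roi((1.0, -29.0, -12.0), 4.0, centered_affine(), SHAPE)
        assert roi.n_voxels >= 1

    def test_centre_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_sphere_roi((500.0, 0.0, 0.0), 4.0, centered_affine(), SHAPE)


class TestSeedFCMap:
    def _vol_with_seed(self, rng, t=80):
        vol = rng.standard_normal((6, 6, 6, t))
        aff = centered_affine(1.0, (6, 6, 6))
        roi = make_sphere_roi((0.0, 0.0, 0.0), 1.0, aff, (6, 6, 6))
        return vol, roi

    def test_voxel_equal_to_seed_series_hits_clip(self, rng):
        vol, roi = self._vol_with_seed(rng)
        i, j, k = roi.voxels[0]
        zm = seed_fc_map(vol, roi)
        assert zm.data[i, j, k] == pytest.approx(np.arctanh(1 - 1e-7))
        assert zm.n_clipped >= 1

    def test_orthogonal_voxel_near_zero(self, rng):
        vol, roi = self._vol_with_seed(rng, t=64)
        i, j, k = roi.voxels[0]
        t = np.arange(64)
        vol[i, j, k] = np.cos(2 * np.pi * t / 8)
        vol[0, 0, 0] = np.sin(2 * np.pi * t / 8)
        zm = seed_fc_map(vol, roi)
        assert abs(zm.data[0, 0, 0]) < 1e-10

    def test_known_coupling_recovered_in_target_region(self):
        # target voxels share the seed's signal at coupling c -> median z ~ artanh(c)
        rng = np.random.default_rng(6)
        t, c = 4000, 0.6
        vol = rng.standard_normal((8, 8, 8, t))
        aff = centered_affine(1.0, (8, 8, 8))
        roi = make_sphere_roi((0.0, 0.0, 0.0), 1.0, aff, (8, 8, 8))
        i, j, k = roi.voxels[0]
        seed_series = vol[i, j, k].copy()
        target = np.s_[6:8, 6:8, 6:8]
        noise = rng.standard_normal((2, 2, 2, t))
        vol[target] = c * seed_series + np.sqrt(1 - c * c) * noise
        zm = seed_fc_map(vol, roi)
        med = np.median(zm.data[target])
        assert med == pytest.approx(np.arctanh(c), abs=3 / np.sqrt(t) + 0.02)

    def test_zero_variance_seed_rejected(self):
        vol = np.ones((4, 4, 4, 10))
        aff = centered_affine(1.0, (4, 4, 4))
        roi = make_sphere_roi((0.0, 0.0, 0.0), 1.0, aff, (4, 4, 4))
        with pytest.raises(ValueError, match="variance"):
            seed_fc_map(vol, roi)


class TestTwoSampleTMap:
    def test_identical_groups_give_zero_t(self, rng):
        maps = [
            FisherZMap(f"s{i}", rng.standard_normal((5, 5, 5)), np.ones((5, 5, 5), bool))
            for i in range(4)
        ]
        t, p, valid = two_sample_tmap(maps, [FisherZMap(m.subject_id + "b", m.data.copy(), m.mask) for m in maps])
        assert np.allclose(t, 0.0)
        assert np.all(p[valid] == pytest.approx(1.0))

    def test_single_voxel_matches_textbook_formula(self):
        a_vals = [1.2, 0.8, 1.5, 1.1]
        b_vals = [0.4, 0.9, 0.2]
        mask = np.ones((1, 1, 1), bool)
        maps_a = [FisherZMap(f"a{i}", np.full((1, 1, 1), v), mask) for i, v in enumerate(a_vals)]
        maps_b = [FisherZMap(f"b{i}", np.full((1, 1, 1), v), mask) for i, v in enumerate(b_vals)]
        t, p, valid = two_sample_tmap(maps_a, maps_b)
        na, nb = len(a_vals), len(b_vals)
        sa2 = np.var(a_vals, ddof=1)
        sb2 = np.var(b_vals, ddof=1)
        sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
        t_hand = (np.mean(a_vals) - np.mean(b_vals)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t[0, 0, 0] == pytest.approx(t_hand, abs=1e-12)
        from scipy import stats

        assert p[0, 0, 0] == pytest.approx(
            2 * stats.t.sf(abs(t_hand), na + nb - 2), abs=1e-12
        )

    def test_zero_variance_voxels_marked_invalid(self):
        mask = np.ones((2, 1, 1), bool)
        mk = lambda v: FisherZMap("s", np.array(v).reshape(2, 1, 1), mask)
        a = [mk([1.0, 0.3]), mk([1.0, 0.5])]
        b = [mk([1.0, 0.1]), mk([1.0, 0.9])]
        _, _, valid = two_sample_tmap(a, b)
        assert not valid[0, 0, 0] and valid[1, 0, 0]

    def test_constructed_group_effect_peaks_in_target_region(self):
        npn = {"MTN": 3, "DMN": 3, "SAN": 3, "STM": 6, "TEP": 3, "HIP": 2, "DAN": 3}
        cs = CohortSpec(n_control=10, n_patient=10, T=120,
                        n_regions_per_network=npn, delta_stm=0.0, seed=3)
        vs = SyntheticVolumeSpec(seed_region="HIP_r01",
                                 effect_targets=("DAN_r01",), effect_coupling=0.3)
        vc = generate_volume_cohort(vs, cs)
        lab = vc.label_map["HIP_r01"]
        vox = np.argwhere(vc.atlas == lab)[0]
        center = tuple((vc.affine @ np.append(vox, 1.0))[:3])
        roi = make_sphere_roi(center, 4.0, vc.affine, vc.atlas.shape)
        groups = {"CN": [], "FBSS": []}
        for r in vc.records:
            groups[r.group].append(
                seed_fc_map(vc.volumes[r.subject_id], roi, None, r.subject_id)
            )
        tvol, _, _ = two_sample_tmap(groups["CN"], groups["FBSS"])
        tvol[vc.atlas == lab] = 0.0  # mask out the seed's own parcel
        peak = np.unravel_index(np.argmax(np.abs(tvol)), tvol.shape)
        assert vc.atlas[peak] == vc.label_map["DAN_r01"]


class TestSmoothnessEstimator:
    def test_white_noise_reports_about_one_voxel(self):
        rng = np.random.default_rng(1)
        maps = [rng.standard_normal(SHAPE) for _ in range(5)]
        est = estimate_smoothness(maps, VOX)
        assert est == pytest.approx(VOX, rel=0.15)

    def test_smoothed_noise_within_20_percent_of_true_fwhm(self):
        rng = np.random.default_rng(2)
        sigma_vox = 6.0 / 2.3548 / VOX
        maps = [
            ndimage.gaussian_filter(rng.standard_normal(SHAPE), sigma_vox)
            for _ in range(8)
        ]
        est = estimate_smoothness(maps, VOX)
        assert est == pytest.approx(6.0, rel=0.2)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_smoothness([np.ones(SHAPE)], VOX)


class TestMonteCarloThreshold:
    def test_unsmoothed_sparse_threshold_is_tiny(self):
        # voxel_p = 1e-4 on 24^3 independent voxels: expect ~1.4 suprathreshold
        # voxels per iterate, so isolated singletons dominate the null maximum
        thr = mc_cluster_threshold(SHAPE, None, 0.0, VOX, voxel_p=1e-4,
                                   alpha=0.05, n_iter=300, seed=12)
        assert thr.min_cluster_extent <= 2

    def test_threshold_nondecreasing_in_fwhm(self):
        extents = [
            mc_cluster_threshold(SHAPE, None, fwhm, VOX, voxel_p=0.05,
                                 alpha=0.05, n_iter=300, seed=31).min_cluster_extent
            for fwhm in (0.0, 4.5, 9.0)
        ]
        assert extents[0] <= extents[1] <= extents[2]
        assert extents[2] > extents[0]

    def test_suprathreshold_fraction_matches_voxel_p(self):
        rng = np.random.default_rng(14)
        from scipy import stats

        p = 0.05
        z = stats.norm.isf(p / 2)
        fracs = []
        sigma = 4.0 / 2.3548 / VOX
        for _ in range(50):
            f = ndimage.gaussian_filter(rng.standard_normal(SHAPE), sigma)
            f /= f.std()
            fracs.append(np.mean(np.abs(f) > z))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - p) < 3 * se + 0.005

    def test_unresolvable_alpha_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            mc_cluster_threshold(SHAPE, None, 0.0, VOX, alpha=0.001, n_iter=100)

    def test_deterministic_under_fixed_seed(self):
        a = mc_cluster_threshold(SHAPE, None, 6.0, VOX, n_iter=150, alpha=0.05, seed=5)
        b = mc_cluster_threshold(SHAPE, None, 6.0, VOX, n_iter=150, alpha=0.05, seed=5)
        assert a == b


class TestApplyClusterThreshold:
    def _thr(self, extent, connectivity="faces"):
        from crossnet.seedfc import MonteCarloThreshold

        return MonteCarloThreshold(0.05, 0.01, 6.0, 1000, extent,
                                   extent * VOX**3, connectivity, VOX**3)

    def test_all_zero_map_gives_empty_report(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        assert apply_cluster_threshold(t, p, self._thr(5), centered_affine()) == []

    def test_blob_kept_or_dropped_by_extent(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        t[2:4, 2:4, 2:4] = 3.0  # 8-voxel positive blob
        p[2:4, 2:4, 2:4] = 0.001
        kept = apply_cluster_threshold(t, p, self._thr(8), centered_affine())
        assert len(kept) == 1 and kept[0].n_voxels == 8 and kept[0].sign == 1
        dropped = apply_cluster_threshold(t, p, self._thr(9), centered_affine())
        assert dropped == []

    def test_positive_and_negative_clusters_are_sign_pure_and_disjoint(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        t[1:3, 1:3, 1:3] = 4.0
        t[3:5, 1:3, 1:3] = -4.0  # face-adjacent to the positive blob
        p[1:5, 1:3, 1:3] = 0.001
        out = apply_cluster_threshold(t, p, self._thr(2), centered_affine())
        assert {c.sign for c in out} == {1, -1}
        assert all(c.n_voxels == 8 for c in out)

    def test_peak_coordinates_reported_in_mm(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        t[10:13, 10:13, 10:13] = 2.0
        t[11, 11, 11] = 7.5
        p[10:13, 10:13, 10:13] = 0.01
        (c,) = apply_cluster_threshold(t, p, self._thr(5), centered_affine())
        expect = (centered_affine() @ np.array([11, 11, 11, 1.0]))[:3]
        assert c.peak_mm == tuple(expect)
        assert c.peak_t == 7.5
        assert c.extent_mm3 == 27 * VOX**3

    def test_component_labels_match_flood_fill_oracle(self, rng):
        def flood_fill_components(mask):
            # brute-force 6-neighbour BFS, independent of scipy/skimage
            comps = np.zeros(mask.shape, dtype=int)
            nxt = 0
            for start in np.argwhere(mask):
                s = tuple(start)
                if comps[s]:
                    continue
                nxt += 1
                stack = [s]
                comps[s] = nxt
                while stack:
                    x, y, z = stack.pop()
                    for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        q = (x + dx, y + dy, z + dz)
                        if all(0 <= q[i] < mask.shape[i] for i in range(3)) \
                                and mask[q] and not comps[q]:
                            comps[q] = nxt
                            stack.append(q)
            return comps

        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.2
            t = np.where(mask, 5.0, 0.0)
            p = np.where(mask, 0.001, 1.0)
            out = apply_cluster_threshold(t, p, self._thr(1), np.eye(4))
            oracle = flood_fill_components(mask)
            sizes = sorted(np.bincount(oracle.ravel())[1:], reverse=True)
            assert sorted((c.n_voxels for c in out), reverse=True) == sizes
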