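import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmh3d import lesion_analysis as la
from wmh3d.volume_io import BinaryMask, LabelMap, Volume
from wmh3d.wmh_core import WMStats


def brute_force_fa(coords, weights, spacing):
    """Independent oracle: explicit accumulation of the weighted inertia
    tensor and eigenvalues via the general (non-symmetric) solver."""
    coords = np.asarray(coords, float) * np.asarray(spacing, float)
    w = np.asarray(weights, float)
    c = np.zeros(3)
    for p, wi in zip(coords, w):
        c += wi * p
    c /= w.sum()
    T = np.zeros((3, 3))
    for p, wi in zip(coords, w):
        d = p - c
        for i in range(3):
            for j in range(3):
                T[i, j] += wi * d[i] * d[j]
    T /= w.sum()
    lam = np.sort(np.real(np.linalg.eigvals(T)))[::-1]
    lam = np.clip(lam, 0, None)
    if (lam**2).sum() == 0:
        return 0.0
    lbar = lam.mean()
    return float(np.sqrt(1.5) * np.sqrt(((lam - lbar) ** 2).sum()) / np.sqrt((lam**2).sum()))


def ball_coords(radius):
    g = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    inside = x**2 + y**2 + z**2 <= radius**2
    return np.c_[x[inside], y[inside], z[inside]]


class TestFA:
    def test_ball_is_isotropic(self):
        coords = ball_coords(8)
        fa = la.lesion_fa(coords, np.ones(len(coords)), (1, 1, 1))
        assert fa < 0.05

    def test_rod_is_anisotropic(self):
        coords = np.c_[np.zeros(21), np.zeros(21), np.arange(21)]
        fa = la.lesion_fa(coords, np.ones(21), (1, 1, 1))
        assert fa > 0.9

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.integers(0, 6, (40, 3))
        w = rng.random(40) + 0.1
        f1 = la.lesion_fa(coords, w, (0.5, 0.5, 1.0))
        f2 = la.lesion_fa(coords, 7.3 * w, (0.5, 0.5, 1.0))
        assert f1 == pytest.approx(f2)

    def test_single_voxel_is_isotropic_point(self):
        assert la.lesion_fa(np.array([[2, 3, 4]]), np.array([5.0]), (1, 1, 1)) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            la.lesion_fa(np.empty((0, 3)), np.empty(0), (1, 1, 1))

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            la.lesion_fa(np.array([[0, 0, 0], [1, 0, 0]]), np.zeros(2), (1, 1, 1))

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        coords = rng.integers(0, 8, (n, 3))
        w = rng.random(n) + 0.05
        spacing = (0.5, 0.5, 1.0)
        assert la.lesion_fa(coords, w, spacing) == pytest.approx(
            brute_force_fa(coords, w, spacing), abs=1e-9
        )

    def test_fa_in_unit_interval_and_monotone_in_aspect_ratio(self):
        fas = []
        for c in (5, 9, 15, 25):
            x, y, z = np.meshgrid(
                np.arange(5), np.arange(5), np.arange(c), indexing="ij"
            )
            coords = np.c_[x.ravel(), y.ravel(), z.ravel()]
            fa = la.lesion_fa(coords, np.ones(len(coords)), (1, 1, 1))
            assert 0.0 <= fa <= 1.0
            fas.append(fa)
        assert all(a < b for a, b in zip(fas, fas[1:]))


class TestDistance:
    def test_face_adjacent_is_within_one_mm(self):
        target = np.zeros((10, 10, 10), bool)
        target[5, 5, 5] = True
        d = la.distance_to_structure(
            np.array([[6, 5, 5]]), BinaryMask(target, (0.5, 0.5, 1.0)), (0.5, 0.5, 1.0)
        )
        assert d <= 1.0

    def test_straight_line_distance(self):
        target = np.zeros((20, 5, 5), bool)
        target[0, 2, 2] = True
        d = la.distance_to_structure(
            np.array([[10, 2, 2]]), BinaryMask(target, (0.5, 0.5, 1.0)), (0.5, 0.5, 1.0)
        )
        assert d == pytest.approx(5.0)

    def test_empty_target_is_infinite(self):
        target = BinaryMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
        assert np.isinf(la.distance_to_structure(np.array([[1, 1, 1]]), target, (1, 1, 1)))


def _scene(shape=(40, 40, 20), spacing=(0.5, 0.5, 1.0)):
    u = np.full(shape, 100.0)
    return u, spacing


class TestFilterFalsePositives:
    def _run(self, labels, u, sulcal, spacing, vent=None):
        vent = vent if vent is not None else np.zeros_like(sulcal)
        return la.filter_false_positives(
            LabelMap(labels, spacing),
            Volume(u, spacing),
            BinaryMask(vent, spacing),
            BinaryMask(sulcal, spacing),
        )

    def test_rod_removed_by_fa(self):
        u, spacing = _scene()
        labels = np.zeros((40, 40, 20), int)
        labels[10, 10, 2:18] = 1  # thin rod, FA ~ 1
        u[labels == 1] = 180.0
        sulcal = np.zeros((40, 40, 20), bool)
        sulcal[0, :, :] = True  # far away
        kept, log = self._run(labels, u, sulcal, spacing)
        assert kept.n_labels == 0
        assert list(log.reason) == ["FA"]

    def test_sphere_near_sulcal_csf_removed(self):
        u, spacing = _scene()
        labels = np.zeros((40, 40, 20), int)
        xx, yy, zz = np.meshgrid(*(np.arange(s) for s in (40, 40, 20)), indexing="ij")
        sphere = (xx - 10) ** 2 + (yy - 20) ** 2 + ((zz - 10) * 2) ** 2 <= 36
        labels[sphere] = 1
        u[sphere] = 180.0
        sulcal = np.zeros((40, 40, 20), bool)
        sulcal[2, :, :] = True  # 1.0 mm in-plane from the sphere edge at x=4
        kept, log = self._run(labels, u, sulcal, spacing)
        assert kept.n_labels == 0
        assert list(log.reason) == ["SULCAL_DIST"]

    def test_deep_sphere_retained(self):
        u, spacing = _scene()
        labels = np.zeros((40, 40, 20), int)
        xx, yy, zz = np.meshgrid(*(np.arange(s) for s in (40, 40, 20)), indexing="ij")
        sphere = (xx - 20) ** 2 + (yy - 20) ** 2 + ((zz - 10) * 2) ** 2 <= 36
        labels[sphere] = 1
        u[sphere] = 180.0
        sulcal = np.zeros((40, 40, 20), bool)
        sulcal[0, :, :] = True  # 10 mm away
        kept, log = self._run(labels, u, sulcal, spacing)
        assert kept.n_labels == 1
        assert log.empty


class TestSmallLesions:
    def _setup(self, shape=(60, 60, 30)):
        spacing = (0.5, 0.5, 1.0)
        rng = np.random.default_rng(0)
        u = 100.0 + rng.normal(0, 1, shape)
        brain = np.ones(shape, bool)
        vent = np.zeros(shape, bool)
        sulcal = np.zeros(shape, bool)
        sulcal[0, :, :] = True
        return u, brain, vent, sulcal, spacing

    def _detect(self, u, brain, vent, sulcal, spacing):
        return la.detect_small_lesions(
            Volume(u, spacing),
            WMStats(100.0, 5.0),
            BinaryMask(brain, spacing),
            BinaryMask(vent, spacing),
            BinaryMask(sulcal, spacing),
        )

    def test_small_bright_blob_detected(self):
        u, brain, vent, sulcal, spacing = self._setup()
        u[28:32, 28:32, 14:17] = 180.0  # 48 voxels ~ 0.012 mL
        lm, _ = self._detect(u, brain, vent, sulcal, spacing)
        assert lm.n_labels == 1
        assert (lm.data > 0).sum() == 48

    def test_large_component_excluded(self):
        u, brain, vent, sulcal, spacing = self._setup()
        u[20:30, 20:30, 10:14] = 180.0  # 400 voxels: belongs to the large path
        lm, _ = self._detect(u, brain, vent, sulcal, spacing)
        assert lm.n_labels == 0

    def test_small_rod_rejected_by_fa(self):
        u, brain, vent, sulcal, spacing = self._setup()
        u[30, 30, 2:28] = 180.0  # 26-voxel rod
        lm, _ = self._detect(u, brain, vent, sulcal, spacing)
        assert lm.n_labels == 0

    def test_sub_minimum_cluster_ignored_as_noise(self):
        u, brain, vent, sulcal, spacing = self._setup()
        u[10:12, 10:12, 20] = 180.0  # 4 voxels: below the noise-size floor
        lm, _ = self._detect(u, brain, vent, sulcal, spacing)
        assert lm.n_labels == 0

    def test_blob_hugging_ventricle_removed(self):
        u, brain, vent, sulcal, spacing = self._setup()
        vent[40:50, 40:50, 10:20] = True
        u[36:40, 42:46, 12:15] = 180.0  # touches the ventricle wall
        lm, _ = self._detect(u, brain, vent, sulcal, spacing)
        assert lm.n_labels == 0


class TestRegionGrow:
    def _grow(self, seeds, u, brain, spacing=(1, 1, 1), stats=WMStats(100.0, 5.0),
              params=None):
        return la.region_grow(
            LabelMap(seeds, spacing),
            Volume(u, spacing),
            stats,
            BinaryMask(brain, spacing),
            params,
        )

    UNCAPPED = la.FilterParams(growth_max_mm=np.inf)

    def test_seed_core_recovers_full_plateau(self):
        u = np.full((30, 30, 10), 100.0)
        plateau = np.zeros((30, 30, 10), bool)
        plateau[10:20, 10:20, 3:7] = True
        u[plateau] = 180.0
        seeds = np.zeros((30, 30, 10), int)
        seeds[13:17, 13:17, 4:6] = 1
        grown = self._grow(seeds, u, np.ones((30, 30, 10), bool), params=self.UNCAPPED)
        assert np.array_equal(grown.data > 0, plateau)

    def test_no_growth_into_baseline_wm(self):
        u = np.full((20, 20, 8), 100.0)
        seeds = np.zeros((20, 20, 8), int)
        seeds[10, 10, 4] = 1
        u[10, 10, 4] = 180.0
        grown = self._grow(seeds, u, np.ones((20, 20, 8), bool))
        assert (grown.data > 0).sum() == 1

    def test_growth_capped_at_maximum_reach(self):
        """A seed inside an arbitrarily large bright region accretes no
        voxel farther than growth_max_mm: edge recovery, not flood fill."""
        u = np.full((30, 30, 10), 180.0)
        seeds = np.zeros((30, 30, 10), int)
        seeds[15, 15, 5] = 1
        grown = self._grow(
            seeds, u, np.ones((30, 30, 10), bool),
            params=la.FilterParams(growth_max_mm=3.0),
        )
        dist = la._morph.distance_to_set_mm(seeds > 0, (1, 1, 1))
        assert np.array_equal(grown.data > 0, dist <= 3.0)

    def test_two_seeds_partition_shared_plateau(self):
        u = np.full((40, 20, 8), 100.0)
        plateau = np.zeros((40, 20, 8), bool)
        plateau[5:35, 5:15, 2:6] = True
        u[plateau] = 180.0
        seeds = np.zeros((40, 20, 8), int)
        seeds[8, 10, 4] = 1
        seeds[32, 10, 4] = 2
        grown = self._grow(seeds, u, np.ones((40, 20, 8), bool), params=self.UNCAPPED)
        covered = grown.data > 0
        assert np.array_equal(covered, plateau)  # union is the plateau
        assert (grown.data == 1).sum() > 0 and (grown.data == 2).sum() > 0
        # deterministic repeat
        again = self._grow(seeds, u, np.ones((40, 20, 8), bool), params=self.UNCAPPED)
        assert np.array_equal(grown.data, again.data)

    def test_superset_and_idempotent(self, bundle, pipeline_default):
        res = pipeline_default
        regrown = la.region_grow(res.lesions, res.u, res.stats, res.brain)
        assert np.array_equal(regrown.data, res.lesions.data)


class TestClassification:
    def _classify(self, lesion_x, target_x, spacing=(0.5, 0.5, 1.0)):
        shape = (40, 10, 10)
        labels = np.zeros(shape, int)
        labels[lesion_x, 5, 5] = 1
        vent = np.zeros(shape, bool)
        vent[target_x, :, :] = True
        u = np.full(shape, 150.0)
        recs = la.classify_lesions(
            LabelMap(labels, spacing),
            Volume(u, spacing),
            BinaryMask(vent, spacing),
            BinaryMask(np.zeros(shape, bool), spacing),
        )
        return recs[0]

    def test_edge_at_2mm_is_pvh(self):
        rec = self._classify(lesion_x=4, target_x=0)  # 4 voxels * 0.5 mm
        assert rec.dist_ventricle_mm == pytest.approx(2.0)
        assert rec.category == "PVH"

    def test_edge_at_5mm_is_dwmh(self):
        rec = self._classify(lesion_x=10, target_x=0)
        assert rec.dist_ventricle_mm == pytest.approx(5.0)
        assert rec.category == "DWMH"

    def test_exactly_3mm_is_dwmh_strict(self):
        rec = self._classify(lesion_x=6, target_x=0)
        assert rec.dist_ventricle_mm == pytest.approx(3.0)
        assert rec.category == "DWMH"

    def test_empty_ventricle_everything_dwmh(self):
        shape = (10, 10, 10)
        labels = np.zeros(shape, int)
        labels[5, 5, 5] = 1
        recs = la.classify_lesions(
            LabelMap(labels, (1, 1, 1)),
            Volume(np.full(shape, 150.0), (1, 1, 1)),
            BinaryMask(np.zeros(shape, bool), (1, 1, 1)),
            BinaryMask(np.zeros(shape, bool), (1, 1, 1)),
        )
        assert recs[0].category == "DWMH"
        assert np.isinf(recs[0].dist_ventricle_mm)

    def test_partition_property(self, pipeline_default):
        for r in pipeline_default.records:
            assert (r.category == "PVH") == (r.dist_ventricle_mm < 3.0)


class TestSummarize:
    def test_empty_records(self):
        s = la.summarize([])
        assert s["lesion_count"] == 0
        assert s["total_wmh_volume_ml"] == 0.0

    def test_two_lesion_additivity(self):
        mk = lambda lab, ml, cat: la.LesionRecord(
            lab, int(ml * 4000), ml, 150.0, (0, 0, 0), 0.1, 1.0 if cat == "PVH" else 9.0,
            5.0, cat,
        )
        s = la.summarize([mk(1, 0.5, "PVH"), mk(2, 0.25, "DWMH")])
        assert s["total_wmh_volume_ml"] == pytest.approx(0.75)
        assert s["pvh_count"] == 1 and s["dwmh_count"] == 1
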