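import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gutcount.core import ImageStack, LabelMap
from gutcount.segmentation import (
    NucleusRecord,
    SegmentationParams,
    measure_nuclei,
    segment_nuclei,
    split_touching,
    threshold_nuclei,
)
from gutcount.synthetic import SimulationParams, place_nuclei, render_channels


def brute_force_otsu(values):
    """Independent oracle: maximise between-class variance over all cuts."""
    xs = np.sort(np.asarray(values, dtype=float).ravel())
    n = xs.size
    best_cut, best_var = None, -1.0
    for i in range(1, n):
        if xs[i] == xs[i - 1]:
            continue
        lo, hi = xs[:i], xs[i:]
        var = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_cut = var, 0.5 * (xs[i - 1] + xs[i])
    return best_cut


def _one_channel(img, voxel_size=(1.0, 1.0, 1.0)):
    return ImageStack(np.asarray(img, dtype=float)[None], voxel_size, ["dna"])


class TestThresholdNuclei:
    def test_all_zero_channel(self):
        stack = _one_channel(np.zeros((4, 6, 6)))
        mask = threshold_nuclei(stack, "dna", SegmentationParams(threshold=10))
        assert not mask.any()

    def test_auto_matches_brute_force_on_two_valued_image(self):
        img = np.full((4, 8, 8), 10.0)
        img[1:3, 2:6, 2:6] = 200.0
        stack = _one_channel(img)
        mask = threshold_nuclei(stack, "dna", SegmentationParams(threshold="auto"))
        cut = brute_force_otsu(img)
        np.testing.assert_array_equal(mask, img > cut)
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_threshold_at_max_gives_empty_mask(self):
        img = np.full((2, 3, 3), 7.0)
        mask = threshold_nuclei(_one_channel(img), "dna", SegmentationParams(threshold=7))
        assert not mask.any()  # strict >

    def test_constant_image_auto_errors(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_nuclei(
                _one_channel(np.full((2, 3, 3), 5.0)), "dna", SegmentationParams()
            )

    def test_unknown_channel(self, flat_stack):
        with pytest.raises(KeyError):
            threshold_nuclei(flat_stack, "nope", SegmentationParams(threshold=1))

    @settings(max_examples=25, deadline=None)
    @given(
        img=hnp.arrays(np.float64, (3, 5, 5), elements=st.floats(0, 255)),
        cut=st.floats(0, 255),
    )
    def test_strict_inequality_property(self, img, cut):
        mask = threshold_nuclei(
            _one_channel(img), "dna", SegmentationParams(threshold=cut)
        )
        np.testing.assert_array_equal(mask, img > cut)


def _sphere_mask(shape, center, radius, voxel_size):
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)], indexing="ij"
    )
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


class TestSplitTouching:
    def test_empty_mask(self):
        lm = split_touching(np.zeros((3, 4, 4), bool), (1, 1, 1), SegmentationParams())
        assert lm.ids.size == 0

    def test_two_separated_spheres(self):
        voxel_size = (1.0, 0.5, 0.5)
        shape = (20, 40, 40)
        a = _sphere_mask(shape, (10, 5, 5), 3.0, voxel_size)
        b = _sphere_mask(shape, (10, 15, 15), 3.0, voxel_size)
        lm = split_touching(a | b, voxel_size, SegmentationParams())
        assert len(lm.ids) == 2
        # each label coextensive with one sphere
        for sphere in (a, b):
            ids = np.unique(lm.labels[sphere])
            assert len(ids) == 1 and ids[0] > 0
            assert (lm.labels == ids[0]).sum() == sphere.sum()

    def test_fused_pair_split_matches_truth(self):
        params = SimulationParams(
            shape_zyx=(20, 64, 64), n_small=0, n_big=0, n_touching_pairs=1, seed=4
        )
        truth = place_nuclei(params)
        mask = truth.label_map.labels > 0
        lm = split_touching(mask, params.voxel_size_zyx, SegmentationParams())
        assert len(lm.ids) == 2
        agree = total = 0
        for tid in truth.label_map.ids:
            m = truth.label_map.labels == tid
            vals, counts = np.unique(lm.labels[m], return_counts=True)
            agree += counts[vals > 0].max()
            total += m.sum()
        assert agree / total >= 0.90

    def test_watershed_disabled_keeps_pair_fused(self):
        params = SimulationParams(
            shape_zyx=(20, 64, 64), n_small=0, n_big=0, n_touching_pairs=1, seed=4
        )
        truth = place_nuclei(params)
        lm = split_touching(
            truth.label_map.labels > 0,
            params.voxel_size_zyx,
            SegmentationParams(watershed_enabled=False),
        )
        assert len(lm.ids) == 1

    def test_partition_property(self, small_truth, small_params):
        mask = small_truth.label_map.labels > 0
        lm = split_touching(mask, small_params.voxel_size_zyx, SegmentationParams())
        assert (lm.labels > 0).sum() == mask.sum()

    def test_watershed_never_decreases_label_count(self, make_simulation):
        for seed in range(3):
            params, truth, _ = make_simulation(seed=seed, n_touching_pairs=1)
            mask = truth.label_map.labels > 0
            n_ws = len(
                split_touching(mask, params.voxel_size_zyx, SegmentationParams()).ids
            )
            n_cc = len(
                split_touching(
                    mask,
                    params.voxel_size_zyx,
                    SegmentationParams(watershed_enabled=False),
                ).ids
            )
            assert n_ws >= n_cc

    def test_min_volume_filter_removes_specks(self):
        mask = np.zeros((5, 10, 10), bool)
        mask[2, 2:8, 2:8] = True  # 36 voxels = 36 um3
        mask[0, 0, 0] = True  # 1 voxel speck
        lm = split_touching(mask, (1, 1, 1), SegmentationParams(min_volume_um3=5.0))
        assert len(lm.ids) == 1
        assert list(lm.ids) == [1]  # compacted

    def test_labels_compacted(self, small_truth, small_params):
        lm = split_touching(
            small_truth.label_map.labels > 0,
            small_params.voxel_size_zyx,
            SegmentationParams(),
        )
        np.testing.assert_array_equal(lm.ids, np.arange(1, len(lm.ids) + 1))


class TestMeasureNuclei:
    def test_single_voxel_volume(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 1
        lm = LabelMap(labels, (1.0, 0.5, 0.5))
        stack = ImageStack(np.ones((1, 2, 2, 2)), (1.0, 0.5, 0.5), ["dna"])
        (rec,) = measure_nuclei(lm, stack)
        assert rec.volume_um3 == pytest.approx(0.25)
        assert rec.centroid_zyx_um == pytest.approx((0.5, 0.25, 0.25))

    def test_digital_sphere_volume(self):
        # analytic oracle: 4/3 pi r^3 for r = 5 um at isotropic 0.25 um voxels
        voxel_size = (0.25, 0.25, 0.25)
        shape = (44, 44, 44)
        sphere = _sphere_mask(shape, (5.5, 5.5, 5.5), 5.0, voxel_size)
        lm = LabelMap(sphere.astype(np.int32), voxel_size)
        stack = ImageStack(np.ones((1, *shape)), voxel_size, ["dna"])
        (rec,) = measure_nuclei(lm, stack)
        analytic = 4.0 / 3.0 * np.pi * 5.0**3
        assert rec.volume_um3 == pytest.approx(analytic, rel=0.02)

    def test_clone_mean_exact_on_noise_free_render(self, make_simulation):
        params, truth, stack = make_simulation(seed=1, clone_fraction=1.0)
        recs = measure_nuclei(truth.label_map, stack)
        assert len(recs) == truth.n_nuclei
        for rec in recs:
            assert rec.mean_intensity["gfp"] == pytest.approx(200.0)
            assert rec.size_class is None and rec.clone is None

    def test_geometry_mismatch_errors(self, flat_stack):
        lm = LabelMap(np.zeros((3, 3, 3), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="mismatch"):
            measure_nuclei(lm, flat_stack)

    def test_idempotent(self, small_truth, small_stack):
        a = measure_nuclei(small_truth.label_map, small_stack)
        b = measure_nuclei(small_truth.label_map, small_stack)
        assert a == b

    def test_centroid_inside_bounds(self, small_truth, small_stack):
        extent = np.array(small_stack.shape_zyx) * np.array(small_stack.voxel_size_zyx)
        for rec in measure_nuclei(small_truth.label_map, small_stack):
            assert np.all(np.array(rec.centroid_zyx_um) > 0)
            assert np.all(np.array(rec.centroid_zyx_um) < extent)


class TestRecoveryInvariant:
    def test_clean_regime_recovers_truth(self, make_simulation):
        # moderate blur, SNR = 10 gaussian noise, no touching pairs
        params, truth, stack = make_simulation(
            seed=12,
            blur_sigma_zyx=(0.5, 0.3, 0.3),
            noise_model="gaussian",
            noise_scale=20.0,
        )
        labels = segment_nuclei(stack, "dna", SegmentationParams())
        recs = measure_nuclei(labels, stack)
        assert len(recs) == truth.n_nuclei
        tt = truth.truth_table
        for rec in recs:
            d = np.linalg.norm(
                tt[["z_um", "y_um", "x_um"]].to_numpy()
                - np.asarray(rec.centroid_zyx_um),
                axis=1,
            )
            true_vol = tt["volume_um3"].iloc[int(d.argmin())]
            assert rec.volume_um3 == pytest.approx(true_vol, rel=0.10)
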