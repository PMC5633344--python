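"""Marker-channel segmentation: edges, watershed splitting, postprocessing."""

import math

import numpy as np
import pytest

from pexflux import segmentation as G
from pexflux import synthetic as S
from pexflux.io import ImageStack

from conftest import make_sphere_stack


class TestPreprocess:
    def test_constant_stack_cancels_exactly(self):
        stack = ImageStack(np.full((4, 8, 8), 37.5))
        out = G.preprocess_stack(stack, 37.5)
        assert np.all(out.data == 0.0)

    def test_zero_background_is_identity(self):
        data = np.random.default_rng(0).normal(100, 5, (4, 8, 8))
        out = G.preprocess_stack(ImageStack(data), 0.0)
        np.testing.assert_array_equal(out.data, data)

    def test_residual_background_mean_near_zero(self, empty_truth):
        noise = S.NoiseModel(background_mean=100.0, background_sd=8.0)
        stacks = S.render_stack(empty_truth, noise, {"m": "peroxisome:marker"}, seed=1)
        out = G.preprocess_stack(stacks["m"], 100.0)
        n = out.data.size
        assert abs(out.data.mean()) < 3 * 8.0 / math.sqrt(n)

    def test_excessive_background_warns(self, caplog):
        stack = ImageStack(np.full((2, 4, 4), 10.0))
        with caplog.at_level("WARNING", logger="pexflux.segmentation"):
            G.preprocess_stack(stack, 100.0)
        assert any("exceeds stack maximum" in r.message for r in caplog.records)


class TestDetectObjectMask:
    def test_empty_stack_gives_empty_mask(self):
        mask = G.detect_object_mask(ImageStack(np.zeros((6, 16, 16))), G.SegmentationParams())
        assert not mask.any()

    def test_single_sphere_one_component_volume_within_25pct(self):
        stack = make_sphere_stack(radius=4.0)
        mask = G.detect_object_mask(stack, G.SegmentationParams())
        from scipy import ndimage as ndi

        _, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 1
        truth = 4.0 / 3.0 * math.pi * 4.0**3
        assert mask.sum() == pytest.approx(truth, rel=0.25)

    def test_separated_spheres_give_two_components(self):
        shape = (24, 64, 64)
        zz, yy, xx = np.indices(shape)
        data = np.zeros(shape)
        for c in [(12, 16, 16), (12, 48, 48)]:
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            data[d2 <= 16] = 200.0
        mask = G.detect_object_mask(ImageStack(data), G.SegmentationParams())
        from scipy import ndimage as ndi

        _, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 2

    def test_raising_high_threshold_never_adds_mask_voxels(self):
        spec = S.GeometrySpec(seed=2, n_peroxisomes=4)
        truth = S.generate_geometry(spec)
        stacks = S.render_stack(truth, S.DEFAULT_NOISE, {"m": "peroxisome:marker"}, seed=2)
        stack = G.preprocess_stack(stacks["m"], 100.0)
        sizes = []
        for high in (0.90, 0.95, 0.98, 0.995):
            p = G.SegmentationParams(low_threshold=0.85, high_threshold=high)
            sizes.append(int(G.detect_object_mask(stack, p).sum()))
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))


class TestSplitObjects:
    def test_single_sphere_single_label(self):
        stack = make_sphere_stack(radius=4.0)
        mask = stack.data > 0
        labels = G.split_objects(mask, G.SegmentationParams())
        assert labels.n_objects == 1

    def test_fused_spheres_split_at_neck(self):
        shape = (24, 64, 64)
        zz, yy, xx = np.indices(shape)
        mask = np.zeros(shape, dtype=bool)
        for c in [(12, 32, 24), (12, 32, 35)]:  # centers 11 apart, radii 6: thin neck
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            mask |= d2 <= 36
        labels = G.split_objects(mask, G.SegmentationParams(min_seed_distance=4))
        assert labels.n_objects == 2

    def test_voxel_conservation(self, rng):
        mask = rng.random((10, 24, 24)) > 0.8
        labels = G.split_objects(mask, G.SegmentationParams())
        np.testing.assert_array_equal(labels.labels > 0, mask)

    def test_empty_mask_gives_empty_map(self):
        labels = G.split_objects(np.zeros((4, 8, 8), bool), G.SegmentationParams())
        assert labels.n_objects == 0


class TestPostprocessLabels:
    def test_touching_mitochondria_merge(self):
        lab = np.zeros((6, 12, 12), dtype=np.int32)
        lab[2, 2:5, 2:5] = 1
        lab[2, 5:8, 2:5] = 2  # touching label 1
        out = G.postprocess_labels(G.LabelMap(lab), "mitochondrion")
        assert out.n_objects == 1

    def test_mitochondrion_inside_peroxisome_removed(self):
        perox = np.zeros((6, 12, 12), dtype=np.int32)
        perox[1:5, 2:9, 2:9] = 1
        mito = np.zeros_like(perox)
        mito[2:4, 4:6, 4:6] = 1
        out = G.postprocess_labels(
            G.LabelMap(mito), "mitochondrion", other=G.LabelMap(perox)
        )
        assert out.n_objects == 0

    def test_disjoint_maps_identity_up_to_reindexing(self):
        lab = np.zeros((6, 12, 12), dtype=np.int32)
        lab[1, 1:3, 1:3] = 2
        lab[4, 8:10, 8:10] = 5
        out = G.postprocess_labels(G.LabelMap(lab), "mitochondrion")
        assert out.n_objects == 2
        np.testing.assert_array_equal(out.labels > 0, lab > 0)

    def test_peroxisome_mode_is_identity(self):
        lab = np.zeros((4, 8, 8), dtype=np.int32)
        lab[1, 1:3, 1:3] = 1
        lab[1, 5:7, 5:7] = 2
        out = G.postprocess_labels(G.LabelMap(lab), "peroxisome")
        np.testing.assert_array_equal(out.labels, lab)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            G.postprocess_labels(
                G.LabelMap(np.zeros((4, 8, 8), np.int32)),
                "mitochondrion",
                other=G.LabelMap(np.zeros((4, 9, 8), np.int32)),
            )


class TestSegmentOrganelles:
    def test_recovers_well_separated_peroxisome_count(self):
        spec = S.GeometrySpec(seed=21, shape=(32, 128, 128), n_peroxisomes=10)
        truth = S.generate_geometry(spec)
        stacks = S.render_stack(truth, S.DEFAULT_NOISE, {"m": "peroxisome:marker"}, seed=21)
        labels = G.segment_organelles(
            stacks["m"], G.SegmentationParams(), camera_background=100.0
        )
        assert labels.n_objects == 10

    def test_tubule_recovered_as_single_mitochondrion(self):
        spec = S.GeometrySpec(
            seed=3, shape=(32, 96, 96), n_peroxisomes=0, n_mitochondria=1,
            mito_walk_steps=200,
        )
        truth = S.generate_geometry(spec)
        stacks = S.render_stack(truth, S.DEFAULT_NOISE, {"m": "mitochondrion:marker"}, seed=3)
        labels = G.segment_organelles(
            stacks["m"], G.SegmentationParams(mode="mitochondrion"), camera_background=100.0
        )
        assert labels.n_objects == 1

    def test_all_noise_stack_yields_no_objects(self, empty_truth):
        stacks = S.render_stack(empty_truth, S.DEFAULT_NOISE, {"m": "peroxisome:marker"}, seed=6)
        labels = G.segment_organelles(
            stacks["m"], G.SegmentationParams(), camera_background=100.0
        )
        assert labels.n_objects == 0

    def test_overlap_exclusion_leaves_no_shared_voxels(self):
        spec = S.GeometrySpec(
            seed=17, shape=(20, 40, 40), n_peroxisomes=1, peroxisome_radius=(4, 5),
            n_mitochondria=1, mito_walk_steps=150, allow_overlap=True, min_separation=1.0,
        )
        truth = S.generate_geometry(spec)
        stacks = S.render_stack(
            truth, S.DEFAULT_NOISE,
            {"p": "peroxisome:marker", "m": "mitochondrion:marker"}, seed=17,
        )
        perox = G.segment_organelles(stacks["p"], G.SegmentationParams(), camera_background=100.0)
        mito = G.segment_organelles(
            stacks["m"], G.SegmentationParams(mode="mitochondrion"),
            camera_background=100.0, other=perox,
        )
        assert not np.any((perox.labels > 0) & (mito.labels > 0))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        G.SegmentationParams(low_threshold=0.9, high_threshold=0.5)
    with pytest.raises(ValueError):
        G.SegmentationParams(mode="nucleus")
    with pytest.raises(ValueError):
        G.SegmentationParams(connectivity=18)
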