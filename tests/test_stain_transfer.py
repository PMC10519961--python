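"""CycleGAN model contracts: losses, buffer, patches, schedule, stitching."""

import numpy as np
import pytest

from virthist import nnet, phantom, stain_transfer as st
from virthist.encode import RGBImage, to_model_tensor, from_model_tensor


class TestLosses:
    def test_total_loss_weighting(self):
        parts = st.LossParts(adv_uv=1.0, adv_he=1.0, cyc=1.0, ident=1.0)
        assert st.total_loss(parts, st.LossWeights(150.0)) == 227.0

    def test_total_loss_zero_parts(self):
        parts = st.LossParts(0.0, 0.0, 0.0, 0.0)
        assert st.total_loss(parts) == 0.0

    def test_doubling_lambda_changes_only_weighted_terms(self):
        parts = st.LossParts(0.5, 0.7, 0.2, 0.1)
        t1 = st.total_loss(parts, st.LossWeights(150.0))
        t2 = st.total_loss(parts, st.LossWeights(300.0))
        assert t2 - t1 == pytest.approx(150.0 * 0.2 + 0.5 * 150.0 * 0.1)

    def test_nan_part_rejected(self):
        with pytest.raises(ValueError):
            st.total_loss(st.LossParts(np.nan, 0, 0, 0))

    def test_discriminator_loss_perfect_discrimination(self):
        assert st.adversarial_loss_d(np.ones((1, 3, 3)), np.zeros((1, 3, 3))) == 0.0

    def test_discriminator_loss_at_half(self):
        half = np.full((1, 4, 4), 0.5)
        assert st.adversarial_loss_d(half, half) == pytest.approx(0.5)

    def test_generator_loss_zero_when_fooled(self):
        assert st.adversarial_loss_g(np.ones((1, 5, 5))) == 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            st.adversarial_loss_g(np.zeros((0,)))

    def test_cycle_loss_identity_generators(self, rng):
        x = rng.random((3, 8, 8))
        assert st.cycle_loss(x, lambda v: v, lambda v: v) == 0.0

    def test_cycle_loss_constant_offset(self, rng):
        x = rng.random((3, 8, 8))
        assert st.cycle_loss(x, lambda v: v, lambda v: v + 0.1) == pytest.approx(0.1)

    def test_identity_loss_non_negative(self, rng):
        y = rng.random((3, 8, 8))
        assert st.identity_loss(y, lambda v: v * 0.9) >= 0


class TestImageBuffer:
    def test_fill_phase_returns_inputs(self):
        buf = st.ImageBuffer(50, np.random.default_rng(0))
        for i in range(50):
            img = np.full((1, 2, 2), float(i))
            assert st.ImageBuffer.query(buf, img) is img
        assert len(buf) == 50

    def test_capacity_never_exceeded(self, rng):
        buf = st.ImageBuffer(50, np.random.default_rng(1))
        for i in range(200):
            buf.query(np.full((1, 2, 2), float(i)))
            assert len(buf) <= 50

    def test_seeded_swap_sequence_reproducible(self):
        def run(seed):
            buf = st.ImageBuffer(5, np.random.default_rng(seed))
            return [float(buf.query(np.full((1,), float(i)))[0])
                    for i in range(30)]
        assert run(7) == run(7)
        assert run(7) != run(8)


class TestNetworkContracts:
    def test_generator_output_bounded_and_shape_preserving(self, rng):
        g = st.build_generator(st.GeneratorSpec(n_res_blocks=2, base_width=4),
                               np.random.default_rng(0))
        for shape in ((3, 64, 64), (3, 32, 48)):
            y = g(rng.normal(size=shape))
            assert y.shape == shape
            assert y.min() >= -1.0 and y.max() <= 1.0

    def test_generator_parameter_count_independent_of_input_size(self):
        g = st.build_generator(st.GeneratorSpec(n_res_blocks=2, base_width=4),
                               np.random.default_rng(0))
        n0 = nnet.parameter_count(g)
        g((np.zeros((3, 32, 32))))
        g((np.zeros((3, 64, 64))))
        assert nnet.parameter_count(g) == n0

    def test_discriminator_maps_256_to_30x30(self, rng):
        d = st.build_discriminator(st.DiscriminatorSpec(base_width=8),
                                   np.random.default_rng(0))
        out = d(rng.normal(size=(3, 256, 256)))
        assert out.shape == (1, 30, 30)

    def test_discriminator_receptive_field_is_70(self):
        assert st.discriminator_receptive_field() == 70

    def test_patch_score_is_mean_of_elements(self, rng):
        arr = rng.normal(size=(1, 30, 30))
        assert st.patch_score(arr) == pytest.approx(arr.mean())

    def test_infer_pads_non_divisible_sizes(self, rng):
        g = st.build_generator(st.GeneratorSpec(n_res_blocks=1, base_width=4),
                               np.random.default_rng(0))
        img = RGBImage(rng.random((30, 34, 3)))
        out = st.infer(g, img)
        assert out.rgb.shape == (30, 34, 3)
        assert out.rgb.min() >= 0 and out.rgb.max() <= 1

    def test_inference_deterministic(self, rng):
        g = st.build_generator(st.GeneratorSpec(n_res_blocks=1, base_width=4),
                               np.random.default_rng(0))
        img = RGBImage(rng.random((32, 32, 3)))
        assert np.array_equal(st.infer(g, img).rgb, st.infer(g, img).rgb)


class TestPreparePatches:
    def test_tiling_count_512_stride_256(self, rng):
        img = RGBImage(rng.random((512, 512, 3)))
        ps = st.prepare_patches(img, patch=256, stride=256, seed=0)
        assert len(ps.train) + len(ps.val) + len(ps.test) == 4

    def test_split_proportions_100_patches(self, rng):
        img = RGBImage(rng.random((320, 320, 3)))
        ps = st.prepare_patches(img, patch=32, stride=32, seed=0)
        assert len(ps.train) == 80
        assert len(ps.val) == 10
        assert len(ps.test) == 10

    def test_splits_are_disjoint(self, rng):
        img = RGBImage(rng.random((128, 128, 3)))
        ps = st.prepare_patches(img, patch=32, stride=32, seed=3)
        all_patches = np.concatenate([ps.train, ps.val, ps.test])
        assert len(all_patches) == 16

    def test_dihedral_group_closure(self):
        """Applying any two group elements lands back in the group."""
        base = np.arange(2 * 4 * 4, dtype=float).reshape(2, 4, 4)
        group = [np.ascontiguousarray(f(base)) for f in st._DIHEDRAL]
        for f in st._DIHEDRAL:
            for g_el in group:
                img = np.ascontiguousarray(f(g_el))
                assert any(np.array_equal(img, member) for member in group)

    def test_image_smaller_than_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            st.prepare_patches(RGBImage(rng.random((16, 16, 3))), patch=32)

    def test_patches_in_model_range(self, rng):
        img = RGBImage(rng.random((64, 64, 3)))
        ps = st.prepare_patches(img, patch=32, stride=32, seed=0)
        full = np.concatenate([ps.train, ps.val, ps.test])
        assert full.min() >= -1 and full.max() <= 1


class TestTraining:
    def test_learning_rate_schedule_linear_decay(self):
        cfg = st.TrainConfig()
        assert st.learning_rate_at(50, cfg) == pytest.approx(2e-4)
        assert st.learning_rate_at(100, cfg) == pytest.approx(2e-4)
        assert st.learning_rate_at(150, cfg) == pytest.approx(1e-4)
        assert st.learning_rate_at(200, cfg) == pytest.approx(2e-6, abs=1e-5)

    def test_short_seeded_run_reproducible(self):
        def run():
            d_a, _ = phantom.make_dual_channel(
                phantom.PhantomSpec(64, 64, n_nuclei=3, seed=1))
            d_b, _ = phantom.make_dual_channel(
                phantom.PhantomSpec(64, 64, n_nuclei=3, seed=2))
            from virthist.encode import to_network_input
            px = st.prepare_patches(to_network_input(d_a), patch=32, seed=1)
            py = st.prepare_patches(phantom.make_pseudo_he(d_b), patch=32, seed=2)
            model = st.CycleGAN(st.GeneratorSpec(n_res_blocks=1, base_width=4),
                                st.DiscriminatorSpec(base_width=4), seed=0)
            _, hist = st.train(model, st.DomainSets(px, py),
                               st.TrainConfig(seed=0, max_iterations=4))
            return hist.total
        assert np.array_equal(run(), run())

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = st.CycleGAN(st.GeneratorSpec(n_res_blocks=1, base_width=4),
                            st.DiscriminatorSpec(base_width=4), seed=5)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = st.CycleGAN.load(path)
        x = rng.normal(size=(3, 32, 32))
        assert np.array_equal(model.G_HE(x), loaded.G_HE(x))


class TestStitchStrips:
    def test_identity_operator_reproduces_input(self, rng):
        img = RGBImage(rng.random((200, 40, 3)))
        out = st.stitch_strips(lambda t: t, img, overlap=32,
                               memory_budget_px=40 * 64)
        assert np.abs(out.rgb - img.rgb).max() < 1e-12

    def test_single_pass_for_short_images(self, rng):
        img = RGBImage(rng.random((40, 40, 3)))
        out = st.stitch_strips(lambda t: t * 0.5, img, overlap=16,
                               memory_budget_px=1 << 20)
        # operator halves the [-1, 1] tensor: v -> (v + 0.5) / 2 in [0, 1]
        assert np.allclose(out.rgb, (img.rgb + 0.5) / 2)

    def test_local_operator_matches_unstitched(self, rng):
        """Stitching with overlap >= receptive field equals full inference."""
        from scipy.ndimage import uniform_filter

        def local_op(t):  # receptive field 9 px
            return np.stack([uniform_filter(c, size=9, mode="nearest")
                             for c in t])

        img = RGBImage(rng.random((300, 48, 3)))
        full = from_model_tensor(local_op(to_model_tensor(img))).rgb
        out = st.stitch_strips(local_op, img, overlap=40,
                               memory_budget_px=48 * 80).rgb
        assert np.abs(out - full).max() < 1e-5

    def test_blending_has_no_seam_on_constant_image(self):
        img = RGBImage(np.full((240, 32, 3), 0.6))
        out = st.stitch_strips(lambda t: t, img, overlap=24,
                               memory_budget_px=32 * 60)
        row_diff = np.abs(np.diff(out.rgb, axis=0)).max()
        assert row_diff < 1e-12
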