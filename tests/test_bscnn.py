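import numpy as np
import pytest

import blindsim as bs
from blindsim.bscnn import (
    BSCNNConfig,
    build_model,
    deconvolve,
    load_model,
    make_dataset,
    parameter_count,
    save_model,
    ssim_loss,
    ssim_loss_grad,
    train,
)

TINY = BSCNNConfig(
    encoder_features=(4, 6, 8),
    decoder_features=(6, 4),
    epochs=3,
    batch_size=8,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    scene = bs.make_cell_like_gt((256, 256), seed=1)
    patches = bs.extract_patches(scene, 40, patch_fov_in_dpsf=8.0, seed=2)
    return make_dataset(patches, d_sp=3.2, d_psf=8.0, seed=3, m_aux=16)


class TestArchitecture:
    @pytest.mark.parametrize("side", [64, 48])
    def test_output_shape_matches_input(self, side):
        model = build_model(TINY)
        x = np.random.default_rng(0).random((2, side, side))
        assert model.forward(x).shape == (2, side, side)

    def test_odd_sizes_handled_by_pad_and_crop(self):
        model = build_model(TINY)
        x = np.random.default_rng(0).random((1, 50, 70))
        assert model.forward(x).shape == (1, 50, 70)

    def test_parameter_count_matches_closed_form(self):
        assert build_model(TINY).n_parameters() == parameter_count(TINY)
        default = BSCNNConfig()
        # per-layer formula: 9*cin*cout + cout per 3x3 stage, 32 + 1 head
        expected = (
            (9 * 1 * 32 + 32) + (9 * 32 * 64 + 64) + (9 * 64 * 128 + 128)
            + (9 * 128 * 512 + 512) + (9 * 512 * 128 + 128)
            + (9 * 128 * 64 + 64) + (9 * 64 * 32 + 32) + (32 + 1)
        )
        assert parameter_count(default) == expected
        assert build_model(default).n_parameters() == expected

    def test_zeroed_head_gives_zero_output(self):
        model = build_model(TINY)
        model.head.w[:] = 0.0
        model.head.b[:] = 0.0
        x = np.random.default_rng(1).random((1, 32, 32))
        assert np.all(model.forward(x) == 0.0)

    def test_mismatched_decoder_depth_rejected(self):
        with pytest.raises(ValueError):
            BSCNNConfig(encoder_features=(8, 16, 32), decoder_features=(16,))

    def test_default_hyperparameters(self):
        cfg = BSCNNConfig()
        assert cfg.beta1 == 0.9 and cfg.beta2 == 0.999
        assert cfg.learning_rate == 0.001
        assert cfg.epochs == 120 and cfg.batch_size == 32

    def test_seeded_initialization_reproducible(self):
        a, b = build_model(TINY), build_model(TINY)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)


class TestSSIMLoss:
    def test_identical_images_give_zero_loss(self):
        x = np.random.default_rng(0).random((32, 32))
        assert ssim_loss(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_contrast_inversion_gives_loss_near_two(self):
        idx = np.indices((32, 32)).sum(axis=0)
        cb = (idx % 2).astype(float) - 0.5  # zero-mean checkerboard
        assert ssim_loss(cb + 0.5, -cb + 0.5) == pytest.approx(2.0, abs=0.1)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((32, 32)), rng.random((32, 32))
        assert ssim_loss(x, y) == pytest.approx(ssim_loss(y, x), abs=1e-12)

    def test_agrees_with_metrics_ssim(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((40, 40)), rng.random((40, 40))
        assert ssim_loss(x, y) == pytest.approx(1.0 - bs.ssim(x, y), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((24, 24)), rng.random((24, 24))
        _, grad = ssim_loss_grad(x, y)
        eps = 1e-6
        for i, j in [(6, 7), (12, 12), (20, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fd = (ssim_loss(xp, y) - ssim_loss(xm, y)) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_loss(np.zeros((8, 8)), np.zeros((9, 9)))


class TestBackprop:
    def test_network_gradient_matches_finite_differences(self):
        model = build_model(TINY)
        rng = np.random.default_rng(4)
        x, y = rng.random((2, 16, 16)), rng.random((2, 16, 16))
        out = model.forward(x)
        _, g = ssim_loss_grad(out, y)
        model.backward(g)
        params, grads = model.parameters(), model.gradients()
        eps = 1e-6
        for pi in (0, 3, len(params) - 2, len(params) - 1):
            p, gr = params[pi], grads[pi]
            idx = p.size // 2
            orig = p.flat[idx]
            p.flat[idx] = orig + eps
            lp = ssim_loss(model.forward(x), y)
            p.flat[idx] = orig - eps
            lm = ssim_loss(model.forward(x), y)
            p.flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert gr.flat[idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestDataset:
    def test_split_proportions_exact(self, tiny_dataset):
        train_set, val_set, test_set = tiny_dataset
        assert (len(train_set), len(val_set), len(test_set)) == (30, 8, 2)

    def test_inputs_non_negative_and_sparse(self, tiny_dataset):
        for sample in tiny_dataset[0][:10]:
            assert sample.input.min() >= 0
            assert np.mean(sample.input == 0) > 0.3

    def test_targets_are_unit_normalized(self, tiny_dataset):
        for sample in tiny_dataset[0][:10]:
            assert sample.target.max() == pytest.approx(1.0)

    def test_provenance_pairs_unique(self, tiny_dataset):
        keys = [s.provenance for split in tiny_dataset for s in split]
        assert len(keys) == len(set(keys))

    def test_deterministic_given_seed(self):
        scene = bs.make_cell_like_gt((128, 128), seed=1)
        patches = bs.extract_patches(scene, 6, patch_fov_in_dpsf=8.0, seed=2)
        a = make_dataset(patches, 3.2, 8.0, seed=5, m_aux=8)
        b = make_dataset(patches, 3.2, 8.0, seed=5, m_aux=8)
        for sa, sb in zip(a[0], b[0]):
            assert np.array_equal(sa.input, sb.input)
            assert np.array_equal(sa.target, sb.target)


class TestTraining:
    def test_smoke_training_decreases_loss(self, tiny_dataset):
        model = build_model(TINY)
        train(model, tiny_dataset, TINY)
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_zero_patience_stops_after_first_non_improvement(self, tiny_dataset):
        cfg = BSCNNConfig(
            encoder_features=(4, 6, 8), decoder_features=(6, 4),
            epochs=50, batch_size=8, early_stop_patience=0, seed=0,
            learning_rate=0.1,  # deliberately unstable so validation worsens
        )
        model = build_model(cfg)
        train(model, tiny_dataset, cfg)
        val = model.history["val_loss"]
        worse = [i for i in range(1, len(val)) if val[i] >= min(val[:i])]
        if worse:  # training stopped at the first non-improving epoch
            assert worse[0] == len(val) - 1

    def test_best_validation_weights_restored(self, tiny_dataset):
        cfg = BSCNNConfig(
            encoder_features=(4, 6, 8), decoder_features=(6, 4),
            epochs=6, batch_size=8, seed=1,
        )
        model = build_model(cfg)
        train(model, tiny_dataset, cfg)
        val_of_returned = 0.0
        x = np.stack([s.input for s in tiny_dataset[1]])
        y = np.stack([s.target for s in tiny_dataset[1]])
        val_of_returned = ssim_loss(model.forward(x), y)
        assert val_of_returned == pytest.approx(min(model.history["val_loss"]), abs=1e-9)

    def test_empty_sets_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError):
            train(model, ([], []), TINY)


class TestInference:
    def test_identical_frames_equal_single_frame_output(self, tiny_dataset):
        model = build_model(TINY)
        frame = tiny_dataset[0][0].input
        stack = bs.FrameStack(frames=np.stack([frame] * 3), role=bs.FrameRole.HP)
        out = deconvolve(model, stack)
        single = np.clip(model.predict(frame / frame.max()), 0, None)
        assert np.allclose(out.pixels, single, atol=1e-12)

    def test_output_non_negative(self, tiny_dataset):
        model = build_model(TINY)
        frames = np.stack([s.input for s in tiny_dataset[0][:4]])
        out = deconvolve(model, bs.FrameStack(frames=frames, role=bs.FrameRole.HP))
        assert out.pixels.min() >= 0

    def test_frame_order_invariance(self, tiny_dataset):
        model = build_model(TINY)
        frames = np.stack([s.input for s in tiny_dataset[0][:4]])
        a = deconvolve(model, bs.FrameStack(frames=frames, role=bs.FrameRole.HP))
        b = deconvolve(model, bs.FrameStack(frames=frames[::-1].copy(), role=bs.FrameRole.HP))
        assert np.allclose(a.pixels, b.pixels, atol=1e-12)

    def test_empty_stack_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError):
            deconvolve(model, bs.FrameStack(frames=np.empty((0, 8, 8)), role=bs.FrameRole.HP))


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_history(self, tmp_path, tiny_dataset):
        model = build_model(TINY)
        train(model, tiny_dataset, TINY)
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        loaded = load_model(path)
        for pa, pb in zip(model.parameters(), loaded.parameters()):
            assert np.array_equal(pa, pb)
        assert loaded.history == model.history
        assert loaded.config == model.config
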