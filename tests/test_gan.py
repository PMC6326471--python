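import numpy as np
import pandas as pd
import pytest

from blockstorm.nn import autograd as ag
from blockstorm.nn.autograd import Adam, Tensor
from blockstorm.nn.gan import (
    LossBreakdown,
    LossWeights,
    PsfKernel,
    TrainConfig,
    TrainedModel,
    composite_loss,
    export_model,
    infer_stack,
    load_model,
    maps_to_table,
    train,
)
from blockstorm.nn.models import (
    DiscriminatorSpec,
    GeneratorSpec,
    PatchDiscriminator,
    UNetGenerator,
)
from blockstorm.simulate import FramePair


def tiny_pairs(n=8, size=16, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        y = np.zeros((size, size))
        k = rng.integers(1, 4)
        ys, xs = rng.integers(2, size - 2, k), rng.integers(2, size - 2, k)
        y[ys, xs] = 1000.0
        from scipy import ndimage

        x = ndimage.gaussian_filter(y, 1.5) + rng.normal(0, 2.0, (size, size))
        pairs.append(FramePair(x=np.clip(x, 0, None), y=y))
    return pairs


class TestLossWeights:
    def test_validation(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_cgan=-1.0)

    def test_schedule(self):
        w = LossWeights(cgan_warmup_iters=1000, cgan_active_every=3)
        assert not w.cgan_active(0)
        assert not w.cgan_active(999)
        assert w.cgan_active(1000)
        assert not w.cgan_active(1001)
        assert not w.cgan_active(1002)
        assert w.cgan_active(1003)

    def test_zero_weight_never_active(self):
        w = LossWeights(lambda_cgan=0.0, cgan_warmup_iters=0)
        assert not w.cgan_active(5000)


class TestPsfKernel:
    def test_peak_at_center_and_nonnegative(self):
        k = PsfKernel(sigma=2.0).array()
        assert k.min() >= 0
        c = k.shape[0] // 2
        assert k[c, c] == k.max() == pytest.approx(1.0)

    def test_support_override(self):
        k = PsfKernel(sigma=1.0, support=5).array()
        assert k.shape == (5, 5)


class TestCompositeLoss:
    def _hand_loss(self, y, y_hat, kern, lam_l1, lam_l1s):
        """Explicit-loop reference for the two L1 terms."""
        pad = kern.shape[0] // 2
        yp = np.pad(y, pad)
        yhp = np.pad(y_hat, pad)
        n = y.shape[0]
        by = np.zeros_like(y)
        byh = np.zeros_like(y_hat)
        for i in range(n):
            for j in range(n):
                acc = acch = 0.0
                for a in range(kern.shape[0]):
                    for b in range(kern.shape[1]):
                        acc += kern[a, b] * yp[i + a, j + b]
                        acch += kern[a, b] * yhp[i + a, j + b]
                by[i, j] = acc
                byh[i, j] = acch
        l1 = np.mean(np.abs(by - byh))
        l1s = np.mean(np.abs(y_hat))
        return lam_l1 * l1 + lam_l1s * l1s, l1, l1s

    def test_matches_hand_loop_oracle(self):
        rng = np.random.default_rng(0)
        y = (rng.random((8, 8)) < 0.1).astype(float)
        y_hat = rng.random((8, 8))
        psf = PsfKernel(sigma=0.8, support=3)
        w = LossWeights(lambda_cgan=3.0, lambda_l1=100.0, lambda_l1s=100.0,
                        cgan_warmup_iters=1000)
        out = composite_loss(None, y, y_hat, None, None, psf, w, iteration=0)
        total, l1, l1s = self._hand_loss(y, y_hat, psf.array().astype(float),
                                         100.0, 100.0)
        assert out.l1_psf == pytest.approx(l1, rel=1e-6)
        assert out.l1_sparse == pytest.approx(l1s, rel=1e-6)
        assert out.l_cgan == 0.0  # warm-up
        assert out.total == pytest.approx(total, rel=1e-6)

    def test_decomposition_identity_with_adversarial_term(self):
        rng = np.random.default_rng(1)
        y = np.zeros((8, 8))
        y_hat = rng.random((8, 8))
        d_real = rng.uniform(0.4, 0.9, (1, 1, 2, 2))
        d_fake = rng.uniform(0.1, 0.6, (1, 1, 2, 2))
        w = LossWeights(cgan_warmup_iters=0, cgan_active_every=1)
        psf = PsfKernel(sigma=1.0)
        out = composite_loss(None, y, y_hat, d_real, d_fake, psf, w, 10)
        assert out.l_cgan > 0
        expected = (w.lambda_cgan * out.l_cgan + w.lambda_l1 * out.l1_psf
                    + w.lambda_l1s * out.l1_sparse)
        assert out.total == pytest.approx(expected, rel=1e-9)

    def test_perfect_prediction_beats_empty(self):
        # the blurred-L1 term must dominate the sparsity term, otherwise an
        # all-zero map would be as good as a perfect one
        y = np.zeros((16, 16))
        y[8, 8] = 1.0
        w = LossWeights()
        psf = PsfKernel(sigma=2.0)
        perfect = composite_loss(None, y, y, None, None, psf, w, 0)
        empty = composite_loss(None, y, np.zeros_like(y), None, None, psf, w, 0)
        assert perfect.total < 0.2 * empty.total

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            composite_loss(None, np.zeros((4, 4)), np.zeros((8, 8)), None,
                           None, PsfKernel(), LossWeights(), 0)


class TestAutograd:
    def test_conv2d_gradient_numeric(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.random((2, 3, 6, 6)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.random((4, 3, 3, 3)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.random(4).astype(np.float32), requires_grad=True)

        def forward():
            out = ag.conv2d(x, w, b, stride=2, pad=1)
            # smooth scalar head so finite differences are clean
            return ag.scale(ag.mean_abs(ag.sigmoid(out)), 10.0)

        loss = forward()
        loss.backward()
        for t in (x, w, b):
            flat = t.data.ravel()
            g = t.grad.ravel()
            for i in rng.choice(flat.size, 4, replace=False):
                eps = 1e-2
                orig = flat[i]
                flat[i] = orig + eps
                lp = float(forward().data)
                flat[i] = orig - eps
                lm = float(forward().data)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert g[i] == pytest.approx(num, abs=2e-3)

    def test_upsample_and_concat_gradients(self):
        x = Tensor(np.arange(1, 9, dtype=np.float32).reshape(1, 2, 2, 2),
                   requires_grad=True)
        up = ag.upsample_nearest(x, 2)
        assert up.shape == (1, 2, 4, 4)
        cat = ag.concat_channels(up, up)
        loss = ag.mean_abs(cat)
        loss.backward()
        # every input element feeds 2 * 4 output cells of |positive| values
        assert np.allclose(x.grad, 2 * 4 / cat.data.size)

    def test_softplus_is_smooth_relu(self):
        x = Tensor(np.array([[-30.0, 0.0, 30.0]], dtype=np.float32),
                   requires_grad=True)
        out = ag.softplus(x)
        assert out.data[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert out.data[0, 1] == pytest.approx(np.log(2.0), rel=1e-5)
        assert out.data[0, 2] == pytest.approx(30.0, rel=1e-6)
        ag.mean_abs(out).backward()
        assert x.grad[0, 1] == pytest.approx(0.5 / 3.0, rel=1e-5)

    def test_bce_matches_formula(self):
        p = Tensor(np.array([0.3, 0.8], dtype=np.float32))
        out = ag.bce(p, 1.0)
        assert float(out.data) == pytest.approx(
            -np.mean(np.log([0.3, 0.8])), rel=1e-5
        )

    def test_adam_converges_on_quadratic(self):
        t = Tensor(np.array([5.0], dtype=np.float32), requires_grad=True)
        opt = Adam([t], lr=0.1, beta1=0.25)
        for _ in range(500):
            opt.zero_grad()
            t.grad = 2 * t.data  # d/dt t^2
            opt.step()
        assert abs(float(t.data[0])) < 1e-2


class TestModels:
    def test_generator_shape_preserved(self):
        gen = UNetGenerator(GeneratorSpec(depth=3, base_channels=8), seed=0)
        x = Tensor(np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32))
        out = gen(x)
        assert out.shape == (2, 1, 32, 32)

    def test_generator_size_agnostic(self):
        gen = UNetGenerator(GeneratorSpec(depth=3, base_channels=8), seed=0)
        x = Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert gen(x).shape == (1, 1, 64, 64)
        x = Tensor(np.zeros((1, 1, 128, 128), dtype=np.float32))
        assert gen(x).shape == (1, 1, 128, 128)

    def test_indivisible_input_rejected(self):
        gen = UNetGenerator(GeneratorSpec(depth=3), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            gen(Tensor(np.zeros((1, 1, 20, 20), dtype=np.float32)))

    def test_depth_validation(self):
        with pytest.raises(ValueError):
            GeneratorSpec(depth=1)

    def test_reduced_depth_4_supported(self):
        gen = UNetGenerator(GeneratorSpec(depth=4, base_channels=8), seed=0)
        out = gen(Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32)))
        assert out.shape == (1, 1, 32, 32)

    def test_discriminator_patch_scores(self):
        disc = PatchDiscriminator(DiscriminatorSpec(n_layers=2, base_channels=8),
                                  seed=0)
        x = Tensor(np.random.default_rng(1).random((2, 1, 32, 32)).astype(np.float32))
        y = Tensor(np.random.default_rng(2).random((2, 1, 32, 32)).astype(np.float32))
        out = disc(x, y)
        assert out.shape[2] == out.shape[3] == 8  # 32 / 2**2
        assert np.all((out.data > 0) & (out.data < 1))

    def test_receptive_field_property(self):
        # 3x3 head, then each stride-2 4x4 conv maps rf -> 2*rf + 2
        assert DiscriminatorSpec(n_layers=1).patch_receptive_field == 8
        assert DiscriminatorSpec(n_layers=2).patch_receptive_field == 18


class TestTraining:
    def test_epochs_zero_returns_untrained(self):
        model = train(tiny_pairs(), GeneratorSpec(depth=2, base_channels=4),
                      DiscriminatorSpec(n_layers=1, base_channels=4),
                      LossWeights(), TrainConfig(epochs=0))
        assert model.history == []

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], GeneratorSpec(), DiscriminatorSpec(), LossWeights(),
                  TrainConfig(epochs=1))

    def test_mixed_sizes_rejected(self):
        pairs = tiny_pairs(2, size=16) + tiny_pairs(2, size=32)
        with pytest.raises(ValueError, match="mixed"):
            train(pairs, GeneratorSpec(), DiscriminatorSpec(), LossWeights(),
                  TrainConfig(epochs=1))

    def test_seeded_determinism(self):
        pairs = tiny_pairs(8)
        args = (GeneratorSpec(depth=2, base_channels=4),
                DiscriminatorSpec(n_layers=1, base_channels=4),
                LossWeights(cgan_warmup_iters=2, cgan_active_every=2))
        m1 = train(pairs, *args, TrainConfig(epochs=2, seed=5),
                   psf=PsfKernel(sigma=1.5))
        m2 = train(pairs, *args, TrainConfig(epochs=2, seed=5),
                   psf=PsfKernel(sigma=1.5))
        h1 = [b.total for b in m1.history]
        h2 = [b.total for b in m2.history]
        assert h1 == h2
        assert len(h1) == 2 * 2  # 8 pairs / batch 4 * 2 epochs

    def test_loss_decomposition_every_iteration(self):
        pairs = tiny_pairs(8)
        w = LossWeights(cgan_warmup_iters=1, cgan_active_every=1)
        model = train(pairs, GeneratorSpec(depth=2, base_channels=4),
                      DiscriminatorSpec(n_layers=1, base_channels=4),
                      w, TrainConfig(epochs=3, seed=1), psf=PsfKernel(sigma=1.5))
        for b in model.history:
            expected = (w.lambda_cgan * b.l_cgan + w.lambda_l1 * b.l1_psf
                        + w.lambda_l1s * b.l1_sparse)
            assert b.total == pytest.approx(expected, rel=1e-9)
            if not w.cgan_active(b.iteration):
                assert b.l_cgan == 0.0

    def test_smoke_convergence(self):
        # a few epochs on a toy dataset must reduce the blurred-L1 term
        pairs = tiny_pairs(16, seed=3)
        model = train(pairs, GeneratorSpec(depth=2, base_channels=8),
                      DiscriminatorSpec(n_layers=1, base_channels=4),
                      LossWeights(cgan_warmup_iters=10**6),
                      TrainConfig(learning_rate=2e-3, epochs=40, seed=2),
                      psf=PsfKernel(sigma=1.5))
        l1 = [b.l1_psf for b in model.history]
        assert np.mean(l1[-20:]) < 0.5 * np.mean(l1[:20])


class TestInference:
    def _quick_model(self):
        return train(tiny_pairs(8), GeneratorSpec(depth=2, base_channels=4),
                     DiscriminatorSpec(n_layers=1, base_channels=4),
                     LossWeights(cgan_warmup_iters=10**6),
                     TrainConfig(epochs=1, seed=0), psf=PsfKernel(sigma=1.5))

    def test_size_agnostic_inference(self):
        model = self._quick_model()  # trained on 16x16
        maps = infer_stack(model, np.zeros((2, 64, 64)))
        assert maps.shape == (2, 64, 64)
        assert np.all(maps >= 0)  # linear head is clipped at inference

    def test_upsampling_inference(self):
        model = self._quick_model()
        maps = infer_stack(model, np.zeros((1, 16, 16)), upsample=2)
        assert maps.shape == (1, 32, 32)

    def test_export_reload_bit_compatible(self, tmp_path):
        model = self._quick_model()
        path = str(tmp_path / "model.npz")
        export_model(model, path)
        back = load_model(path)
        rng = np.random.default_rng(4)
        stack = rng.random((3, 16, 16)) * 50
        assert np.array_equal(infer_stack(model, stack), infer_stack(back, stack))

    def test_export_metadata(self, tmp_path):
        import yaml

        model = self._quick_model()
        path = str(tmp_path / "model.npz")
        export_model(model, path)
        meta = yaml.safe_load((tmp_path / "model.yaml").read_text())
        assert meta["generator_spec"]["depth"] == 2
        assert meta["seed"] == 0

    def test_export_reduced_depth4(self, tmp_path):
        pairs = [FramePair(x=np.random.default_rng(0).random((16, 16)),
                           y=np.zeros((16, 16)))]
        model = train(pairs, GeneratorSpec(depth=4, base_channels=4),
                      DiscriminatorSpec(n_layers=1, base_channels=4),
                      LossWeights(), TrainConfig(epochs=0), psf=PsfKernel())
        path = str(tmp_path / "deep.npz")
        export_model(model, path)
        assert load_model(path).gspec.depth == 4


class TestArtifactSuppression:
    def test_fewer_false_detections_than_baseline_on_compressed_noise(
        self, trained_end_to_end
    ):
        # on noise-only compressed frames the learned localizer should emit
        # far fewer events than a classical detector run at a permissive
        # 1-sigma threshold, which fires on blocking artifacts
        from blockstorm.baseline import DetectionConfig, detect_peaks
        from blockstorm.camera import load_sensor_preset, simulate_sensor
        from blockstorm.degradation import CompressionConfig, block_transform_degrade

        model, cfg, _, _ = trained_end_to_end
        sensor = load_sensor_preset("huawei_p9_sec53")
        comp = CompressionConfig(quality=70, mode="bespoke_transform")
        dark = np.zeros(cfg.fov)
        stack = np.stack([
            block_transform_degrade(simulate_sensor(dark, sensor, seed=i), comp)
            for i in range(20)
        ])

        det_cfg = DetectionConfig(peak_threshold_k=1.0)
        n_baseline = sum(len(detect_peaks(f, det_cfg)) for f in stack)
        maps = infer_stack(model, stack, upsample=cfg.upsample)
        gan = maps_to_table(maps, threshold_fraction=0.3,
                            pixel_size=cfg.pixel_size, upsample=cfg.upsample)
        assert len(gan) < n_baseline


class TestMapsToTable:
    def test_empty_map(self):
        out = maps_to_table(np.zeros((2, 10, 10)))
        assert len(out) == 0
        assert list(out.columns) == ["frame", "x", "y", "photons"]

    def test_single_pixel_coordinate_oracle(self):
        # map index (row 10, col 20) at pixel 100 nm, upsample 5:
        # centre-of-pixel convention gives ((20+0.5)*20, (10+0.5)*20) nm
        m = np.zeros((1, 64, 64))
        m[0, 10, 20] = 1.0
        out = maps_to_table(m, threshold_fraction=0.3, pixel_size=100.0,
                            upsample=5)
        assert len(out) == 1
        assert out["x"].iloc[0] == pytest.approx(410.0)
        assert out["y"].iloc[0] == pytest.approx(210.0)

    def test_threshold_semantics(self):
        m = np.zeros((1, 32, 32))
        m[0, 5, 5] = 0.9
        m[0, 20, 20] = 0.5
        two = maps_to_table(m, threshold_fraction=0.3)
        one = maps_to_table(m, threshold_fraction=0.6)
        assert len(two) == 2
        assert len(one) == 1

    def test_connected_component_centroid(self):
        m = np.zeros((1, 16, 16))
        m[0, 4, 4] = 1.0
        m[0, 4, 5] = 3.0  # 8-connected pair: one row at weighted centroid
        out = maps_to_table(m, threshold_fraction=0.2, pixel_size=100.0,
                            upsample=1)
        assert len(out) == 1
        cx = (4 * 1.0 + 5 * 3.0) / 4.0
        assert out["x"].iloc[0] == pytest.approx((cx + 0.5) * 100.0)
        assert out["photons"].iloc[0] == pytest.approx(4.0)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            maps_to_table(np.zeros((1, 4, 4)), threshold_fraction=0.0)
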