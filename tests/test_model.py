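"""Encoder contract, heads, and the gradient-blocked dual forward pass."""

import numpy as np
import pytest

from supconvoice.autodiff import Tensor
from supconvoice.losses import SupConConfig, combined_objective
from supconvoice.model import (CE_ONLY, SUPCON, ClassifierHead, DualHeadModel,
                               ProjectionHead, TinyEncoder, make_tiny_encoder,
                               pool_frames)
from supconvoice.nn import cross_entropy


@pytest.fixture(scope="module")
def tiny_model():
    return DualHeadModel(make_tiny_encoder(32, 2, seed=0), seed=0)


@pytest.fixture(scope="module")
def wave_batch():
    rng = np.random.default_rng(0)
    return rng.standard_normal((4, 16000)).astype(np.float32) * 0.1


class TestTinyEncoder:
    def test_frame_count_for_standard_input(self):
        enc = make_tiny_encoder(32, 1, seed=0)
        out = enc(np.zeros((1, 80_000), dtype=np.float32))
        assert out.shape == (1, 250, 32)  # 80,000 / 320

    def test_seeded_initialisation_is_identical(self):
        a = make_tiny_encoder(32, 2, seed=7).state_dict()
        b = make_tiny_encoder(32, 2, seed=7).state_dict()
        assert set(a) == set(b)
        for k in a:
            assert np.array_equal(a[k], b[k]), k

    def test_layer_selection_equals_instrumented_forward(self, wave_batch):
        enc = make_tiny_encoder(32, 3, seed=1)
        full = enc(wave_batch)  # runs all blocks, stashes per-block outputs
        mid = enc(wave_batch, layer=2)
        # recompute block-by-block from the front-end
        x = Tensor(wave_batch)
        b, length = x.shape
        t = length // enc.STRIDE
        frames = x[:, : t * enc.STRIDE].reshape(b, t, enc.STRIDE)
        filt = enc.frame_proj(frames)
        cos_p, sin_p = filt[:, :, : enc.d], filt[:, :, enc.d:]
        h = ((cos_p * cos_p + sin_p * sin_p) + 1e-8).log() * 0.25
        for block in enc.blocks[:2]:
            h = block(h)
        assert np.allclose(mid.data, h.data, atol=1e-6)

    def test_requested_layer_independent_of_later_blocks(self, wave_batch):
        enc = make_tiny_encoder(32, 3, seed=2)
        before = enc(wave_batch, layer=1).data.copy()
        for p in enc.blocks[2].parameters():
            p.data = p.data + 1.0  # perturb a later block
        after = enc(wave_batch, layer=1).data
        assert np.array_equal(before, after)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_tiny_encoder(4, 1, seed=0)
        with pytest.raises(ValueError):
            make_tiny_encoder(32, 0, seed=0)
        enc = make_tiny_encoder(32, 2, seed=0)
        with pytest.raises(ValueError):
            enc(np.zeros((1, 16000), dtype=np.float32), layer=5)


class TestPoolFrames:
    def test_identical_frames_pool_to_themselves(self):
        v = np.arange(6.0)
        frames = np.tile(v, (5, 1))
        assert np.allclose(pool_frames(frames).data, v)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        frames = rng.standard_normal((7, 4))
        a = pool_frames(frames).data
        b = pool_frames(frames[rng.permutation(7)]).data
        assert np.allclose(a, b)

    def test_matches_independent_column_mean(self):
        rng = np.random.default_rng(4)
        frames = rng.standard_normal((7, 4))
        oracle = np.array([sum(frames[t, j] for t in range(7)) / 7 for j in range(4)])
        assert np.allclose(pool_frames(frames).data, oracle, atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pool_frames(np.zeros((0, 4)))


class TestClassifierHead:
    def test_eval_mode_is_deterministic(self):
        head = ClassifierHead(16, seed=0)
        head.eval()
        x = Tensor(np.random.default_rng(0).standard_normal((3, 16)))
        assert np.array_equal(head(x).data, head(x).data)

    def test_hidden_width_is_64(self):
        head = ClassifierHead(24, seed=0)
        assert head.fc1.weight.shape == (24, 64)
        assert head.fc2.weight.shape == (64, 2)

    def test_zero_weights_give_zero_logits(self):
        head = ClassifierHead(8, seed=0)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        head.eval()
        out = head(Tensor(np.ones((2, 8))))
        assert np.array_equal(out.data, np.zeros((2, 2)))

    def test_train_mode_dropout_changes_outputs(self):
        head = ClassifierHead(16, dropout=0.5, seed=0)
        head.train(True)
        x = Tensor(np.ones((8, 16)))
        assert not np.array_equal(head(x).data, head(x).data)


class TestProjectionHead:
    def test_output_is_unit_norm(self):
        proj = ProjectionHead(16, seed=0)
        z = proj(Tensor(np.random.default_rng(1).standard_normal((5, 16))))
        assert np.allclose(np.linalg.norm(z.data, axis=1), 1.0, atol=1e-6)

    def test_default_output_width_is_32(self):
        proj = ProjectionHead(16)
        z = proj(Tensor(np.zeros((2, 16))))
        assert z.shape == (2, 32)

    def test_scale_invariance_with_bias_free_layers(self):
        proj = ProjectionHead(8, seed=2)
        proj.fc1.bias.data = np.zeros_like(proj.fc1.bias.data)
        proj.fc2.bias.data = np.zeros_like(proj.fc2.bias.data)
        x = np.random.default_rng(2).standard_normal((4, 8))
        a = proj(Tensor(x)).data
        b = proj(Tensor(10.0 * x)).data
        assert np.allclose(a, b, atol=1e-6)

    def test_zero_input_is_epsilon_stabilised(self):
        proj = ProjectionHead(8, seed=3)
        for p in proj.parameters():
            p.data = np.zeros_like(p.data)
        z = proj(Tensor(np.zeros((1, 8))))
        assert np.all(np.isfinite(z.data))


class TestDualForward:
    def test_shape_contract(self, tiny_model, wave_batch):
        tiny_model.eval()
        out = tiny_model(wave_batch, mode=SUPCON)
        assert out.logits.shape == (4, 2)
        assert out.projection.shape == (4, 32)
        assert np.allclose(np.linalg.norm(out.projection.data, axis=1), 1.0, atol=1e-6)
        ce_out = tiny_model(wave_batch, mode=CE_ONLY)
        assert ce_out.projection is None

    def test_classification_loss_never_reaches_encoder_in_supcon_mode(self, wave_batch):
        model = DualHeadModel(make_tiny_encoder(32, 2, seed=5), seed=5)
        model.train(True)
        model.zero_grad()
        out = model(wave_batch, mode=SUPCON)
        ce = cross_entropy(out.logits, np.array([0, 1, 0, 1]))
        ce.backward()
        for p in model.encoder_parameters():
            assert p.grad is None or np.all(p.grad == 0.0)
        assert any(p.grad is not None and np.any(p.grad != 0)
                   for p in model.classifier.parameters())

    def test_contrastive_loss_never_reaches_classifier(self, wave_batch):
        from supconvoice.losses import supcon_loss

        model = DualHeadModel(make_tiny_encoder(32, 2, seed=6), seed=6)
        model.train(True)
        model.zero_grad()
        out = model(wave_batch, mode=SUPCON)
        supcon_loss(out.projection, np.array([0, 1, 0, 1])).backward()
        for p in model.classifier.parameters():
            assert p.grad is None or np.all(p.grad == 0.0)
        assert any(p.grad is not None and np.any(p.grad != 0)
                   for p in model.encoder_parameters())

    def test_ce_only_mode_updates_encoder(self, wave_batch):
        model = DualHeadModel(make_tiny_encoder(32, 2, seed=7), seed=7)
        model.train(True)
        model.zero_grad()
        out = model(wave_batch, mode=CE_ONLY)
        cross_entropy(out.logits, np.array([0, 1, 0, 1])).backward()
        grads = [p.grad for p in model.encoder_parameters()]
        assert any(g is not None and np.any(g != 0) for g in grads)

    def test_unknown_mode_rejected(self, tiny_model, wave_batch):
        with pytest.raises(ValueError):
            tiny_model(wave_batch, mode="BOTH")

    def test_combined_objective_on_live_model(self, wave_batch):
        model = DualHeadModel(make_tiny_encoder(32, 2, seed=8), seed=8)
        model.eval()
        out = model(wave_batch, mode=SUPCON)
        total, sup, ce = combined_objective(out.logits, out.projection,
                                            np.array([0, 1, 0, 1]), SupConConfig())
        assert np.isfinite(total.item())
        assert total.item() == pytest.approx(sup.item() + ce.item(), abs=1e-9)
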