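import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nabind.model import (
    FusionModel,
    ModelConfig,
    PredictionResult,
    Tensor,
    featurize,
    load_checkpoint,
    pad_batch,
    predict,
    save_checkpoint,
)
from nabind.plm import StubBackend
from nabind.records import ProteinRecord


class TestConfigGeometry:
    def test_default_widths_match_published_architecture(self):
        cfg = ModelConfig()
        assert cfg.plm_width == 1280
        assert cfg.stream_width == 512
        assert cfg.fused_width == 2304

    @settings(deadline=None, max_examples=30)
    @given(
        st.sampled_from([8, 16, 32, 64]),
        st.sampled_from([4, 8, 16]),
    )
    def test_fused_width_is_sum_of_stream_widths(self, plm_w, stream_w):
        cfg = ModelConfig(
            plm_width=plm_w,
            stream_width=stream_w,
            refine_heads=2,
            backbone_heads=2,
            backbone_layers=0,
            ffn_width=8,
        )
        assert cfg.fused_width == plm_w + 2 * stream_w

    def test_invalid_head_divisibility_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(stream_width=10, refine_heads=3, plm_width=16,
                        backbone_heads=2, ffn_width=8)


class TestStreamOps:
    def test_projection_output_width_and_nonneg_preactivation(self, tiny_model):
        block = Tensor(np.random.default_rng(0).normal(size=(1, 7, 5)))
        out = tiny_model.project_stream(block, "atchley")
        assert out.shape == (1, 7, 16)
        pre = tiny_model.atchley_proj.linear(block).relu().data
        assert (pre >= 0).all()

    def test_projection_width_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.project_stream(Tensor(np.zeros((1, 4, 20))), "atchley")

    def test_positional_encoding_is_additive_and_content_free(self, tiny_model):
        rng = np.random.default_rng(1)
        b1 = Tensor(rng.normal(size=(1, 9, 16)))
        b2 = Tensor(rng.normal(size=(1, 9, 16)))
        e1 = tiny_model.add_positional_encoding(b1).data - b1.data
        e2 = tiny_model.add_positional_encoding(b2).data - b2.data
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_refiner_preserves_shape_and_handles_length_one(self, tiny_model):
        one = Tensor(np.random.default_rng(0).normal(size=(1, 1, 16)))
        out = tiny_model.refine_stream(one, "atchley")
        assert out.shape == (1, 1, 16)

    def test_fusion_concatenation_and_slicing(self, tiny_model):
        rng = np.random.default_rng(2)
        p = Tensor(rng.normal(size=(1, 5, 16)))
        a = Tensor(rng.normal(size=(1, 5, 16)))
        b = Tensor(rng.normal(size=(1, 5, 16)))
        fused = tiny_model.fuse_streams(p, a, b)
        assert fused.shape == (1, 5, 48)
        np.testing.assert_array_equal(fused.data[..., :16], p.data)
        np.testing.assert_array_equal(fused.data[..., 16:32], a.data)
        np.testing.assert_array_equal(fused.data[..., 32:], b.data)

    def test_stream_ablation_zeroes_at_fusion(self, tiny_config):
        from dataclasses import replace

        model = FusionModel(replace(tiny_config, streams=("plm",)), seed=0)
        rng = np.random.default_rng(3)
        p = Tensor(rng.normal(size=(1, 4, 16)))
        a = Tensor(rng.normal(size=(1, 4, 16)))
        b = Tensor(rng.normal(size=(1, 4, 16)))
        fused = model.fuse_streams(p, a, b)
        np.testing.assert_array_equal(fused.data[..., :16], p.data)
        assert not fused.data[..., 16:].any()


class TestBackboneAndHeads:
    def test_eval_forward_is_deterministic(self, tiny_model, forward_args):
        out1 = tiny_model.forward(*forward_args)[1].data
        out2 = tiny_model.forward(*forward_args)[1].data
        np.testing.assert_array_equal(out1, out2)

    def test_zero_layers_backbone_is_identity(self, tiny_config):
        from dataclasses import replace

        model = FusionModel(replace(tiny_config, backbone_layers=0), seed=0)
        x = Tensor(np.random.default_rng(0).normal(size=(1, 6, 48)))
        mask = np.ones((1, 6))
        np.testing.assert_array_equal(model.backbone_forward(x, mask).data, x.data)

    def test_all_masked_input_rejected(self, tiny_model):
        x = Tensor(np.zeros((1, 4, 48)))
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(x, np.zeros((1, 4)))

    def test_residue_head_shape_and_shift_invariance(self, tiny_model, forward_args):
        _, logits, _ = tiny_model.forward(*forward_args)
        assert logits.shape[-1] == 2
        probs = logits.softmax(axis=-1).data
        shifted = (logits + Tensor(np.full(logits.shape, 3.7))).softmax(axis=-1).data
        np.testing.assert_allclose(probs, shifted, atol=1e-12)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_protein_head_pooling_identities(self, tiny_model):
        from nabind.nn import masked_mean_pool

        row = np.random.default_rng(0).normal(size=48)
        constant = Tensor(np.tile(row, (1, 5, 1)))
        pooled = masked_mean_pool(constant, np.ones((1, 5)))
        np.testing.assert_allclose(pooled.data[0], row, atol=1e-12)
        single = masked_mean_pool(Tensor(row[None, None, :]), np.ones((1, 1)))
        np.testing.assert_allclose(single.data[0], row, atol=1e-12)

    def test_padding_never_leaks_into_real_positions(self, tiny_config, stub16):
        """Appending masked padding leaves logits at real positions unchanged."""
        model = FusionModel(tiny_config, seed=11).set_training(False)
        rec = ProteinRecord("a", "MKRWLAEHGT")
        feats = featurize([rec], stub16)[0]
        batch = pad_batch([feats])
        _, res_logits, prot_logits = model.forward(
            batch["plm"], batch["atchley"], batch["blosum"], batch["mask"]
        )
        pad = 6
        padded = {
            k: np.concatenate([batch[k], np.zeros((1, pad, batch[k].shape[2]))], axis=1)
            for k in ("plm", "atchley", "blosum")
        }
        mask = np.concatenate([batch["mask"], np.zeros((1, pad))], axis=1)
        _, res_p, prot_p = model.forward(
            padded["plm"], padded["atchley"], padded["blosum"], mask
        )
        np.testing.assert_allclose(
            res_p.data[0, :10], res_logits.data[0, :10], rtol=1e-5, atol=1e-8
        )
        np.testing.assert_allclose(prot_p.data, prot_logits.data, rtol=1e-5, atol=1e-8)


class TestPredict:
    def test_probabilities_and_calls(self, tiny_model, stub16, sample_record):
        result = predict(sample_record, tiny_model, stub16)
        assert result.residue_probabilities.shape == (len(sample_record),)
        assert ((result.residue_probabilities >= 0) & (result.residue_probabilities <= 1)).all()
        assert 0.0 <= result.protein_probability <= 1.0

    def test_zero_threshold_calls_everything(self, tiny_model, stub16, sample_record):
        result = predict(sample_record, tiny_model, stub16, threshold=0.0)
        assert result.residue_calls.all()
        assert result.protein_call == 1

    def test_invalid_task_rejected(self, tiny_model, stub16, sample_record):
        with pytest.raises(ValueError):
            predict(sample_record, tiny_model, stub16, task="nonsense")


def test_checkpoint_roundtrip_preserves_outputs(tiny_config, stub16, sample_record, tmp_path):
    model = FusionModel(tiny_config, seed=3).set_training(False)
    before = predict(sample_record, model, stub16).residue_probabilities
    path = save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(path)
    after = predict(sample_record, restored, stub16).residue_probabilities
    np.testing.assert_array_equal(before, after)
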