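"""Architectural contracts of the joint network."""

import dataclasses

import numpy as np
import pytest

from lesionjoint.joint_model import (ClsNet, CrossStitch, JointModel, LGM,
                                     ModelConfig)
from lesionjoint.nn import tensor as T
from lesionjoint.nn.tensor import Tensor
from lesionjoint.objectives import LossWeights
from lesionjoint.workflow import compute_losses


def _rand_input(cfg, n=1, seed=0):
    rng = np.random.default_rng(seed)
    return Tensor(rng.normal(
        size=(n, 1) + cfg.input_size).astype(np.float32))


class TestConfig:
    def test_indivisible_input_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=(24, 24, 24))

    def test_wrong_alpha_or_channel_counts_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(fusion_weights=(1.0, 1.0))
        with pytest.raises(ValueError):
            ModelConfig(cls_channels=(8, 8))

    def test_unknown_variants_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(lgm_variant="bogus")
        with pytest.raises(ValueError):
            ModelConfig(share_variant="bogus")

    def test_json_roundtrip(self, desk_cfg):
        again = ModelConfig.from_json(desk_cfg.to_json())
        assert again == desk_cfg


class TestInfoShare:
    def test_patch_embed_grid_is_sixteenth_of_input(self, tiny_model, desk_cfg):
        out = tiny_model.share.patch_embed(_rand_input(tiny_model.cfg))
        assert out.shape == (1, 4, 1, 1, 1)
        m32 = JointModel(desk_cfg, seed=0)
        out32 = m32.share.patch_embed(_rand_input(desk_cfg))
        assert out32.shape[2:] == (2, 2, 2)

    def test_zero_input_zero_bias_gives_zero_embedding(self, desk_cfg):
        model = JointModel(desk_cfg, seed=0)
        model.share.branch.patch_conv.bias.data[:] = 0
        x = Tensor(np.zeros((1, 1) + desk_cfg.input_size, dtype=np.float32))
        assert np.all(model.share.patch_embed(x).data == 0)

    def test_branches_conformable_at_half_resolution(self, tiny_model):
        x = _rand_input(tiny_model.cfg)
        loc = tiny_model.share.local_branch(x)
        glo = tiny_model.share.global_branch(x)
        assert loc.shape == glo.shape
        assert loc.shape == (1, 4, 8, 8, 8)

    def test_local_zero_input_zero_bias_linearity(self, desk_cfg):
        model = JointModel(desk_cfg, seed=1)
        br = model.share.branch
        # LN of a constant input is degenerate; feed zeros post-norm instead
        h = Tensor(np.zeros((1, 1) + desk_cfg.input_size, dtype=np.float32))
        for conv in (br.local_conv1, br.local_conv2, br.local_conv3):
            conv.bias.data[:] = 0
        out = br.local_conv3(T.relu(br.local_conv2(T.relu(br.local_conv1(h)))))
        assert np.all(out.data == 0)

    def test_global_branch_reduces_to_upsampled_norm_when_attention_silenced(
            self, desk_cfg):
        """With attention projections and MLPs zeroed, the transformer is the
        identity and the global branch equals upsample(LN(patch_embed))."""
        model = JointModel(desk_cfg, seed=2)
        br = model.share.branch
        for blk in br.swin:
            blk.proj.weight.data[:] = 0
            blk.proj.bias.data[:] = 0
            blk.mlp2.weight.data[:] = 0
            blk.mlp2.bias.data[:] = 0
        x = _rand_input(desk_cfg, seed=3)
        expected = T.resize3d(br.embed_norm(br.patch_embed(x)),
                              desk_cfg.half_size, "linear").data
        np.testing.assert_allclose(br.global_branch(x).data, expected,
                                   atol=1e-6)


class TestCrossStitch:
    def test_identity_weights_pass_through_exactly(self):
        cs = CrossStitch()
        rng = np.random.default_rng(4)
        loc = Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32))
        glo = Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32))
        out = cs(loc, glo)
        np.testing.assert_array_equal(out.fseg.data, loc.data)
        np.testing.assert_array_equal(out.fcls.data, glo.data)

    def test_constant_maps_mix_linearly(self):
        cs = CrossStitch()
        cs.w_seg1.data[()] = 0.5
        cs.w_seg2.data[()] = 0.5
        loc = Tensor(np.full((1, 1, 2, 2, 2), 2.0, dtype=np.float32))
        glo = Tensor(np.full((1, 1, 2, 2, 2), 4.0, dtype=np.float32))
        np.testing.assert_allclose(cs(loc, glo).fseg.data, 3.0)

    def test_shape_mismatch_rejected(self):
        cs = CrossStitch()
        with pytest.raises(ValueError):
            cs(Tensor(np.zeros((1, 1, 2, 2, 2))),
               Tensor(np.zeros((1, 1, 4, 4, 4))))


class TestSegNet:
    def test_output_at_input_resolution_with_probabilities(self, tiny_model):
        x = _rand_input(tiny_model.cfg)
        state = tiny_model(x)
        assert state.prob_map.shape == (1, 1) + tiny_model.cfg.input_size
        p = state.prob_map.data
        assert p.min() > 0.0 and p.max() < 1.0

    def test_scale_ladder_strictly_increasing(self, tiny_model):
        state = tiny_model(_rand_input(tiny_model.cfg))
        edges = [m.shape[-1] for m in state.seg_maps.maps]
        assert edges == sorted(edges)
        assert edges == [2, 4, 8]          # L/8, L/4, L/2 for L=16

    def test_zero_logits_give_half_probability(self, tiny_cfg):
        model = JointModel(tiny_cfg, seed=5)
        for head in (model.seg.head1, model.seg.head2, model.seg.head3,
                     model.seg.head4):
            head.weight.data[:] = 0
            head.bias.data[:] = 0
        state = model(_rand_input(tiny_cfg))
        np.testing.assert_allclose(state.prob_map.data, 0.5, atol=1e-6)

    def test_alpha_0001_equals_full_resolution_head_alone(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, fusion_weights=(0, 0, 0, 1.0))
        model = JointModel(cfg, seed=6)
        x = _rand_input(cfg)
        shared = model.share(x)
        prob, _ = model.seg(shared.fseg)
        # recompute the d3 head alone
        seg = model.seg
        e1 = seg.enc1(shared.fseg)
        e2 = seg.enc2(seg.down1(e1))
        e3 = seg.enc3(seg.down2(e2))
        d1 = seg.dec1(T.concat([T.resize3d(e3, (4, 4, 4), "linear"), e2], 1))
        d2 = seg.dec2(T.concat([T.resize3d(d1, (8, 8, 8), "linear"), e1], 1))
        d3 = seg.dec3(T.resize3d(d2, cfg.input_size, "linear"))
        expected = T.sigmoid(seg.head4(d3)).data
        np.testing.assert_allclose(prob.data, expected, atol=1e-6)


class TestLGM:
    def test_full_variant_shapes(self, tiny_model):
        state = tiny_model(_rand_input(tiny_model.cfg))
        # P at 16^3 -> P' at 8^3; J at 4^3 after the stride-2 fusion convs
        assert state.lgm.p_down.shape[2:] == (8, 8, 8)
        assert state.lgm.fused.shape == (1, 4, 4, 4, 4)
        att = state.lgm.attention.data
        assert att.min() > 0.0 and att.max() < 1.0

    def test_attention_identity_forced(self, tiny_cfg):
        model = JointModel(tiny_cfg, seed=7)
        rng = np.random.default_rng(8)
        P = Tensor(rng.random((1, 1) + tiny_cfg.input_size).astype(np.float32))
        D = Tensor(rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        state = model.lgm(P, D)
        forced = T.mul(Tensor(np.ones_like(state.attention.data)), D)
        np.testing.assert_array_equal(forced.data, D.data)

    def test_variant_off_is_bypass(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, lgm_variant="off")
        model = JointModel(cfg, seed=9)
        state = model(_rand_input(cfg))
        np.testing.assert_array_equal(state.lgm.fused.data,
                                      state.shared.fcls.data)

    @pytest.mark.parametrize("variant,expect_half", [
        ("dot_product", False), ("concat", False), ("dot_add", True)])
    def test_other_variants_run_and_produce_expected_grids(self, tiny_cfg,
                                                           variant,
                                                           expect_half):
        cfg = dataclasses.replace(tiny_cfg, lgm_variant=variant)
        model = JointModel(cfg, seed=10)
        state = model(_rand_input(cfg))
        edge = state.lgm.fused.shape[-1]
        assert edge == (8 if expect_half else 4)
        assert state.cls.probs.shape == (1, 2)


class TestClsNet:
    def test_probabilities_on_simplex(self, tiny_model):
        state = tiny_model(_rand_input(tiny_model.cfg, n=2, seed=12))
        s = state.cls.probs.data.sum(axis=1)
        np.testing.assert_allclose(s, 1.0, atol=1e-6)

    def test_full_scale_channel_concatenation_length(self):
        """64+128+256 pooled features enter the final fully connected layer."""
        rng = np.random.default_rng(13)
        cfg = ModelConfig.desk(cls_channels=(64, 128, 256))
        net = ClsNet(cfg, rng=rng)
        J = Tensor(rng.normal(size=(1, 8, 8, 8, 8)).astype(np.float32))
        state = net(J)
        assert sum(g.shape[1] for g in state.gap_vectors) == 448
        assert state.fc_weights.shape == (448, 2)

    def test_zero_input_zero_bias_gives_uniform_prediction(self, tiny_cfg):
        model = JointModel(tiny_cfg, seed=14)
        J = Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32))
        state = model.cls(J)
        np.testing.assert_allclose(state.probs.data, 0.5, atol=1e-6)


class TestJointForward:
    def test_dual_has_strictly_more_parameters_than_only_local(self, tiny_cfg):
        dual = JointModel(tiny_cfg, seed=15)
        local = JointModel(dataclasses.replace(tiny_cfg,
                                               share_variant="only_local"),
                           seed=15)
        assert dual.num_parameters() > local.num_parameters()

    def test_share_off_duplicates_the_extractor(self, tiny_cfg):
        off = JointModel(dataclasses.replace(tiny_cfg, share_variant="off"),
                         seed=16)
        dual = JointModel(tiny_cfg, seed=16)
        assert off.num_parameters() > dual.num_parameters()

    @pytest.mark.parametrize("variant", ["only_local", "only_global", "off"])
    def test_share_variants_forward(self, tiny_cfg, variant):
        cfg = dataclasses.replace(tiny_cfg, share_variant=variant)
        model = JointModel(cfg, seed=17)
        state = model(_rand_input(cfg))
        assert state.prob_map.shape[2:] == cfg.input_size
        assert state.cls.probs.shape == (1, 2)
        if variant in ("only_local", "only_global"):
            np.testing.assert_array_equal(state.shared.fseg.data,
                                          state.shared.fcls.data)

    def test_every_parameter_receives_gradient(self, tiny_cfg):
        """No dead branches: the total loss touches every learnable."""
        model = JointModel(tiny_cfg, seed=18)
        rng = np.random.default_rng(19)
        vols = rng.normal(size=(2, 1) + tiny_cfg.input_size).astype(np.float32)
        masks = (rng.random((2, 1) + tiny_cfg.input_size) < 0.1).astype(np.float32)
        labels = np.array([0.0, 1.0])
        loss, *_ = compute_losses(model, vols, masks, labels, LossWeights())
        model.zero_grad()
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []

    def test_classification_loss_reaches_seg_head_only_through_lgm(
            self, tiny_cfg):
        """With LGM off and the cross-task loss disabled, the classification
        loss must not touch segmentation-head parameters."""
        cfg = dataclasses.replace(tiny_cfg, lgm_variant="off")
        model = JointModel(cfg, seed=20)
        rng = np.random.default_rng(21)
        x = Tensor(rng.normal(size=(1, 1) + cfg.input_size).astype(np.float32))
        state = model(x)
        from lesionjoint.objectives import bce_loss
        l_cls = bce_loss(state.cls.probs[:, 1], np.array([1.0]))
        model.zero_grad()
        l_cls.backward()
        seg_grads = [p.grad for n, p in model.named_parameters()
                     if n.startswith("seg.")]
        assert all(g is None or np.all(g == 0) for g in seg_grads)
        # and with the full LGM the path exists
        model2 = JointModel(tiny_cfg, seed=20)
        state2 = model2(x)
        l_cls2 = bce_loss(state2.cls.probs[:, 1], np.array([1.0]))
        model2.zero_grad()
        l_cls2.backward()
        touched = [n for n, p in model2.named_parameters()
                   if n.startswith("seg.") and p.grad is not None
                   and np.any(p.grad != 0)]
        assert touched

    def test_inference_is_deterministic(self, tiny_model, phantom_cases):
        case = phantom_cases[0]
        vol = case.volume[::2, ::2, ::2].astype(np.float32)  # 16^3
        p1, m1, c1 = tiny_model.predict(vol)
        p2, m2, c2 = tiny_model.predict(vol)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(c1, c2)

    def test_wrong_input_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model(Tensor(np.zeros((1, 1, 32, 32, 32), dtype=np.float32)))


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    again = JointModel.load(path)
    assert again.cfg == tiny_model.cfg
    x = _rand_input(tiny_model.cfg, seed=22)
    np.testing.assert_array_equal(tiny_model(x).prob_map.data,
                                  again(x).prob_map.data)
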