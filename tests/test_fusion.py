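"""Contrastive alignment, the two-phase fusion and the full forward pass."""

import numpy as np
import pytest

import cmmfnet as cm
from cmmfnet._tensor import Tensor
from cmmfnet.fusion import INIT_LOG_SCALE, ChannelAttention, dff_phase1
from cmmfnet.nn import TransformerBlock

from test_nn import zero_output_projections


# --------------------------------------------------------------------------
# normalization and similarity
# --------------------------------------------------------------------------

def test_l2_normalize_examples(rng):
    np.testing.assert_allclose(cm.l2_normalize(np.array([[3.0, 4.0]])).data,
                               [[0.6, 0.8]])
    unit = np.array([[1.0, 0.0, 0.0]])
    np.testing.assert_allclose(cm.l2_normalize(unit).data, unit)
    vecs = rng.normal(size=(1000, 8))
    norms = np.linalg.norm(cm.l2_normalize(vecs).data, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-6)
    with pytest.raises(ValueError):
        cm.l2_normalize(np.zeros((1, 4)))


def test_similarity_logits_temperature_and_cosines():
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    logits = cm.similarity_logits(z, z).data
    assert logits[0, 0] == pytest.approx(1.0 / 0.07)
    assert logits[0, 1] == pytest.approx(0.0, abs=1e-12)
    anti = cm.similarity_logits(z[:1], -z[:1]).data
    assert anti[0, 0] == pytest.approx(-np.exp(INIT_LOG_SCALE))


def test_similarity_logits_bounded_by_temperature(rng):
    z_a = cm.l2_normalize(rng.normal(size=(20, 8))).data
    z_b = cm.l2_normalize(rng.normal(size=(20, 8))).data
    logits = cm.similarity_logits(z_a, z_b).data
    assert np.all(np.abs(logits) <= np.exp(INIT_LOG_SCALE) + 1e-6)


def test_similarity_logits_validation(rng):
    with pytest.raises(ValueError):
        cm.similarity_logits(np.ones((2, 3)), np.ones((2, 4)))
    with pytest.raises(ValueError):
        cm.similarity_logits(2 * np.ones((1, 4)), np.ones((1, 4)))


# --------------------------------------------------------------------------
# phase 1
# --------------------------------------------------------------------------

def test_phase1_with_zeroed_projections_is_layernorm(rng):
    blocks = [TransformerBlock(8, 2, rng) for _ in range(2)]
    for b in blocks:
        zero_output_projections(b)
    F = Tensor(rng.normal(size=(3, 3, 8)))
    out = dff_phase1(F, blocks, norm="layernorm").data
    centered = F.data - F.data.mean(-1, keepdims=True)
    expected = centered / np.sqrt(centered.var(-1, keepdims=True) + 1e-5)
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_phase1_output_tokens_are_standardized(rng):
    blocks = [TransformerBlock(8, 2, rng)]
    out = dff_phase1(Tensor(rng.normal(size=(4, 3, 8))), blocks).data
    np.testing.assert_allclose(out.mean(-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.var(-1), 1.0, atol=1e-3)


def test_phase1_l2_option_and_empty_stack_error(rng):
    blocks = [TransformerBlock(8, 2, rng)]
    out = dff_phase1(Tensor(rng.normal(size=(2, 3, 8))), blocks, norm="l2")
    np.testing.assert_allclose(np.linalg.norm(out.data, axis=-1), 1.0,
                               atol=1e-6)
    with pytest.raises(ValueError):
        dff_phase1(Tensor(np.zeros((1, 3, 8))), [])
    with pytest.raises(ValueError):
        cm.ModelConfig(embed_dim=8, n_heads=2, dff_layers=0, ehr_len=4)


# --------------------------------------------------------------------------
# phase 2: channel attention
# --------------------------------------------------------------------------

def test_channel_attention_identity_at_zero_weights(rng):
    ca = ChannelAttention(3, 1, rng)
    ca.w1.weight.data[:] = 0.0
    ca.w2.weight.data[:] = 0.0
    F = Tensor(rng.normal(size=(4, 3, 8)))
    np.testing.assert_array_equal(ca(F).data, F.data)  # sigma(0)+sigma(0)=1


def test_channel_attention_constant_rows_equal_gates(rng):
    ca = ChannelAttention(3, 1, rng)
    F = Tensor(np.tile(np.array([1.5, -0.2, 0.7])[None, :, None], (2, 1, 8)))
    g_ap = ca.gate(F.mean(axis=-1)).data
    g_mp = ca.gate(F.max(axis=-1)).data
    np.testing.assert_allclose(g_ap, g_mp, atol=1e-12)


def test_channel_attention_multipliers_inside_open_interval(rng):
    ca = ChannelAttention(3, 1, rng)
    for _ in range(20):
        F = Tensor(rng.normal(scale=5.0, size=(3, 3, 16)))
        mult = (ca.gate(F.mean(axis=-1)) + ca.gate(F.max(axis=-1))).data
        assert np.all(mult > 0.0) and np.all(mult < 2.0)


def test_channel_attention_reduction_ratio_must_divide(rng):
    with pytest.raises(ValueError):
        ChannelAttention(3, 2, rng)


# --------------------------------------------------------------------------
# classification head and full model
# --------------------------------------------------------------------------

def test_classify_zero_weights_yields_bias_row(rng):
    from cmmfnet.fusion import classify
    from cmmfnet.nn import Linear

    head = Linear(3 * 8, 3, rng)
    head.weight.data[:] = 0.0
    head.bias.data[:] = [0.3, -1.0, 2.0]
    logits = classify(Tensor(rng.normal(size=(5, 3, 8))), head).data
    np.testing.assert_allclose(logits, np.tile([0.3, -1.0, 2.0], (5, 1)))


def test_classify_is_affine(rng):
    from cmmfnet.fusion import classify
    from cmmfnet.nn import Linear

    head = Linear(3 * 8, 3, rng)
    F = rng.normal(size=(2, 3, 8))
    G = rng.normal(size=(2, 3, 8))
    lhs = classify(Tensor(F + G), head).data - classify(Tensor(G), head).data
    rhs = classify(Tensor(F), head).data - classify(Tensor(np.zeros_like(F)),
                                                    head).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def _forward_batch(rng, cfg, n=4):
    crop_s, crop_l = cfg.crop_small, cfg.crop_large
    return {
        "roi_small": rng.random((n, *crop_s)),
        "roi_large": rng.random((n, *crop_l)),
        "bbox_small": rng.uniform(0.2, 0.8, size=(n, 6)),
        "bbox_large": rng.uniform(0.2, 0.8, size=(n, 6)),
        "ehr": rng.normal(size=(n, cfg.ehr_len)),
        "labels": rng.integers(0, 3, size=n),
    }


def test_model_forward_shapes(rng):
    cfg = cm.tiny_model_config(ehr_len=5)
    model = cm.CMMFNet(cfg, rng)
    out = model.forward(_forward_batch(np.random.default_rng(1), cfg))
    assert out.logits.shape == (4, 3)
    assert out.l1.shape == (4, 4) and out.l2.shape == (4, 4)
    assert out.fused.shape == (4, 3, 64)
    np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-9)


def test_duplicated_sample_duplicates_its_logits_row(rng):
    """The classification path has no cross-sample coupling."""
    cfg = cm.tiny_model_config(ehr_len=5)
    model = cm.CMMFNet(cfg, rng)
    batch = _forward_batch(np.random.default_rng(2), cfg, n=3)
    dup = {k: (np.concatenate([v, v[1:2]]) if v.ndim else v)
           for k, v in batch.items()}
    out = model.forward(dup)
    np.testing.assert_allclose(out.logits.data[3], out.logits.data[1],
                               atol=1e-12)


def test_forward_is_deterministic(rng):
    cfg = cm.tiny_model_config(ehr_len=5)
    model = cm.CMMFNet(cfg, rng)
    batch = _forward_batch(np.random.default_rng(3), cfg)
    a = model.forward(batch).logits.data
    b = model.forward(batch).logits.data
    np.testing.assert_array_equal(a, b)


def test_ablation_modality_subsets_forward(rng):
    """Every ablation configuration (single modality, dual CT, no fusion
    head) produces well-formed logits."""
    variants = [("small",), ("large",), ("clinical",), ("small", "large")]
    for mods in variants:
        cfg = cm.tiny_model_config(ehr_len=5, modalities=mods,
                                   reduction_ratio=1)
        model = cm.CMMFNet(cfg, np.random.default_rng(0))
        out = model.forward(_forward_batch(np.random.default_rng(4), cfg))
        assert out.logits.shape == (4, 3)
        if "clinical" not in mods:
            assert out.l1 is None and out.l2 is None
    cfg = cm.tiny_model_config(ehr_len=5, use_dff=False)
    out = cm.CMMFNet(cfg, np.random.default_rng(0)).forward(
        _forward_batch(np.random.default_rng(5), cfg))
    assert out.logits.shape == (4, 3)


def test_gradients_reach_every_parameter_group(rng):
    """A combined loss on a random batch sends a nonzero gradient into
    every named parameter tensor."""
    cfg = cm.tiny_model_config(ehr_len=5)
    model = cm.CMMFNet(cfg, rng)
    batch = _forward_batch(np.random.default_rng(6), cfg)
    out = model.forward(batch)
    bundle = cm.total_loss(cm.clip_contrastive_loss(out.l1),
                           cm.clip_contrastive_loss(out.l2),
                           cm.focal_loss(out.logits, batch["labels"]))
    bundle._total_tensor.backward()
    for name, p in model.named_parameters().items():
        assert p.grad is not None and np.any(p.grad != 0), name


def test_loss_gradient_matches_finite_difference(rng):
    """Spot-check backprop through the full model against central
    differences on three scattered parameters."""
    cfg = cm.tiny_model_config(ehr_len=5, embed_dim=16, depth=1, n_heads=2,
                               crop_small=(8, 8, 8), crop_large=(16, 16, 8))
    model = cm.CMMFNet(cfg, rng)
    batch = _forward_batch(np.random.default_rng(7), cfg, n=3)

    out = model.forward(batch)
    bundle = cm.total_loss(cm.clip_contrastive_loss(out.l1),
                           cm.clip_contrastive_loss(out.l2),
                           cm.focal_loss(out.logits, batch["labels"]))
    omega0 = bundle.omega  # omega is detached: hold it fixed for the check

    def loss_value():
        o = model.forward(batch)
        sc = float(cm.clip_contrastive_loss(o.l1).data)
        lc = float(cm.clip_contrastive_loss(o.l2).data)
        fo = float(cm.focal_loss(o.logits, batch["labels"]).data)
        return omega0 * (sc + lc) + (1.0 - omega0) * fo

    model.zero_grad()
    bundle._total_tensor.backward()
    params = model.named_parameters()
    eps = 1e-5
    for name in ["head.weight", "cle.embed", "cte_small.patch_proj.weight"]:
        p = params[name]
        idx = tuple(np.random.default_rng(8).integers(0, s)
                    for s in p.data.shape)
        analytic = p.grad[idx]
        old = p.data[idx]
        p.data[idx] = old + eps
        up = loss_value()
        p.data[idx] = old - eps
        down = loss_value()
        p.data[idx] = old
        assert (up - down) / (2 * eps) == pytest.approx(analytic, rel=1e-3,
                                                        abs=1e-7)


def test_share_cte_reuses_transformer_weights(rng):
    cfg = cm.tiny_model_config(ehr_len=5, share_cte=True)
    model = cm.CMMFNet(cfg, rng)
    assert model.cte_small.blocks is model.cte_large.blocks
    assert model.cte_small.pos is not model.cte_large.pos
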