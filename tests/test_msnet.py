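"""Attention contracts, loss closed forms, weight sharing, parameter counts."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from rfbispec.msnet import (
    MSNet,
    NetConfig,
    attention_loss,
    cosine_similarity,
    count_parameters,
    gated_attention,
    shared_ratio,
    sm_loss,
    total_loss,
    _sm_loss_tensor,
)
from rfbispec.nn.autograd import Tensor
from rfbispec.nn.backbones import feature_param_count

TINY = NetConfig(backbone="tinycnn")


def _att_params(rng, L=5, M=6):
    return (
        rng.standard_normal((L, M)),
        rng.standard_normal((L, M)),
        rng.standard_normal(L),
    )


class TestGatedAttention:
    def test_single_instance_identity(self, rng):
        V, U, w = _att_params(rng)
        h = rng.standard_normal((1, 6))
        out = gated_attention(h, V, U, w)
        assert out.a_k.tolist() == [1.0]
        assert np.allclose(out.z_dl, h[0])

    def test_identical_instances_uniform_weights(self, rng):
        V, U, w = _att_params(rng)
        h = np.tile(rng.standard_normal(6), (4, 1))
        out = gated_attention(h, V, U, w)
        assert np.allclose(out.a_k, 0.25)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), K=st.integers(1, 8))
    def test_simplex_property(self, seed, K):
        """Attention weights are strictly positive and sum to one."""
        r = np.random.default_rng(seed)
        V, U, w = _att_params(r)
        h = r.standard_normal((K, 6))
        out = gated_attention(h, V, U, w)
        assert np.all(out.a_k > 0)
        assert out.a_k.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(out.z_dl, out.a_k @ h)

    def test_permutation_equivariance(self, rng):
        V, U, w = _att_params(rng)
        h = rng.standard_normal((4, 6))
        perm = [2, 0, 3, 1]
        out = gated_attention(h, V, U, w)
        out_p = gated_attention(h[perm], V, U, w)
        assert np.allclose(out_p.a_k, out.a_k[perm])
        assert np.allclose(out_p.z_dl, out.z_dl, atol=1e-12)

    def test_shape_validation(self, rng):
        V, U, w = _att_params(rng)
        with pytest.raises(ValueError):
            gated_attention(rng.standard_normal((4, 7)), V, U, w)


class TestAttentionLoss:
    def test_perfect_prediction_near_zero(self):
        assert attention_loss([1 - 1e-7], [1]) == pytest.approx(0.0, abs=1e-5)

    def test_coin_flip_is_ln2(self):
        assert attention_loss([0.5], [1]) == pytest.approx(np.log(2))

    def test_nonnegative_and_clamped(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        assert attention_loss(p, y) >= 0
        assert np.isfinite(attention_loss([0.0, 1.0], [0, 1]))

    def test_negative_convention_flag(self):
        assert attention_loss([0.3], [1], negative_convention=True) == (
            pytest.approx(attention_loss([0.7], [1]))
        )


class TestCosine:
    def test_basic_identities(self, rng):
        f = rng.standard_normal(8)
        assert cosine_similarity(f, f) == pytest.approx(1.0)
        assert cosine_similarity(f, -f) == pytest.approx(-1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(4), np.ones(4))


class TestSMLoss:
    def test_identical_embeddings_closed_form(self, rng):
        K, nper = 4, 3
        f = np.tile(rng.standard_normal(8), (K * nper, 1))
        types = np.repeat(np.arange(K), nper)
        n = K * nper
        expect = -n * np.log(1 / K) - n * (K - 1) * np.log(1 - 1 / K)
        assert sm_loss(f, types, tau=0.1) == pytest.approx(expect)

    def test_prototypes_beat_label_permutation(self):
        """Well-separated per-type clusters score lower than the same
        embeddings with shuffled type labels."""
        rng = np.random.default_rng(0)
        K, nper, M = 4, 6, 16
        protos = np.eye(M)[:K]
        f = np.repeat(protos, nper, axis=0) + 0.05 * rng.standard_normal(
            (K * nper, M)
        )
        types = np.repeat(np.arange(K), nper)
        permuted = rng.permutation(types)
        assert sm_loss(f, types, tau=0.1) < sm_loss(f, permuted, tau=0.1)

    def test_nonnegative(self, rng):
        f = rng.standard_normal((12, 8))
        types = np.tile(np.arange(4), 3)
        assert sm_loss(f, types) >= 0

    def test_single_type_rejected(self, rng):
        with pytest.raises(ValueError):
            sm_loss(rng.standard_normal((4, 8)), np.zeros(4))

    def test_tensor_path_matches_numpy(self, rng):
        """The differentiable training-path SM loss agrees with the
        reference numpy implementation."""
        B, K, M = 5, 4, 8
        f = rng.standard_normal((B, K, M)).astype(np.float32)
        t_val = float(
            _sm_loss_tensor(Tensor(f).l2_normalize(axis=-1), 0.1).data
        )
        np_val = sm_loss(f.reshape(-1, M), np.tile(np.arange(K), B), tau=0.1)
        assert t_val == pytest.approx(np_val, rel=1e-4)


class TestTotalLoss:
    def test_lambda_zero(self):
        rep = total_loss(0.4, 5.0, replace(TINY, lambda_sm=0.0))
        assert rep.total == pytest.approx(0.4)

    def test_weighted_sum(self):
        rep = total_loss(0.5, 2.0, replace(TINY, lambda_sm=0.1))
        assert rep.total == pytest.approx(0.7)

    def test_sm_disabled(self):
        rep = total_loss(0.5, 2.0, replace(TINY, use_sm=False))
        assert rep.total == pytest.approx(0.5)
        assert rep.loss_sm == 0.0


@pytest.fixture(scope="module")
def model():
    return MSNet(TINY, seed=0)


class TestModel:

    def test_backbone_feature_shapes(self, model, rng):
        x = Tensor(rng.standard_normal((2, 4, 3, 32, 32)).astype(np.float32))
        H = model.backbone_features(x)
        assert H.shape == (2, 4, 128)

    def test_weight_sharing_identical_branches(self, model, rng):
        """The same image on two branches yields the same feature vector."""
        img = rng.standard_normal((3, 32, 32)).astype(np.float32)
        x = np.stack([img] * 4)[None]
        H = model.backbone_features(Tensor(x))
        assert np.allclose(H.data[0, 0], H.data[0, 1])
        assert np.allclose(H.data[0, 0], H.data[0, 3])

    def test_forward_contract(self, model, rng):
        x = rng.standard_normal((4, 3, 32, 32)).astype(np.float32)
        p, att = model.forward(x)
        assert 0 < p < 1
        assert att.a_k.sum() == pytest.approx(1.0, abs=1e-6)
        p2, att2 = model.forward(x)
        assert p == p2
        assert np.array_equal(att.a_k, att2.a_k)

    def test_no_fatt_uses_uniform_mean(self, rng):
        m = MSNet(replace(TINY, use_fatt=False), seed=0)
        x = rng.standard_normal((4, 3, 32, 32)).astype(np.float32)
        _, att = m.forward(x)
        assert np.allclose(att.a_k, 0.25)

    def test_unshared_model_differs_per_branch(self, rng):
        m = MSNet(replace(TINY, share_weights=False), seed=0)
        img = rng.standard_normal((3, 32, 32)).astype(np.float32)
        x = np.stack([img] * 4)[None]
        H = m.backbone_features(Tensor(x))
        assert not np.allclose(H.data[0, 0], H.data[0, 1])

    def test_non_runnable_backbone_raises(self):
        with pytest.raises(NotImplementedError):
            MSNet(NetConfig(backbone="resnet50"))


class TestParameterAccounting:
    def test_linear_head_worked_example(self):
        # a lone M=2048 -> 2 linear map with bias
        cfg = NetConfig(backbone="resnet50", use_fatt=False)
        head_only = count_parameters(cfg) - feature_param_count("resnet50")
        assert head_only == 2048 * 2 + 2 == 4098

    def test_resnet50_feature_extractor_count(self):
        """Sum over the standard 50-layer bottleneck architecture."""
        assert feature_param_count("resnet50") == 23_508_032

    def test_shared_ratio_for_resnet50(self):
        assert round(shared_ratio(NetConfig(backbone="resnet50")), 2) == 25.83

    def test_sharing_difference_identity(self):
        for backbone in ("tinycnn", "resnet50", "vgg19", "resnet101"):
            cfg = NetConfig(backbone=backbone)
            diff = count_parameters(
                replace(cfg, share_weights=False)
            ) - count_parameters(cfg)
            assert diff == (cfg.K - 1) * feature_param_count(backbone)

    def test_model_matches_analytic_count(self):
        m = MSNet(TINY, seed=0)
        assert m.n_params() == count_parameters(TINY)
        m4 = MSNet(replace(TINY, share_weights=False), seed=0)
        assert m4.n_params() == count_parameters(
            replace(TINY, share_weights=False)
        )

    def test_zoo_only_backbones_raise(self):
        with pytest.raises(NotImplementedError):
            count_parameters(NetConfig(backbone="swin"))
        with pytest.raises(ValueError):
            count_parameters(NetConfig(backbone="nosuch"))
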