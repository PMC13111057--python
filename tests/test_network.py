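import numpy as np
import pytest

from bcstgcn import autodiff as ad
from bcstgcn.autodiff import Tensor
from bcstgcn.network import (BCSTGCN, LayerSpec, ModelConfig, STGCNUnit,
                             build_backbone, count_flops, count_parameters,
                             default_config, dense_flops, load_checkpoint,
                             prune_layers, save_checkpoint)
from bcstgcn.skeleton import KeypointScheme, build_adjacency


def tiny_config(**kw):
    kw.setdefault("channels", (4, 8))
    kw.setdefault("stride_layers", (2,))
    kw.setdefault("dropout", 0.0)
    return default_config(**kw)


class TestAutodiff:
    def test_finite_difference_gradients_on_full_model(self):
        """Backprop through BN, attention, both convs and the head agrees
        with central finite differences."""
        model = BCSTGCN(default_config(channels=(4,), stride_layers=(),
                                       dropout=0.0, seed=3))
        model.set_training(True)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 3, 8, 17))
        y = np.array([0, 1, 2])

        def loss_value():
            return ad.cross_entropy(model.forward(X), y)

        loss = loss_value()
        model.zero_grad()
        loss.backward()
        checked = 0
        for name, p in model.named_parameters():
            idx = np.unravel_index(rng.integers(0, p.size), p.data.shape)
            eps = 1e-5
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_value().data)
            p.data[idx] = orig - eps
            lm = float(loss_value().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            bp = p.grad[idx]
            assert abs(fd - bp) <= 1e-3 * max(1.0, abs(fd)), \
                f"{name}: fd={fd}, backprop={bp}"
            checked += 1
        assert checked > 10

    def test_broadcast_gradients_unreduce_correctly(self):
        a = Tensor(np.ones((3, 1)), requires_grad=True)
        b = Tensor(np.ones((1, 4)), requires_grad=True)
        out = ad.reduce_sum(ad.mul(a + b, a))
        out.backward()
        assert a.grad.shape == (3, 1)
        assert b.grad.shape == (1, 4)
        # d/da_i sum_ij (a_i^2 + a_i b_j) = 4(2a_i) + sum_j b_j = 12 at a=b=1
        assert np.allclose(a.grad, 12.0)
        assert np.allclose(b.grad, 3.0)


class TestSTGCNUnit:
    def test_identity_configured_unit_doubles_positive_input(self):
        """With identity weights on an edgeless single-joint graph, no BN and
        identity residual, the unit outputs main + residual = 2x."""
        scheme = KeypointScheme(names=("solo",), edges=())
        adj = build_adjacency(scheme, "uniform")
        spec = LayerSpec(in_channels=2, out_channels=2, dropout=0.0,
                         use_bc=False, use_bn=False)
        rng = np.random.default_rng(0)
        unit = STGCNUnit(spec, adj, rng, temporal_kernel=9,
                         c_lambda=0.0, leaky_slope=0.2)
        unit.gcn.weights[0].data = np.eye(2)
        unit.gcn.bias.data = np.zeros(2)
        unit.tcn_weight.data = np.zeros((2, 2, 9))
        unit.tcn_weight.data[:, :, 4] = np.eye(2)
        unit.tcn_bias.data = np.zeros(2)
        x = np.abs(rng.normal(size=(2, 2, 10, 1))) + 0.1
        out = unit.forward(Tensor(x))
        assert np.allclose(out.data, 2 * x, atol=1e-12)

    @pytest.mark.parametrize("T,expected", [(150, 75), (75, 38), (10, 5)])
    def test_stride_two_halves_frames_with_ceil(self, adj, T, expected):
        spec = LayerSpec(in_channels=3, out_channels=4, temporal_stride=2,
                         dropout=0.0, use_bc=False)
        unit = STGCNUnit(spec, adj, np.random.default_rng(0), 9, 0.0, 0.2)
        out = unit.forward(Tensor(np.random.default_rng(1).normal(
            size=(2, 3, T, 17))))
        assert out.shape == (2, 4, expected, 17)

    def test_unit_matches_straight_line_dense_oracle(self, adj):
        """Eval-mode unit forward replicated step by step with plain numpy."""
        spec = LayerSpec(in_channels=2, out_channels=3, dropout=0.0,
                         use_bc=False, use_bn=False)
        rng = np.random.default_rng(5)
        unit = STGCNUnit(spec, adj, rng, temporal_kernel=3, c_lambda=0.0,
                         leaky_slope=0.2)
        unit.set_training(False)
        x = np.random.default_rng(6).normal(size=(1, 2, 6, 17))
        out = unit.forward(Tensor(x)).data

        # oracle: spatial conv
        y = np.zeros((1, 3, 6, 17))
        for k in range(adj.K):
            mix = adj.A_norm[k] * unit.gcn.edge_importance[k].data
            for t in range(6):
                y[0, :, t, :] += unit.gcn.weights[k].data @ (x[0, :, t, :] @ mix)
        y += unit.gcn.bias.data[None, :, None, None]
        y = np.maximum(y, 0)
        # temporal conv, kernel 3, pad 1
        yp = np.pad(y, ((0, 0), (0, 0), (1, 1), (0, 0)))
        z = np.zeros_like(y)
        for t in range(6):
            for tap in range(3):
                z[0, :, t, :] += np.einsum(
                    "oc,cv->ov", unit.tcn_weight.data[:, :, tap],
                    yp[0, :, t + tap, :])
        z += unit.tcn_bias.data[None, :, None, None]
        # residual projection (1x1 conv) and final relu
        res = np.einsum("oc,nctv->notv", unit.res_weight.data[:, :, 0], x)
        res += unit.res_bias.data[None, :, None, None]
        expected = np.maximum(z + res, 0)
        assert np.allclose(out, expected, atol=1e-5)


class TestBackbone:
    def test_default_stack_maps_to_four_logits(self):
        model = BCSTGCN(default_config())
        X = np.random.default_rng(0).normal(size=(2, 3, 20, 17))
        logits = model.predict_logits(X)
        assert logits.shape == (2, 4)
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_eval_forward_is_deterministic(self):
        model = BCSTGCN(tiny_config(seed=1))
        X = np.random.default_rng(2).normal(size=(3, 3, 12, 17))
        assert np.array_equal(model.predict_logits(X), model.predict_logits(X))

    def test_single_unit_model_equals_manual_composition(self):
        cfg = ModelConfig(layers=(LayerSpec(3, 5, dropout=0.0, use_bc=False),))
        model = BCSTGCN(cfg)
        model.set_training(False)
        X = np.random.default_rng(3).normal(size=(2, 3, 8, 17))
        # manual: data BN -> unit -> GAP -> FC, reusing the model's modules
        N, C, T, V = X.shape
        y = np.transpose(X, (0, 1, 3, 2)).reshape(N, C * V, T)
        y = model.data_bn.forward(Tensor(y)).data
        y = np.transpose(y.reshape(N, C, V, T), (0, 1, 3, 2))
        y = model.units[0].forward(Tensor(y)).data
        pooled = y.mean(axis=(2, 3))
        expected = pooled @ model.fc.weight.data.T + model.fc.bias.data
        assert np.allclose(model.predict_logits(X), expected, atol=1e-10)

    def test_attention_switch_reduces_to_plain_stgcn(self):
        """With B=1, C=0 (attention off) and M=1, the BC network reproduces
        the plain ST-GCN forward pass."""
        plain = BCSTGCN(tiny_config(use_bc=False, seed=4))
        fused = BCSTGCN(tiny_config(use_bc=True, seed=4))
        plain_params = dict(plain.named_parameters())
        for name, p in fused.named_parameters():
            if name in plain_params:
                p.data = plain_params[name].data.copy()
        fused.set_attention_enabled(False)
        X = np.random.default_rng(5).normal(size=(2, 3, 12, 17))
        assert np.allclose(plain.predict_logits(X), fused.predict_logits(X),
                           atol=1e-6)
        fused.set_attention_enabled(True)
        assert not np.allclose(plain.predict_logits(X),
                               fused.predict_logits(X), atol=1e-6)


class TestPruning:
    def test_default_prune_set_leaves_valid_eight_layer_chain(self):
        cfg = default_config()
        pruned = prune_layers(cfg, {7, 9})
        assert len(pruned.layers) == 8
        model = BCSTGCN(pruned)
        X = np.random.default_rng(0).normal(size=(2, 3, 16, 17))
        assert model.predict_logits(X).shape == (2, 4)

    def test_empty_prune_set_is_identity(self):
        cfg = default_config()
        assert prune_layers(cfg, set()) == cfg

    def test_pruning_strictly_reduces_parameters_and_flops(self):
        full = BCSTGCN(default_config())
        pruned = BCSTGCN(prune_layers(default_config(), {7, 9}))
        assert count_parameters(pruned) < count_parameters(full)
        shape = (1, 3, 150, 17)
        assert count_flops(pruned, shape) < count_flops(full, shape)

    def test_stride_layers_cannot_be_pruned(self):
        cfg = default_config(channels=(8, 8, 8), stride_layers=(2,))
        with pytest.raises(ValueError, match="stride"):
            prune_layers(cfg, {2})

    @pytest.mark.parametrize("bad", [{5}, {8}])
    def test_block_transition_layers_cannot_be_pruned(self, bad):
        with pytest.raises(ValueError, match="width"):
            prune_layers(default_config(), bad)

    def test_width_changing_layers_cannot_be_pruned(self):
        with pytest.raises(ValueError, match="width"):
            prune_layers(default_config(stride_layers=()), {5})


class TestAccounting:
    def test_fc_parameter_count(self):
        from bcstgcn.network import Linear
        fc = Linear(256, 4, np.random.default_rng(0))
        assert sum(p.size for p in fc.parameters()) == 256 * 4 + 4

    def test_toy_config_parameter_count_matches_hand_sum(self):
        cfg = ModelConfig(layers=(LayerSpec(3, 4, use_bc=False,
                                            residual=False),))
        model = BCSTGCN(cfg)
        V, K = 17, 3
        expected = (
            2 * 3 * V            # data BN gamma+beta over C*V
            + K * (4 * 3)        # spatial conv weights per partition
            + 4                  # spatial conv bias
            + K * V * V          # edge importance
            + 2 * 4              # bn1
            + 4 * 4 * 9 + 4      # temporal conv
            + 2 * 4              # bn2
            + 4 * 4 + 4          # fc
        )
        assert count_parameters(model) == expected

    def test_dense_flops(self):
        assert dense_flops(17, 1) == 2 * 17

    def test_flops_linear_in_frames_for_stride_one_stack(self):
        model = BCSTGCN(default_config(channels=(8, 8), stride_layers=(),
                                       use_bc=False))
        f1 = count_flops(model, (1, 3, 50, 17))
        f2 = count_flops(model, (1, 3, 100, 17))
        # FC head cost is frame-independent; subtract it before comparing
        head = dense_flops(8, 4)
        assert f2 - head == 2 * (f1 - head)

    def test_toy_flops_match_hand_derived_macs(self):
        cfg = ModelConfig(layers=(LayerSpec(3, 4, use_bc=False,
                                            residual=False),))
        model = BCSTGCN(cfg)
        T, V, K = 10, 17, 3
        macs = K * (3 * T * V * V + 3 * 4 * T * V) + 4 * 4 * 9 * T * V + 4 * 4
        assert count_flops(model, (1, 3, T, V)) == 2 * macs


def test_checkpoint_round_trip(tmp_path):
    model = BCSTGCN(tiny_config(seed=7))
    X = np.random.default_rng(8).normal(size=(2, 3, 10, 17))
    # touch BN running stats so they differ from init
    model.set_training(True)
    model.forward(X)
    before = model.predict_logits(X)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    again = load_checkpoint(path)
    assert np.allclose(again.predict_logits(X), before, atol=1e-12)
    assert count_parameters(again) == count_parameters(model)


def test_build_backbone_wrapper(scheme):
    model = build_backbone(tiny_config(), scheme=scheme)
    assert isinstance(model, BCSTGCN)
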