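"""The BCST-GCN backbone.

Input batch normalization over (C x V), a stack of ST-GCN units (spatial
graph convolution -- plain or attention-fused -- followed by a 9-tap temporal
convolution, residual connection and dropout), global average pooling over
frames and joints, and a fully connected classifier head.

The layer stack is configurable; the default plan uses ten units in three
constant-width blocks (64, 128, 256 channels) with temporal stride 2 at the
block transitions, and supports pruning of width-preserving layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .skeleton import (AdjacencySet, KeypointScheme, build_adjacency,
                       build_pig_scheme)

DEFAULT_CHANNELS = (64, 64, 64, 64, 128, 128, 128, 256, 256, 256)
DEFAULT_STRIDE_LAYERS = (5, 8)       # 1-based layers with temporal stride 2
DEFAULT_PRUNED_LAYERS = (7, 9)       # isomorphic with their predecessors
TEMPORAL_KERNEL = 9
NUM_CLASSES = 4


@dataclass(frozen=True)
class LayerSpec:
    in_channels: int
    out_channels: int
    temporal_stride: int = 1
    residual: bool = True
    dropout: float = 0.5
    use_bc: bool = True
    use_bn: bool = True

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.temporal_stride not in (1, 2):
            raise ValueError("temporal_stride must be 1 or 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    layers: tuple[LayerSpec, ...]
    temporal_kernel: int = TEMPORAL_KERNEL
    num_classes: int = NUM_CLASSES
    partition_strategy: str = "spatial-configuration"
    c_lambda: float | None = None      # None -> 1/V (above-uniform links kept)
    leaky_slope: float = 0.2
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.temporal_kernel % 2 != 1:
            raise ValueError("temporal_kernel must be odd")
        prev = self.in_channels
        for i, spec in enumerate(self.layers, start=1):
            if spec.in_channels != prev:
                raise ValueError(
                    f"layer {i} expects {spec.in_channels} channels, "
                    f"chain provides {prev}")
            prev = spec.out_channels


def default_config(channels=DEFAULT_CHANNELS,
                   stride_layers=DEFAULT_STRIDE_LAYERS,
                   in_channels: int = 3, use_bc: bool = True,
                   dropout: float = 0.5, seed: int = 0,
                   **kwargs) -> ModelConfig:
    """Build a ModelConfig from a channel plan and 1-based stride positions."""
    layers = []
    prev = in_channels
    for i, ch in enumerate(channels, start=1):
        layers.append(LayerSpec(
            in_channels=prev, out_channels=ch,
            temporal_stride=2 if i in stride_layers else 1,
            residual=(i != 1), dropout=dropout, use_bc=use_bc))
        prev = ch
    return ModelConfig(layers=tuple(layers), in_channels=in_channels,
                       seed=seed, **kwargs)


def prune_layers(config: ModelConfig, drop) -> ModelConfig:
    """Remove width-preserving layers (1-based indices) from the stack.

    Only layers with in_channels == out_channels and temporal stride 1 may be
    dropped: they sit inside constant-dimension blocks, so removing them keeps
    the channel chain valid while strictly reducing parameters and FLOPs.
    """
    drop = set(drop)
    for idx in drop:
        if not (1 <= idx <= len(config.layers)):
            raise ValueError(f"layer index {idx} out of range")
        spec = config.layers[idx - 1]
        if spec.in_channels != spec.out_channels:
            raise ValueError(
                f"layer {idx} changes width "
                f"({spec.in_channels}->{spec.out_channels}); refusing to prune "
                "a dimension-changing layer")
        if spec.temporal_stride != 1:
            raise ValueError(
                f"layer {idx} has temporal stride {spec.temporal_stride}; "
                "refusing to prune a striding layer")
    kept = tuple(spec for i, spec in enumerate(config.layers, start=1)
                 if i not in drop)
    return replace(config, layers=kept)


# ---------------------------------------------------------------------------
# modules

class Module:
    """Minimal parameter container with named traversal."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def set_training(self, mode: bool):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(mode)
        return self


def _uniform(rng, shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        self.weight = _uniform(rng, (n_out, n_in), n_in)
        self.bias = _uniform(rng, (n_out,), n_in)

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, ad.transpose(self.weight, (1, 0))) + self.bias


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = tuple(x.shape[1] if i == 1 else 1 for i in range(x.ndim))
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            n = x.size // x.shape[1]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.reshape(-1))
            unbiased = var.reshape(-1) * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            return ad.batch_norm(x, self.gamma, self.beta, self.eps,
                                 mu=mu, var=var)
        mu = Tensor(self.running_mean.reshape(shape))
        var = Tensor(self.running_var.reshape(shape))
        inv = ad.power(var + self.eps, -0.5)
        gamma = ad.reshape(self.gamma, shape)
        beta = ad.reshape(self.beta, shape)
        return ad.mul(ad.mul(x - mu, inv), gamma) + beta


class SpatialGraphConv(Module):
    """Partitioned spatial graph convolution, plain or attention-fused.

    Plain form:  f_out = sum_k W_k (f_in (A_norm_k * M_k))
    BC form:     f_out = sum_k W_k (f_in (A_norm_k * B_k * M_k + C))

    where B_k / C are recomputed each forward pass from the current features
    (averaged over frames) and trained attention parameters, so attention and
    the convolution stack update jointly.
    """

    def __init__(self, spec: LayerSpec, adj: AdjacencySet, rng,
                 c_lambda: float, leaky_slope: float):
        super().__init__()
        self.spec = spec
        self.adj = adj
        self.c_lambda = c_lambda
        self.leaky_slope = leaky_slope
        K, V = adj.K, adj.V
        c_in, c_out = spec.in_channels, spec.out_channels
        self.weights = [_uniform(rng, (c_out, c_in), c_in)
                        for _ in range(K)]
        self.bias = _uniform(rng, (c_out,), c_in)
        # learnable edge importance, initialized to all-ones
        self.edge_importance = [Tensor(np.ones((V, V)), requires_grad=True)
                                for _ in range(K)]
        self.attention_enabled = spec.use_bc
        if spec.use_bc:
            f_prime = c_out
            self.attn_W = _uniform(rng, (c_in, f_prime), c_in)
            self.attn_a = _uniform(rng, (2 * f_prime, 1), 2 * f_prime)
        self._norm = [Tensor(adj.A_norm[k]) for k in range(K)]
        self._masks = [Tensor((adj.A[k] > 0).astype(float)) for k in range(K)]
        self.last_maps: dict | None = None

    def _attention(self, x: Tensor):
        """Shared alpha from frame-averaged features; returns (B_k list, C)."""
        V = self.adj.V
        f_prime = self.attn_W.shape[1]
        h = ad.transpose(ad.reduce_mean(x, axis=2), (0, 2, 1))   # (N, V, C_in)
        Wh = ad.matmul(h, self.attn_W)                           # (N, V, F')
        s_src = ad.matmul(Wh, Tensor._make(
            self.attn_a.data[:f_prime], (self.attn_a,),
            lambda g: (np.concatenate([g, np.zeros((f_prime, 1))]),)))
        s_dst = ad.matmul(Wh, Tensor._make(
            self.attn_a.data[f_prime:], (self.attn_a,),
            lambda g: (np.concatenate([np.zeros((f_prime, 1)), g]),)))
        e = ad.leaky_relu(s_src + ad.transpose(s_dst, (0, 2, 1)),
                          self.leaky_slope)                      # (N, V, V)
        alpha = ad.softmax_rows(e)
        Bs = []
        for k in range(self.adj.K):
            masked = ad.mul(alpha, self._masks[k])
            row = ad.reduce_sum(masked, axis=-1, keepdims=True)
            Bs.append(ad.div(masked, row + 1e-12))
        C = ad.threshold(alpha, self.c_lambda)
        self.last_maps = {
            "alpha": alpha.data,
            "B": np.stack([b.data for b in Bs], axis=1),   # (N, K, V, V)
            "C": C.data,
        }
        return Bs, C

    def forward(self, x: Tensor) -> Tensor:
        N = x.shape[0]
        V = self.adj.V
        use_attn = self.spec.use_bc and self.attention_enabled
        if use_attn:
            Bs, C = self._attention(x)
        mixes = []
        for k in range(self.adj.K):
            if use_attn:
                mix = ad.mul(ad.mul(self._norm[k], Bs[k]),
                             self.edge_importance[k]) + C       # (N, V, V)
                mix = ad.reshape(mix, (N, 1, V, V))
            else:
                mix = ad.mul(self._norm[k], self.edge_importance[k])  # (V, V)
            mixes.append(mix)
        out = ad.graph_conv(x, mixes, self.weights)
        return out + ad.reshape(self.bias, (1, -1, 1, 1))


class STGCNUnit(Module):
    """Spatial graph conv -> 9-tap temporal conv -> residual -> dropout."""

    def __init__(self, spec: LayerSpec, adj: AdjacencySet, rng,
                 temporal_kernel: int, c_lambda: float, leaky_slope: float):
        super().__init__()
        self.spec = spec
        self.kt = temporal_kernel
        self.pad = (temporal_kernel - 1) // 2
        c_in, c_out = spec.in_channels, spec.out_channels
        self.gcn = SpatialGraphConv(spec, adj, rng, c_lambda, leaky_slope)
        self.bn1 = BatchNorm(c_out) if spec.use_bn else None
        self.tcn_weight = _uniform(rng, (c_out, c_out, temporal_kernel),
                                   c_out * temporal_kernel)
        self.tcn_bias = _uniform(rng, (c_out,), c_out * temporal_kernel)
        self.bn2 = BatchNorm(c_out) if spec.use_bn else None
        if not spec.residual:
            self.res_weight = None
        elif c_in == c_out and spec.temporal_stride == 1:
            self.res_weight = "identity"
        else:
            self.res_weight = _uniform(rng, (c_out, c_in, 1), c_in)
            self.res_bias = _uniform(rng, (c_out,), c_in)

    def forward(self, x: Tensor, dropout_rng=None) -> Tensor:
        y = self.gcn.forward(x)
        if self.bn1 is not None:
            y = self.bn1.forward(y)
        y = ad.relu(y)
        y = ad.temporal_conv(y, self.tcn_weight, self.tcn_bias,
                             stride=self.spec.temporal_stride, pad=self.pad)
        if self.bn2 is not None:
            y = self.bn2.forward(y)
        if self.res_weight is None:
            res = None
        elif isinstance(self.res_weight, str):
            res = x
        else:
            res = ad.temporal_conv(x, self.res_weight, self.res_bias,
                                   stride=self.spec.temporal_stride, pad=0)
        y = y if res is None else y + res
        y = ad.relu(y)
        if self.training and self.spec.dropout > 0 and dropout_rng is not None:
            keep = 1.0 - self.spec.dropout
            mask = dropout_rng.random(size=y.shape) < keep
            y = ad.dropout(y, mask, keep)
        return y


class BCSTGCN(Module):
    """Full backbone: data BN -> ST-GCN units -> GAP -> FC logits."""

    def __init__(self, config: ModelConfig,
                 scheme: KeypointScheme | None = None):
        super().__init__()
        self.config = config
        self.scheme = scheme or build_pig_scheme()
        self.adj = build_adjacency(self.scheme, config.partition_strategy)
        V = self.adj.V
        c_lambda = config.c_lambda if config.c_lambda is not None else 1.0 / V
        rng = np.random.default_rng(config.seed)
        self.data_bn = BatchNorm(config.in_channels * V)
        self.units = [STGCNUnit(spec, self.adj, rng, config.temporal_kernel,
                                c_lambda, config.leaky_slope)
                      for spec in config.layers]
        c_last = config.layers[-1].out_channels if config.layers else config.in_channels
        self.fc = Linear(c_last, config.num_classes, rng)
        self.dropout_rng = np.random.default_rng(config.seed + 1)

    # -- runtime ablation switch ------------------------------------------
    def set_attention_enabled(self, enabled: bool) -> "BCSTGCN":
        for unit in self.units:
            unit.gcn.attention_enabled = enabled
        return self

    @property
    def attention_enabled(self) -> bool:
        return any(u.gcn.attention_enabled and u.spec.use_bc for u in self.units)

    def forward(self, x) -> Tensor:
        x = Tensor._wrap(x)
        N, C, T, V = x.shape
        # normalize per (channel, joint) pair across the batch and frames
        y = ad.transpose(x, (0, 1, 3, 2))            # (N, C, V, T)
        y = ad.reshape(y, (N, C * V, T))
        y = self.data_bn.forward(y)
        y = ad.reshape(y, (N, C, V, T))
        y = ad.transpose(y, (0, 1, 3, 2))            # (N, C, T, V)
        for unit in self.units:
            y = unit.forward(y, dropout_rng=self.dropout_rng)
        pooled = ad.reduce_mean(y, axis=(2, 3))      # (N, C_last)
        return self.fc.forward(pooled)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode forward pass (dropout off, running BN,
        no autodiff graph)."""
        mode = self.training
        self.set_training(False)
        with ad.no_grad():
            out = self.forward(x).data
        self.set_training(mode)
        return out

    def attention_maps(self, x: np.ndarray) -> list:
        """Per-layer attention maps (averaged over the batch) for inspection."""
        self.predict_logits(x)
        out = []
        for unit in self.units:
            maps = unit.gcn.last_maps
            if maps is None:
                out.append(None)
            else:
                out.append({"alpha": maps["alpha"].mean(axis=0),
                            "B": maps["B"].mean(axis=0),
                            "C": maps["C"].mean(axis=0)})
        return out


def build_backbone(config: ModelConfig,
                   scheme: KeypointScheme | None = None) -> BCSTGCN:
    """Construct the model for a config (thin functional wrapper)."""
    return BCSTGCN(config, scheme=scheme)


# ---------------------------------------------------------------------------
# accounting

def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars (weights, biases, BN affine, M_k,
    attention a and W)."""
    return int(sum(p.size for p in model.parameters()))


def dense_flops(n_in: int, n_out: int, n_samples: int = 1) -> float:
    """FLOPs of a fully connected map (multiply-accumulates x 2)."""
    return 2.0 * n_in * n_out * n_samples


def count_flops(model: BCSTGCN, input_shape) -> float:
    """Analytic FLOP count (MACs x 2) of a forward pass at ``input_shape``.

    Counts the convolution, attention and FC multiply-accumulates; elementwise
    normalization and activations are excluded.
    """
    N, C, T, V = input_shape
    macs = 0.0
    K = model.adj.K
    kt = model.config.temporal_kernel
    for unit in model.units:
        spec = unit.spec
        c_in, c_out = spec.in_channels, spec.out_channels
        if spec.use_bc and unit.gcn.attention_enabled:
            f_prime = unit.gcn.attn_W.shape[1]
            macs += V * c_in * f_prime + 2 * V * f_prime
        macs += K * (c_in * T * V * V + c_in * c_out * T * V)
        T_out = -(-T // spec.temporal_stride)        # ceil division
        macs += c_out * c_out * kt * T_out * V
        if unit.res_weight is not None and not isinstance(unit.res_weight, str):
            macs += c_in * c_out * T_out * V
        T = T_out
    macs += model.config.layers[-1].out_channels * model.config.num_classes
    return 2.0 * macs * N


# ---------------------------------------------------------------------------
# checkpointing (portable array archive + embedded JSON config)

def save_checkpoint(model: BCSTGCN, path) -> None:
    arrays = {name: p.data for name, p in model.named_parameters()}
    for i, unit in enumerate(model.units):
        for bn_name in ("bn1", "bn2"):
            bn = getattr(unit, bn_name)
            if bn is not None:
                arrays[f"units.{i}.{bn_name}.running_mean"] = bn.running_mean
                arrays[f"units.{i}.{bn_name}.running_var"] = bn.running_var
    arrays["data_bn.running_mean"] = model.data_bn.running_mean
    arrays["data_bn.running_var"] = model.data_bn.running_var
    cfg = asdict(model.config)
    arrays["__config__"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, scheme: KeypointScheme | None = None) -> BCSTGCN:
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    cfg_dict = json.loads(bytes(arrays.pop("__config__")).decode())
    cfg_dict["layers"] = tuple(LayerSpec(**l) for l in cfg_dict["layers"])
    config = ModelConfig(**cfg_dict)
    model = BCSTGCN(config, scheme=scheme)
    params = dict(model.named_parameters())
    for name, value in arrays.items():
        if name.endswith("running_mean") or name.endswith("running_var"):
            obj = model
            *parts, attr = name.split(".")
            for part in parts:
                obj = obj[int(part)] if isinstance(obj, list) else getattr(obj, part)
            setattr(obj, attr, value)
        else:
            params[name].data = value.copy()
    return model
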