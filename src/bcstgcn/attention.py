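"""The BC module: global/local self-attention over the skeleton graph.

A single self-attention coefficient computation feeds two matrices per layer:
the local matrix B (masked to the first-order neighborhood of each partition
and row-renormalized) modulates the physical edges, while the global matrix C
(hard-thresholded at C_lambda) adds non-physical edges between joints that the
attention finds strongly coupled.  The attention-fused spatial convolution is

    f_out = sum_k W_k ( f_in ( A_norm_k * B_k * M_k + C_k ) )

with * elementwise and M_k the learnable edge-importance weights.

This module holds the plain-numpy functional forms (also used as inspection
utilities); the trainable twin lives inside :mod:`bcstgcn.network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import AdjacencySet

DEFAULT_LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class AttentionParams:
    """Shared linear map W (F -> F'), scoring vector a (2F'), and knobs."""

    W: np.ndarray          # (F, F')
    a: np.ndarray          # (2 F',)
    leaky_slope: float = DEFAULT_LEAKY_SLOPE
    C_lambda: float = 0.0

    def __post_init__(self):
        if self.W.ndim != 2 or self.W.shape[1] < 1:
            raise ValueError("W must be a (F, F') matrix with F' >= 1")
        if self.a.shape != (2 * self.W.shape[1],):
            raise ValueError("a must have length 2 F'")
        if not (0 < self.leaky_slope < 1):
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.C_lambda < 0:
            raise ValueError("C_lambda must be >= 0")


@dataclass(frozen=True)
class AttentionMaps:
    """Raw scores e, row-stochastic alpha, local B per partition, global C."""

    e: np.ndarray
    alpha: np.ndarray
    B: np.ndarray          # (K, V, V)
    C: np.ndarray          # (V, V)


def attention_scores(h: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Raw coefficients e[k, l] = LeakyReLU(a^T [W h_k || W h_l]).

    The concatenation splits into two inner products, so the V x V matrix is
    an outer sum of per-node scores.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValueError("h must be (V, F)")
    if h.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"feature dim {h.shape[1]} does not match W rows {params.W.shape[0]}")
    Fp = params.W.shape[1]
    Wh = h @ params.W                        # (V, F')
    s_src = Wh @ params.a[:Fp]
    s_dst = Wh @ params.a[Fp:]
    e = s_src[:, None] + s_dst[None, :]
    return np.where(e > 0, e, params.leaky_slope * e)


def attention_normalize(e: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the raw coefficients; each row sums to 1."""
    e = np.asarray(e, dtype=float)
    shifted = e - e.max(axis=-1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=-1, keepdims=True)


def threshold_global(C_raw: np.ndarray, C_lambda: float) -> np.ndarray:
    """Zero global-attention entries not strictly above C_lambda (idempotent)."""
    if C_lambda < 0:
        raise ValueError("C_lambda must be >= 0")
    C_raw = np.asarray(C_raw, dtype=float)
    return np.where(C_raw > C_lambda, C_raw, 0.0)


def local_attention(alpha: np.ndarray, neighborhood_mask: np.ndarray) -> np.ndarray:
    """Mask alpha to a partition's neighborhood, then renormalize rows.

    Rows with no surviving support stay all-zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    mask = np.asarray(neighborhood_mask, dtype=float)
    if mask.shape != alpha.shape:
        raise ValueError("mask shape must match alpha")
    masked = alpha * mask
    row = masked.sum(axis=-1, keepdims=True)
    return np.divide(masked, row, out=np.zeros_like(masked), where=row > 0)


def compute_attention_maps(h: np.ndarray, params: AttentionParams,
                           adj: AdjacencySet) -> AttentionMaps:
    """One shared coefficient pass -> (e, alpha, B per partition, C)."""
    e = attention_scores(h, params)
    alpha = attention_normalize(e)
    B = np.stack([local_attention(alpha, (adj.A[k] > 0).astype(float))
                  for k in range(adj.K)])
    C = threshold_global(alpha, params.C_lambda)
    return AttentionMaps(e=e, alpha=alpha, B=B, C=C)


def bc_spatial_conv(f_in: np.ndarray, adj: AdjacencySet,
                    B: np.ndarray, C: np.ndarray,
                    M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Attention-fused spatial graph convolution on one clip.

    Parameters
    ----------
    f_in : (C_in, T, V) feature tensor.
    adj : partitioned adjacency (supplies A_norm_k).
    B : (K, V, V) local attention matrices.
    C : (K, V, V) or (V, V) global attention (shared across partitions).
    M : (K, V, V) edge-importance weights.
    W : (K, C_out, C_in) per-partition channel maps.

    Returns (C_out, T, V); the same mixing is applied to every frame.
    """
    f_in = np.asarray(f_in, dtype=float)
    K = adj.K
    if C.ndim == 2:
        C = np.broadcast_to(C, (K,) + C.shape)
    if not (B.shape[0] == C.shape[0] == M.shape[0] == W.shape[0] == K):
        raise ValueError("partition counts of adj, B, C, M, W must agree")
    out = None
    for k in range(K):
        mix = adj.A_norm[k] * B[k] * M[k] + C[k]
        mixed = f_in @ mix                       # (C_in, T, V)
        term = np.einsum("oc,ctv->otv", W[k], mixed, optimize=True)
        out = term if out is None else out + term
    return out


def plain_spatial_conv(f_in: np.ndarray, adj: AdjacencySet,
                       M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Baseline spatial conv f_out = sum_k W_k (f_in (A_norm_k * M_k))."""
    K = adj.K
    ones = np.ones((K, adj.V, adj.V))
    return bc_spatial_conv(f_in, adj, B=ones, C=np.zeros((K, adj.V, adj.V)),
                           M=M, W=W)


def export_maps_tsv(maps: AttentionMaps, out_dir, prefix: str = "layer") -> list:
    """Dump B_k and C as TSV matrices for inspection; returns file paths."""
    import os

    paths = []
    for k in range(maps.B.shape[0]):
        p = os.path.join(out_dir, f"{prefix}_B{k}.tsv")
        np.savetxt(p, maps.B[k], delimiter="\t", fmt="%.6f")
        paths.append(p)
    p = os.path.join(out_dir, f"{prefix}_C.tsv")
    np.savetxt(p, maps.C, delimiter="\t", fmt="%.6f")
    paths.append(p)
    return paths
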