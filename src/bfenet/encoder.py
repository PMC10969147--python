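"""Adaptive adjacency construction from channel tokens (transformer encoder).

Given one token per EEG channel (a projection of that channel's CNN
features), a single pre-norm transformer encoder block produces two N x N
couplings that are fused into the graph used downstream:

* ``A`` — the head-averaged multi-head attention weights
  softmax(Q K^T / sqrt(d_k)), a row-stochastic similarity between channels;
* ``S = G G^T`` — the Gram matrix of the encoder output features G, a
  symmetric positive semidefinite "self-attention matrix";
* ``E = row-softmax(A + S)`` — the bounded, strictly positive adjacency.

``E`` is then sparsified per row by top-k. There are no positional
encodings: channel order is arbitrary, and the whole chain is permutation
equivariant (a property the tests assert).

All functions accept either a plain (N, d) numpy array — returning numpy
results, convenient for analysis — or a batched autodiff ``Tensor``
(B, N, d) as used during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from ._autograd import Tensor

ArrayOrTensor = Union[np.ndarray, Tensor]

LAYER_NORM_EPS = 1e-5


@dataclass
class EncoderParams:
    """Learnable parameters of one encoder block (all autodiff tensors)."""

    d_model: int
    h: int
    WQ: Tensor
    WK: Tensor
    WV: Tensor
    WO: Tensor
    bO: Tensor
    ln1_gamma: Tensor
    ln1_beta: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor
    mlp_W1: Tensor
    mlp_b1: Tensor
    mlp_W2: Tensor
    mlp_b2: Tensor
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.h != 0:
            raise ValueError(f"d_model={self.d_model} not divisible by h={self.h}")

    @property
    def dk(self) -> int:
        return self.d_model // self.h

    def tensors(self) -> dict[str, Tensor]:
        return {
            k: getattr(self, k)
            for k in (
                "WQ", "WK", "WV", "WO", "bO",
                "ln1_gamma", "ln1_beta", "ln2_gamma", "ln2_beta",
                "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2",
            )
        }


def init_encoder_params(
    d_model: int, h: int, rng: np.random.Generator, dropout: float = 0.1,
    residual_gain: float = 0.1,
) -> EncoderParams:
    """Fan-in-scaled uniform init; layer norms start at identity.

    The output projection and the second MLP map are scaled down by
    ``residual_gain`` so the encoder starts close to the identity on its
    residual path: early in training G stays near the input tokens and the
    Gram matrix S reflects their geometry rather than random-weight noise.
    """

    def lin(n_in, n_out, gain=1.0):
        lim = gain * np.sqrt(1.0 / n_in)
        return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)), requires_grad=True)

    hidden = 4 * d_model
    return EncoderParams(
        d_model=d_model,
        h=h,
        WQ=lin(d_model, d_model),
        WK=lin(d_model, d_model),
        WV=lin(d_model, d_model),
        WO=lin(d_model, d_model, gain=residual_gain),
        bO=Tensor(np.zeros(d_model), requires_grad=True),
        ln1_gamma=Tensor(np.ones(d_model), requires_grad=True),
        ln1_beta=Tensor(np.zeros(d_model), requires_grad=True),
        ln2_gamma=Tensor(np.ones(d_model), requires_grad=True),
        ln2_beta=Tensor(np.zeros(d_model), requires_grad=True),
        mlp_W1=lin(d_model, hidden),
        mlp_b1=Tensor(np.zeros(hidden), requires_grad=True),
        mlp_W2=lin(hidden, d_model, gain=residual_gain),
        mlp_b2=Tensor(np.zeros(d_model), requires_grad=True),
        dropout=dropout,
    )


@dataclass
class EncoderState:
    """Every intermediate of the adjacency construction, kept for inspection."""

    Xi: ArrayOrTensor
    Xn1: ArrayOrTensor
    Qi: ArrayOrTensor  # (h, N, dk) per batch element
    Ki: ArrayOrTensor
    Vi: ArrayOrTensor
    head_weights: ArrayOrTensor  # (h, N, N)
    A: ArrayOrTensor  # (N, N) attention adjacency
    Xn2: ArrayOrTensor
    G: ArrayOrTensor  # (N, d_model) encoder output
    S: ArrayOrTensor  # (N, N) Gram matrix of G
    E: ArrayOrTensor  # (N, N) fused adjacency


@dataclass
class SparseAdjacency:
    """Row-wise top-k filtered adjacency."""

    matrix: np.ndarray
    k: int
    retained_index: list[np.ndarray]


# ---------------------------------------------------------------------------
# numpy <-> tensor plumbing


def _lift(x: ArrayOrTensor) -> tuple[Tensor, bool]:
    """Promote (N, d) numpy input to a batch-1 Tensor; remember to squeeze."""
    if isinstance(x, Tensor):
        return x, False
    x = np.asarray(x, dtype=np.float64)
    return Tensor(x[None]), True


def _lower(t: Tensor, squeeze: bool) -> ArrayOrTensor:
    return t.data[0] if squeeze else t


# ---------------------------------------------------------------------------
# Operations


def layer_norm(
    X: ArrayOrTensor, gamma: Tensor | np.ndarray | None = None,
    beta: Tensor | np.ndarray | None = None, eps: float = LAYER_NORM_EPS,
) -> ArrayOrTensor:
    """Normalize each token over the feature axis, then apply affine scale/shift."""
    t, squeeze = _lift(X)
    d = t.shape[-1]
    gamma = gamma if gamma is not None else Tensor(np.ones(d))
    beta = beta if beta is not None else Tensor(np.zeros(d))
    mu = t.mean(axis=-1, keepdims=True)
    xc = t - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc * (var + eps) ** -0.5
    out = xn * gamma + beta
    return _lower(out, squeeze)


def _split_heads(x: Tensor, h: int) -> Tensor:
    B, N, d = x.shape
    return x.reshape(B, N, h, d // h).swapaxes(1, 2)  # (B, h, N, dk)


def _merge_heads(x: Tensor) -> Tensor:
    B, h, N, dk = x.shape
    return x.swapaxes(1, 2).reshape(B, N, h * dk)


def attention_adjacency(
    Xn1: ArrayOrTensor,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Multi-head attention: head-averaged adjacency A plus the context output.

    Returns ``(A, context, extras)`` where extras holds the per-head Q/K/V
    projections and attention weight matrices. In eval mode dropout is
    inactive and every row of A sums to 1.
    """
    t, squeeze = _lift(Xn1)
    if t.shape[-2] < 2:
        raise ValueError("need at least 2 channel tokens to build a graph")
    Q = _split_heads(t @ params.WQ, params.h)
    K = _split_heads(t @ params.WK, params.h)
    V = _split_heads(t @ params.WV, params.h)
    scores = (Q @ K.mT) * (1.0 / np.sqrt(params.dk))
    weights = scores.softmax(axis=-1)  # (B, h, N, N)
    A = weights.mean(axis=1)  # head average keeps rows stochastic
    if training and rng is not None:
        A = A.dropout(params.dropout, rng, training=True)
    context = _merge_heads(weights @ V) @ params.WO + params.bO
    extras = {"Qi": Q, "Ki": K, "Vi": V, "head_weights": weights}
    if squeeze:
        extras = {k: v.data[0] for k, v in extras.items()}
    return _lower(A, squeeze), _lower(context, squeeze), extras


def encoder_forward(
    Xi: ArrayOrTensor,
    params: EncoderParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> EncoderState:
    """Run the full encoder block and fuse the adjacency.

    Pre-norm residual wiring: Xn2 = LN2(Xi + MultiHead(LN1(Xi))) and
    G = MLP(Xn2) + Xi + MultiHead(LN1(Xi)), followed by S = G G^T and
    E = row-softmax(A + S).
    """
    t, squeeze = _lift(Xi)
    Xn1 = layer_norm(t, params.ln1_gamma, params.ln1_beta)
    A, mh, extras = attention_adjacency(Xn1, params, training=training, rng=rng)
    residual = t + mh
    Xn2 = layer_norm(residual, params.ln2_gamma, params.ln2_beta)
    hidden = (Xn2 @ params.mlp_W1 + params.mlp_b1).gelu()
    if training and rng is not None:
        hidden = hidden.dropout(params.dropout, rng, training=True)
    G = hidden @ params.mlp_W2 + params.mlp_b2 + residual
    S = G @ G.mT
    E = (A + S).softmax(axis=-1)
    for name, val in (("G", G), ("E", E)):
        if not np.isfinite(val.data).all():
            raise FloatingPointError(f"non-finite values at encoder stage {name}")
    if squeeze:
        extras = {
            k: (v.data[0] if isinstance(v, Tensor) else v) for k, v in extras.items()
        }
        return EncoderState(
            Xi=t.data[0], Xn1=Xn1.data[0], A=A.data[0], Xn2=Xn2.data[0],
            G=G.data[0], S=S.data[0], E=E.data[0], **extras,
        )
    return EncoderState(Xi=t, Xn1=Xn1, A=A, Xn2=Xn2, G=G, S=S, E=E, **extras)


def fuse_adjacency(A: ArrayOrTensor, G: ArrayOrTensor) -> ArrayOrTensor:
    """E = row-softmax(A + G G^T): strictly positive, rows summing to 1."""
    At, sq_a = _lift(A)
    Gt, sq_g = _lift(G)
    S = Gt @ Gt.mT
    E = (At + S).softmax(axis=-1)
    return _lower(E, sq_a and sq_g)


def topk_mask(E: np.ndarray, k: int) -> np.ndarray:
    """Binary mask of the k largest entries per row (ties -> lowest column index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    N = E.shape[-1]
    if k >= N:
        return np.ones_like(E)
    # stable argsort of negated values: descending, ties by lower index first
    order = np.argsort(-E, axis=-1, kind="stable")
    mask = np.zeros_like(E)
    np.put_along_axis(mask, order[..., :k], 1.0, axis=-1)
    return mask


def topk_sparsify(E: np.ndarray, k: int) -> SparseAdjacency:
    """Keep the k largest entries of each row at their values, zero the rest."""
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] != E.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {E.shape}")
    mask = topk_mask(E, k)
    retained = [np.flatnonzero(mask[i]) for i in range(E.shape[0])]
    return SparseAdjacency(matrix=E * mask, k=k, retained_index=retained)
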