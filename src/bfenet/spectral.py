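"""Spectral graph convolution utilities and the propagation rule.

The model's forward rule is the renormalized propagation

    H' = sigma( D_hat^{-1/2} (E_sym + I) D_hat^{-1/2}  X  Theta ),

where E_sym = (E + E^T)/2 (row-wise top-k output is generally asymmetric),
self-loops make isolated rows well-posed, and D_hat is the degree matrix of
the loop-augmented adjacency. The normalized Laplacian and its
eigendecomposition are provided as diagnostics: the spectrum motivates the
convolution but is never needed to evaluate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from ._autograd import Tensor

ArrayOrTensor = Union[np.ndarray, Tensor]

_DEG_EPS = 1e-12


@dataclass
class GraphStructure:
    """Node features attached to a weighted channel graph."""

    node_features: np.ndarray  # (N, d)
    edge_weights: np.ndarray  # (N, N) nonnegative

    def __post_init__(self):
        X = np.asarray(self.node_features, dtype=np.float64)
        E = np.asarray(self.edge_weights, dtype=np.float64)
        if E.ndim != 2 or E.shape[0] != E.shape[1]:
            raise ValueError(f"edge_weights must be square, got {E.shape}")
        if X.shape[0] != E.shape[0]:
            raise ValueError("node count mismatch between features and edges")
        if np.any(E < 0):
            raise ValueError("edge weights must be nonnegative")
        self.node_features, self.edge_weights = X, E


def propagation_operator(E: ArrayOrTensor) -> ArrayOrTensor:
    """P = D_hat^{-1/2} (E_sym + I) D_hat^{-1/2}; symmetric by construction.

    Accepts an (N, N) numpy matrix or a batched (B, N, N) Tensor.
    """
    if isinstance(E, Tensor):
        Es = (E + E.mT) * 0.5
        N = Es.shape[-1]
        Eh = Es + np.eye(N)
        d = Eh.sum(axis=-1)  # strictly positive thanks to the self-loop
        dis = d ** -0.5
        return Eh * dis.reshape(*d.shape, 1) * dis.reshape(*d.shape[:-1], 1, N)
    E = np.asarray(E, dtype=np.float64)
    if np.any(E < 0):
        raise ValueError("adjacency must be nonnegative")
    if not np.isfinite(E).all():
        raise ValueError("adjacency must be finite")
    Es = (E + E.T) * 0.5
    Eh = Es + np.eye(E.shape[0])
    dis = 1.0 / np.sqrt(Eh.sum(axis=1))
    return Eh * dis[:, None] * dis[None, :]


# Spec-facing alias: the operation named after the normalization step.
normalize_adjacency = propagation_operator


def laplacian_spectrum(E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized Laplacian L_hat = I - D^{-1/2} E_sym D^{-1/2} and its spectrum.

    No self-loops here (this is the classical graph Laplacian); zero-degree
    rows get an epsilon-guarded inverse square root and contribute eigenvalue
    1 through the identity. Returns (L_hat, U, Lambda) with ascending
    eigenvalues; for symmetric nonnegative input all eigenvalues lie in [0, 2].
    """
    E = np.asarray(E, dtype=np.float64)
    if np.any(E < 0):
        raise ValueError("adjacency must be nonnegative")
    Es = (E + E.T) * 0.5
    d = Es.sum(axis=1)
    dis = np.where(d > _DEG_EPS, 1.0 / np.sqrt(np.maximum(d, _DEG_EPS)), 0.0)
    E_hat = Es * dis[:, None] * dis[None, :]
    L_hat = np.eye(E.shape[0]) - E_hat
    lam, U = np.linalg.eigh(L_hat)
    return L_hat, U, np.diag(lam)


_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
    "tanh": np.tanh,
}


def gcn_layer(
    graph: GraphStructure, Theta: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One spectral graph convolution: H' = sigma(P X Theta)."""
    Theta = np.asarray(Theta, dtype=np.float64)
    if graph.node_features.shape[1] != Theta.shape[0]:
        raise ValueError(
            f"feature width {graph.node_features.shape[1]} != Theta rows {Theta.shape[0]}"
        )
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    P = propagation_operator(graph.edge_weights)
    return _ACTIVATIONS[activation](P @ graph.node_features @ Theta)


def gcn_layer_tensor(E: Tensor, X: Tensor, Theta: Tensor) -> Tensor:
    """Batched differentiable GCN layer with ReLU, used inside the network."""
    P = propagation_operator(E)
    return (P @ X @ Theta).relu()
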