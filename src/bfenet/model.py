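"""BFE-Net assembly and the scikit-learn style classifier.

Architecture, per frequency band (five bands fused at the head):

1. A stack of 1-D convolutions along time (kernel shared across EEG
   channels, so channels never mix), each layer conv -> dropout -> max-pool,
   with the running output *tapped* after every layer.
2. Per tap: each channel's (filters x time) block is flattened and linearly
   projected to a d_model token; the token set feeds the adjacency encoder
   (attention + Gram fusion + row-wise top-k) to build that depth's graph.
3. A spectral GCN layer propagates the same tokens over the learned graph;
   the flattened outputs of all depths concatenate into the band vector.

The five band vectors are concatenated, passed through dropout and a single
fully connected layer with softmax. Training minimizes cross-entropy with
Adam and stops early once the macro one-vs-rest AUC on the training
partition reaches a threshold (0.99 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autograd import Tensor, concatenate
from .data_model import FeatureSample
from .encoder import (
    EncoderParams,
    encoder_forward,
    init_encoder_params,
    layer_norm as enc_layer_norm,
    topk_mask,
    topk_sparsify,
    SparseAdjacency,
)
from .spectral import gcn_layer_tensor

ADJACENCY_MODES = ("adaptive", "no_self_matrix", "fixed")


@dataclass
class ModelConfig:
    """Hyperparameters of the network; defaults follow the 62-channel setup."""

    n_channels: int
    n_classes: int
    n_bands: int = 5
    n_layers: int = 3
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel_time: int = 5
    pool_time: int = 2
    dropout: float = 0.1
    d_model: int = 128
    heads: int = 8
    k: int = 10
    gcn_out: int = 32
    share_encoder: bool = False
    adjacency_mode: str = "adaptive"
    seed: int = 0

    def __post_init__(self):
        self.conv_filters = tuple(self.conv_filters)
        if len(self.conv_filters) != self.n_layers:
            raise ValueError(
                f"conv_filters has {len(self.conv_filters)} entries for "
                f"n_layers={self.n_layers}"
            )
        if self.d_model % self.heads != 0:
            raise ValueError(f"d_model={self.d_model} not divisible by heads={self.heads}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.adjacency_mode not in ADJACENCY_MODES:
            raise ValueError(f"adjacency_mode must be one of {ADJACENCY_MODES}")

    def layer_time_lengths(self, T: int) -> list[int]:
        """Time-axis length after each conv+pool layer; errors name the layer."""
        lengths = []
        L = T
        for i in range(self.n_layers):
            L = L - self.kernel_time + 1
            if L < 1:
                raise ValueError(
                    f"layer {i + 1}: time axis exhausted by kernel {self.kernel_time} "
                    f"(length before conv: {L + self.kernel_time - 1})"
                )
            L = L // self.pool_time
            if L < 1:
                raise ValueError(
                    f"layer {i + 1}: time axis exhausted by pooling {self.pool_time}"
                )
            lengths.append(L)
        return lengths


TINY_CONFIG = dict(
    conv_filters=(4, 8, 16),
    kernel_time=3,
    d_model=32,
    heads=4,
    k=3,
    gcn_out=8,
)
"""Desk-scale hyperparameters for 8-channel synthetic corpora."""


class Adam:
    """Adam optimizer over a flat name -> Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class BandBranchOutput:
    """One band's flattened multi-depth GCN output plus the learned graphs."""

    band_vector: np.ndarray
    per_layer_adjacency: list[SparseAdjacency]


class BFENet:
    """The bare network: parameter container plus differentiable forward."""

    def __init__(self, config: ModelConfig, T: int,
                 rng: np.random.Generator | None = None,
                 fixed_adjacency: np.ndarray | None = None):
        self.config = config
        self.T = T
        self.time_lengths = config.layer_time_lengths(T)
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.fixed_adjacency = None
        if config.adjacency_mode == "fixed":
            if fixed_adjacency is None:
                raise ValueError("adjacency_mode='fixed' requires fixed_adjacency")
            fixed_adjacency = np.asarray(fixed_adjacency, dtype=np.float64)
            if fixed_adjacency.shape != (config.n_channels, config.n_channels):
                raise ValueError("fixed adjacency shape mismatch")
            if np.any(fixed_adjacency < 0):
                raise ValueError("fixed adjacency must be nonnegative")
            self.fixed_adjacency = fixed_adjacency
        self.params: dict[str, Tensor] = {}
        self.encoders: dict[tuple[int, int], EncoderParams] = {}
        self._build(rng)

    # -- construction ---------------------------------------------------------

    #: target squared norm of a channel token. Tokens are layer-normalized
    #: after projection with gain sqrt(TOKEN_SCALE / d_model), so the Gram
    #: matrix S = G G^T starts as TOKEN_SCALE * cosine similarity — bounded,
    #: inside the responsive range of the row softmax in E = softmax(A + S).
    TOKEN_SCALE = 2.0

    def _lin(self, rng, n_in, n_out) -> Tensor:
        lim = np.sqrt(1.0 / n_in)
        return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)), requires_grad=True)

    def _semi_orthogonal(self, rng, n_in, n_out) -> Tensor:
        """Projection with orthonormal rows or columns: preserves the tap
        geometry (inner products up to scale) instead of scrambling it."""
        big, small = max(n_in, n_out), min(n_in, n_out)
        A = rng.standard_normal((big, small))
        Q, R = np.linalg.qr(A)
        Q = Q * np.sign(np.diag(R))  # fix sign ambiguity for determinism
        W = Q if n_in >= n_out else np.ascontiguousarray(Q.T)
        return Tensor(W, requires_grad=True)

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        for b in range(cfg.n_bands):
            in_ch = 1
            for l, (f, tl) in enumerate(zip(cfg.conv_filters, self.time_lengths)):
                lim = np.sqrt(1.0 / (in_ch * cfg.kernel_time))
                self.params[f"band{b}_conv{l}_W"] = Tensor(
                    rng.uniform(-lim, lim, size=(f, in_ch, cfg.kernel_time)),
                    requires_grad=True,
                )
                self.params[f"band{b}_conv{l}_b"] = Tensor(
                    np.zeros(f), requires_grad=True
                )
                self.params[f"band{b}_proj{l}_W"] = self._semi_orthogonal(
                    rng, f * tl, cfg.d_model
                )
                self.params[f"band{b}_proj{l}_b"] = Tensor(
                    np.zeros(cfg.d_model), requires_grad=True
                )
                self.params[f"band{b}_tokln{l}_gamma"] = Tensor(
                    np.full(cfg.d_model, np.sqrt(self.TOKEN_SCALE / cfg.d_model)),
                    requires_grad=True,
                )
                self.params[f"band{b}_tokln{l}_beta"] = Tensor(
                    np.zeros(cfg.d_model), requires_grad=True
                )
                if cfg.adjacency_mode != "fixed":
                    if cfg.share_encoder and l > 0:
                        self.encoders[(b, l)] = self.encoders[(b, 0)]
                    else:
                        enc = init_encoder_params(
                            cfg.d_model, cfg.heads, rng, dropout=cfg.dropout
                        )
                        self.encoders[(b, l)] = enc
                        for name, t in enc.tensors().items():
                            self.params[f"band{b}_enc{l}_{name}"] = t
                self.params[f"band{b}_gcn{l}_Theta"] = self._lin(
                    rng, cfg.d_model, cfg.gcn_out
                )
                in_ch = f
        fc_in = cfg.n_bands * cfg.n_layers * cfg.n_channels * cfg.gcn_out
        self.params["fc_W"] = self._lin(rng, fc_in, cfg.n_classes)
        self.params["fc_b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward --------------------------------------------------------------

    def _band_branch(self, x_band: np.ndarray, b: int, training: bool,
                     rng: np.random.Generator | None,
                     collect_states: bool = False):
        """x_band: (B, N, T) -> (band vector Tensor (B, L*N*gcn_out), adjacency list)."""
        cfg = self.config
        B, N, T = x_band.shape
        h = Tensor(x_band.reshape(B * N, 1, T))
        vecs, adjacencies, states = [], [], []
        for l in range(cfg.n_layers):
            h = h.conv1d(self.params[f"band{b}_conv{l}_W"], self.params[f"band{b}_conv{l}_b"])
            if training and rng is not None:
                h = h.dropout(cfg.dropout, rng, training)
            h = h.maxpool1d(cfg.pool_time)
            f, tl = h.shape[1], h.shape[2]
            tap = h.reshape(B, N, f * tl)
            tok = tap @ self.params[f"band{b}_proj{l}_W"] + self.params[f"band{b}_proj{l}_b"]
            tok = enc_layer_norm(
                tok,
                self.params[f"band{b}_tokln{l}_gamma"],
                self.params[f"band{b}_tokln{l}_beta"],
            )
            if cfg.adjacency_mode == "fixed":
                E_sparse = Tensor(self.fixed_adjacency)
                state = None
            else:
                state = encoder_forward(tok, self.encoders[(b, l)], training=training, rng=rng)
                E = state.A.softmax(axis=-1) if cfg.adjacency_mode == "no_self_matrix" else state.E
                mask = topk_mask(E.data, cfg.k)
                E_sparse = E * mask
            Hg = gcn_layer_tensor(E_sparse, tok, self.params[f"band{b}_gcn{l}_Theta"])
            vecs.append(Hg.reshape(B, N * cfg.gcn_out))
            adjacencies.append(E_sparse.data if isinstance(E_sparse, Tensor) else E_sparse)
            if collect_states:
                states.append(state)
        out = concatenate(vecs, axis=1)
        return (out, adjacencies, states) if collect_states else (out, adjacencies)

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """X: (B, N, T, n_bands) -> (logits Tensor (B, n_classes), aux dict).

        aux["adjacency"][(band, layer)] holds the per-sample sparse adjacency
        stack, shape (B, N, N) ((N, N) in fixed mode).
        """
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[3] != cfg.n_bands:
            raise ValueError(
                f"expected (B, {cfg.n_channels}, T, {cfg.n_bands}), got {X.shape}"
            )
        if X.shape[1] != cfg.n_channels:
            raise ValueError(f"expected {cfg.n_channels} channels, got {X.shape[1]}")
        band_vecs, adjacency = [], {}
        for b in range(cfg.n_bands):
            vec, adjs = self._band_branch(X[:, :, :, b], b, training, rng)
            band_vecs.append(vec)
            for l, a in enumerate(adjs):
                adjacency[(b, l)] = a
        z = concatenate(band_vecs, axis=1)
        if training and rng is not None:
            z = z.dropout(cfg.dropout, rng, training)
        logits = z @ self.params["fc_W"] + self.params["fc_b"]
        return logits, {"adjacency": adjacency}

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(X), batch_size):
            logits, _ = self.forward(X[lo : lo + batch_size], training=False)
            out.append(logits.softmax(axis=-1).data)
        return np.concatenate(out)

    def loss(self, X: np.ndarray, y: np.ndarray, training: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        logits, _ = self.forward(X, training=training, rng=rng)
        logp = logits.log_softmax(axis=-1)
        onehot = np.eye(self.config.n_classes)[np.asarray(y, dtype=int)]
        return -(logp * onehot).sum() * (1.0 / len(y))


# ---------------------------------------------------------------------------
# Spec-facing functional wrappers


def conv_stack_forward(band_features: np.ndarray, net: BFENet, band: int = 0,
                       training: bool = False,
                       rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Per-layer tapped CNN outputs for one band: list of (N, filters, time)."""
    x = np.asarray(band_features, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    cfg = net.config
    B, N, T = x.shape
    h = Tensor(x.reshape(B * N, 1, T))
    taps = []
    for l in range(cfg.n_layers):
        h = h.conv1d(net.params[f"band{band}_conv{l}_W"], net.params[f"band{band}_conv{l}_b"])
        if training and rng is not None:
            h = h.dropout(cfg.dropout, rng, training)
        h = h.maxpool1d(cfg.pool_time)
        f, tl = h.shape[1], h.shape[2]
        tap = h.data.reshape(B, N, f, tl)
        taps.append(tap[0] if squeeze else tap)
    return taps


def band_branch_forward(band_features: np.ndarray, net: BFENet,
                        band: int = 0) -> BandBranchOutput:
    """Eval-mode single-sample band branch with exported sparse adjacencies."""
    x = np.asarray(band_features, dtype=np.float64)[None]  # (1, N, T)
    vec, adjs = net._band_branch(x, band, training=False, rng=None)
    return BandBranchOutput(
        band_vector=vec.data[0],
        per_layer_adjacency=[topk_sparsify(a[0], net.config.k) for a in adjs],
    )


def full_forward(sample: FeatureSample, net: BFENet) -> np.ndarray:
    """Class probabilities for a single trial (eval mode)."""
    if sample.n_bands != net.config.n_bands:
        raise ValueError(
            f"sample has {sample.n_bands} bands, model expects {net.config.n_bands}"
        )
    return net.predict_proba(sample.features[None])[0]


# ---------------------------------------------------------------------------
# Estimator


def macro_ovr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC; absent classes are skipped with a warning."""
    import warnings

    from sklearn.metrics import roc_auc_score

    y_true = np.asarray(y_true, dtype=int)
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("AUC undefined with a single class present")
    aucs = []
    for c in range(scores.shape[1]):
        if c not in present:
            warnings.warn(f"class {c} absent from labels; skipped in macro AUC")
            continue
        aucs.append(roc_auc_score((y_true == c).astype(int), scores[:, c]))
    return float(np.mean(aucs))


class BFENetClassifier(ClassifierMixin, BaseEstimator):
    """Subject-independent EEG emotion classifier with learned channel graphs.

    Accepts feature tensors of shape (n_samples, n_channels, T, n_bands).
    Fitting runs Adam on the cross-entropy loss in shuffled mini-batches and
    stops early when the macro one-vs-rest AUC on the training data reaches
    ``auc_stop``. Deterministic for a fixed ``random_state``.

    Attributes set by fit: ``classes_``, ``net_``, ``stop_epoch_``,
    ``loss_history_``, ``auc_history_``, ``n_parameters_``.
    """

    def __init__(self, n_layers=3, conv_filters=(64, 128, 256), kernel_time=5,
                 pool_time=2, dropout=0.1, d_model=128, heads=8, k=10,
                 gcn_out=32, share_encoder=False, adjacency_mode="adaptive",
                 fixed_adjacency=None, learning_rate=1e-3, batch_size=64,
                 max_epochs=100, auc_stop=0.99, random_state=0):
        self.n_layers = n_layers
        self.conv_filters = conv_filters
        self.kernel_time = kernel_time
        self.pool_time = pool_time
        self.dropout = dropout
        self.d_model = d_model
        self.heads = heads
        self.k = k
        self.gcn_out = gcn_out
        self.share_encoder = share_encoder
        self.adjacency_mode = adjacency_mode
        self.fixed_adjacency = fixed_adjacency
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.auc_stop = auc_stop
        self.random_state = random_state

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(
                f"X must be (n_samples, channels, time, bands), got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y):
        if not 0 < self.auc_stop <= 1:
            raise ValueError(f"auc_stop must be in (0, 1], got {self.auc_stop}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, N, T, n_bands = X.shape
        mode = "fixed" if self.adjacency_mode in ("distance", "plv", "fixed") \
            else self.adjacency_mode
        config = ModelConfig(
            n_channels=N, n_classes=len(self.classes_), n_bands=n_bands,
            n_layers=self.n_layers, conv_filters=tuple(self.conv_filters),
            kernel_time=self.kernel_time, pool_time=self.pool_time,
            dropout=self.dropout, d_model=self.d_model, heads=self.heads,
            k=self.k, gcn_out=self.gcn_out, share_encoder=self.share_encoder,
            adjacency_mode=mode, seed=int(self.random_state),
        )
        rng = np.random.default_rng(int(self.random_state))
        net = BFENet(config, T, rng, fixed_adjacency=self.fixed_adjacency)
        opt = Adam(net.params, lr=self.learning_rate)
        loss_history, auc_history = [], []
        stop_epoch = self.max_epochs
        for epoch in range(1, self.max_epochs + 1):
            perm = rng.permutation(n)
            epoch_losses, epoch_scores = [], []
            for lo in range(0, n, self.batch_size):
                idx = perm[lo : lo + self.batch_size]
                opt.zero_grad()
                logits, _ = net.forward(X[idx], training=True, rng=rng)
                logp = logits.log_softmax(axis=-1)
                onehot = np.eye(len(self.classes_))[y_idx[idx]]
                loss = -(logp * onehot).sum() * (1.0 / len(idx))
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {lo // self.batch_size}; "
                        f"history: {loss_history[-5:]}"
                    )
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
                epoch_scores.append(np.exp(logp.data))
            loss_history.append(float(np.mean(epoch_losses)))
            # AUC monitored from the epoch's training-mode outputs (dropout
            # active), matching the protocol of monitoring during training
            auc = macro_ovr_auc(y_idx[perm], np.concatenate(epoch_scores))
            auc_history.append(auc)
            if auc >= self.auc_stop:
                stop_epoch = epoch
                break
        self.net_ = net
        self.stop_epoch_ = stop_epoch
        self.loss_history_ = loss_history
        self.auc_history_ = auc_history
        self.n_parameters_ = net.n_parameters
        return self

    def predict_proba(self, X):
        X = self._validate_X(X)
        return self.net_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def export_adjacency(self, X) -> dict:
        """Per-sample sparse adjacencies {(band, layer): (n, N, N)} in eval mode."""
        X = self._validate_X(X)
        out: dict[tuple[int, int], list[np.ndarray]] = {}
        for lo in range(0, len(X), 256):
            _, aux = self.net_.forward(X[lo : lo + 256], training=False)
            for key, a in aux["adjacency"].items():
                if a.ndim == 2:  # fixed mode: same graph for every sample
                    a = np.broadcast_to(a, (len(X[lo : lo + 256]),) + a.shape)
                out.setdefault(key, []).append(np.asarray(a))
        return {k: np.concatenate(v) for k, v in out.items()}
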