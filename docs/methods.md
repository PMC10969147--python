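# Methods

## The model

`bfenet` implements a subject-independent EEG emotion classifier that learns
its own channel-connectivity graphs instead of fixing them from electrode
geometry or a functional-connectivity statistic. The input is one trial of
band-wise differential-entropy (DE) features, a tensor `X ∈ R^{N×T×C}` with
`N` EEG channels, `T` time windows and `C = 5` canonical bands (delta, theta,
alpha, beta, gamma). Each band is processed by its own branch:

1. **CNN taps.** A stack of `L = 3` one-dimensional convolutions along time
   (kernel `1×5`, valid, stride 1; each layer followed by dropout 0.1 and
   max-pooling of width 2). Kernels are shared across channels and never mix
   channels, so each channel keeps its own feature series. The running output
   is *tapped* after every layer, giving `L` feature sets at increasing
   abstraction.
2. **Token embedding.** Per tap, each channel's `(filters × time)` block is
   flattened and linearly projected to a `d_model`-dimensional token, then
   layer-normalized per token. The projection is initialized
   semi-orthogonally and the token-norm gain starts at `sqrt(2/d_model)`;
   see "Numerical choices" for why.
3. **Adaptive adjacency.** A single pre-norm transformer-encoder block turns
   the token set into a graph:
   `A` = head-averaged multi-head attention weights
   `softmax(QK^T/√d_k)` (row-stochastic, dropout 0.1 in training);
   `G` = encoder output (attention residual plus MLP residual);
   `S = GG^T`, the Gram ("self-attention") matrix, symmetric PSD;
   `E = row-softmax(A + S)`, the fused adjacency — strictly positive with
   unit row sums. Per row, only the `k` largest entries of `E` are kept
   (top-k, default `k = 10`; ties broken toward the lower column index;
   the diagonal competes like any other entry).
4. **Spectral graph convolution.** The sparse graph is symmetrized,
   self-loops are added, and one GCN layer propagates the same tokens:
   `H' = ReLU(D̂^{-1/2}(E_sym + I)D̂^{-1/2} X Θ)`. The normalized-Laplacian
   eigendecomposition is implemented as a diagnostic utility
   (`laplacian_spectrum`); the forward pass uses only the renormalized
   propagation operator.
5. **Fusion and head.** The flattened GCN outputs of all `L` taps form the
   band vector; the five band vectors are concatenated, passed through
   dropout 0.1 and a single fully connected softmax layer.

Each band/depth pair has its own encoder parameters by default
(`share_encoder=False`); no positional encodings are used, which makes the
entire adjacency chain permutation-equivariant in the channel order — a
property the tests assert end-to-end.

Training minimizes cross-entropy with Adam (learning rate `1e-3`, batch 64,
at most 100 epochs). After each epoch the macro one-vs-rest AUC of the
epoch's training-mode outputs (dropout active) is computed; training halts
once it reaches 0.99 and the current weights are kept. Evaluation is
leave-one-subject-out (LOSO) throughout: one fold per subject, mean and
population standard deviation of per-subject accuracies, pooled confusion
matrix. Two identically seeded runs produce byte-identical reports.

The whole network, including backpropagation, runs on a small reverse-mode
automatic-differentiation core over numpy (`bfenet._autograd`), written for
this package and verified against central finite differences for every
primitive and for the assembled model.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `conv_filters` | (64, 128, 256) | kernels per CNN layer (full-scale config) |
| `kernel_time`, `pool_time` | 5, 2 | conv kernel / pooling width along windows |
| `d_model`, `heads` | 128, 8 | token width and attention heads |
| `k` | 10 | retained entries per adjacency row |
| `gcn_out` | 32 | GCN output width per node |
| `dropout` | 0.1 | all dropout sites |
| `learning_rate` | 1e-3 | Adam step size |
| `auc_stop` | 0.99 | training-AUC early-stop threshold |

`TINY_CONFIG` (filters (4, 8, 16), kernel 3, `d_model` 32, 4 heads, `k` 3,
`gcn_out` 8) is the desk-scale configuration used for 8-channel synthetic
corpora; kernel 3 is required because three conv+pool stages at kernel 5
would exhaust a 32-window time axis, which the configuration validator
rejects up front.

## Synthetic data: what it emulates and what it does not

Real DE-feature corpora of this kind (62 channels, 15 subjects × 3 sessions,
balanced trials over 3 or 4 emotion classes) are licensed downloads, so the
package ships a generator that reproduces their *registry structure* exactly
— subjects, sessions, balanced labels, per-trial `N×T×C` tensors, trailing
zero padding — with a planted, known ground truth for connectivity.

Each class `c` owns a sparse symmetric graph `M_c` (each channel linked to
roughly `s` partners, degrees in `[s, 2s]`; distinct edge sets across
classes). The latent channel signals of a class-`c` trial are drawn i.i.d.
per window with covariance `Σ_{c,b} = I + ρ·g_b·M_c`, where
`ρ = α/(1+α)` maps the coupling strength `α ≥ 0` to an edge correlation and
`g_b = (0.2, 0.35, 0.5, 0.85, 1.0)` makes beta/gamma carry the strongest
coupling, reflecting the common finding that high-frequency bands are the
most emotion-informative. If a graph's spectrum would make `Σ` indefinite,
the coupling is rescaled so the smallest eigenvalue stays ≥ 0.05. The stored
feature is the Gaussian differential entropy `0.5·ln(2πe·v)` of each
window's sample variance (`m = 20` latent samples per window), plus a
per-subject offset (`β = 0.3`) and observation noise (0.05).

Two properties are deliberate:

* **Marginals are class-invariant.** Every channel has unit variance in
  every class, so nothing is recoverable from per-channel statistics — a
  mean classifier is at chance by construction, and class recovery requires
  cross-channel structure.
* **α = 0 collapses all classes onto one distribution**, giving an exact
  null: for any fixed classifier, expected accuracy on the balanced,
  label-independent test sets is exactly 1/3.

What the generator does *not* emulate: raw EEG waveforms and their spectra,
artifacts, volume conduction, non-stationarity across sessions, or —
importantly — class-conditional *mean/power* structure, which real emotion
datasets have in abundance. Passing recovery tests on this corpus therefore
says the pipeline can exploit covariance structure; it does not certify
real-data accuracy, and failure modes specific to the covariance-only null
(next section) do not imply failure on real data.

## What the recovery study shows — and its structural ceiling

An independent oracle, a logistic probe on explicit per-band cross-channel
correlation features, recovers the class almost perfectly on held-out
subjects at `α = 2` (≈ 94–99% across seeds) and is at chance at `α = 0`:
the corpus carries the signal. A probe on the *model's own* per-trial
propagation operators reaches ≈ 84%: the learned graphs carry it too.

The full network, however, plateaus around 35–40% LOSO accuracy at `α = 2`
(chance 33%), above its distance-adjacency ablation but far from the probe.
The reason is structural, not a training bug. With class-invariant marginals
the only class-bearing information is *which* channels co-fluctuate; with no
positional encodings the channel tokens are exchangeable, so the GCN output
`ReLU(P·X·Θ)` mixes neighbor features with data-dependent weights but
carries no channel-identity tags, and a single linear softmax head cannot
decode *which* partner was mixed. Only weak summary statistics (row sums /
degree patterns of `P`) leak through — and their measured readout ceiling
(~40%) matches the observed plateau. On real data the same architecture
reads class information directly from token means, a pathway this null
corpus intentionally withholds. The study is reported as measured in
`scripts/acceptance.py`; the desk-scale study sizes (8 channels, 6 subjects,
12 trials each, `T = 32`, 3 seeds) are the package's chosen conditions.

## Numerical choices

* **Token embedding.** Semi-orthogonal projection init preserves the inner
  products of the tap features instead of scrambling them; the per-token
  LayerNorm with gain `sqrt(2/d_model)` makes the initial Gram matrix
  `S ≈ 2·cosine-similarity`, bounded and inside the responsive range of the
  row softmax in `E = softmax(A + S)` (an unnormalized `S` scales with
  `d_model` and saturates the softmax into a near-identity graph). The
  encoder's residual projections (`W_O`, second MLP map) start at gain 0.1
  so `G` stays near the tokens early in training. These choices doubled the
  per-trial recovery of planted edges in top-k(`E`) in our measurements.
* **Top-k ties** break toward the lower column index (stable sort), making
  sparsification deterministic; `k ≥ N` is a no-op.
* **Symmetrization** `(E + E^T)/2` precedes graph normalization because
  row-wise top-k output is generally asymmetric while two-sided degree
  normalization presumes symmetry; self-loops keep isolated rows well-posed.
* **Layer-norm epsilon** 1e-5; Laplacian utilities guard zero-degree rows
  with an epsilon inverse square root.
* **Population (1/n) variance** everywhere: DE windows, per-subject
  z-scoring, fold-accuracy standard deviations.
* **Per-subject normalization** z-scores each (subject, channel, band)
  series over unpadded windows of all that subject's trials; zero-variance
  slices are zeroed with a logged warning. Padding is trailing zeros, and
  over-long trials are an error rather than silently truncated.
* **Determinism.** All randomness flows from a single `numpy` Generator per
  fit (parameter init, batch shuffling, dropout masks); fold seeds derive
  from the study seed by addition.

## Design choices where the method description was open

* Per-head attention matrices are *averaged* into `A` (keeps rows
  stochastic; concatenation has no N×N form).
* The softmax in `E = softmax(A + S)` is row-wise, matching the attention
  convention and yielding a row-stochastic operator.
* The Laplacian eigendecomposition is a diagnostic; the forward rule is the
  renormalized propagation operator, the only reading that is well-posed for
  sparse rows.
* The AUC early-stop monitor uses the training partition (no validation
  split is part of the protocol), computed from the epoch's training-mode
  outputs.
* The classification head is a single fully connected layer with dropout 0.1
  before it; the MLP inside the encoder is the standard two-layer GELU block
  with hidden width `4·d_model`.
* Band edges for the raw-signal path follow the common convention
  delta 1–3, theta 4–7, alpha 8–13, beta 14–30, gamma 31–50 Hz; the DE
  window length defaults to 1 s and is configurable (4 s segmentation is
  reachable through the same parameter).
* Electrode coordinates for tests and the distance ablation come from a
  synthetic Fibonacci-spiral hemisphere (`make_synthetic_montage`), clearly
  labelled synthetic; real cap geometries load from a `name,x,y,z` CSV.

## Known limitations

* The recovery criterion "≥ 80% LOSO at strong coupling" is not met by the
  full network on the covariance-only corpus for the structural reasons
  above; the package reports the honest numbers instead.
* The chance-band check on the null corpus is a calibrated 95% statistical
  test and therefore fails for ~5% of seed choices by construction.
* Training is CPU-bound numpy; the full 62-channel, 265-window configuration
  builds and runs but is sized for workstations, not for the minutes-scale
  loops the synthetic studies use.
* The PLV ablation needs raw time-domain signals, which the DE-only
  synthetic corpora do not provide; it is exercised on analytic signals in
  the tests.
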