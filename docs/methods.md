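# Methods

## Problem and model

`scpatch` performs supervised cell-type annotation from single-cell RNA-seq
count matrices. Each cell's expression profile — a length-G vector of
log-normalised counts — is laid row-major into a vector padded to the
smallest multiple of P², cut into N = ⌈G/P²⌉ flattened patches of P² gene
values, and treated as a token sequence:

1. **Patch embedding.** Each patch is mapped to a D-dimensional token by a
   single shared linear projection (mathematically identical to a stride-P
   convolution over the 2D gene grid). A learnable class token is prepended
   and a learned position embedding (one row per token) is added, fixing each
   patch's identity in the otherwise permutation-invariant encoder.
2. **Encoder.** `depth` pre-norm transformer blocks: h ← h + MHSA(LN(h));
   h ← h + MLP(LN(h)), where MHSA is standard scaled dot-product multi-head
   self-attention and the MLP is linear(D→⌈mlp_ratio·D⌉) → GELU → linear(→D).
   GELU uses the exact form x·Φ(x) with Φ the standard-normal CDF evaluated
   via the error function, not the tanh approximation.
3. **Head.** After a final LayerNorm, the class-token row (or the token mean,
   per `pooling`) passes through a three-layer MLP
   (linear → GELU → linear → GELU → linear) to K logits; softmax yields
   per-class confidences, and the argmax (ties broken toward the lowest class
   index) is the predicted type.

Grouping genes into patches shortens the input sequence from G tokens to
G/P² tokens, which keeps self-attention tractable for genome-scale inputs
and pools sparse signals within each patch.

## Preprocessing

Counts are normalised per cell: value ← ln(1 + s·count/cell_total) with
scale factor s = 10,000, so ∑ expm1(value) = s for every cell exactly. Cells
with zero total count raise an error naming the cell rather than producing
NaN. Query matrices are aligned to a model's frozen reference gene list by
exact string matching: unmatched query genes are dropped, missing reference
genes zero-filled, and the match/drop/fill counts logged. Gene layout is a
fixed bijection (gene j → slot j) serialized with the checkpoint; any fixed
bijection is equivalent since patches are flattened before projection.

## Training

The loss is sparse categorical cross-entropy, mean over the batch of
−ln p[y] with probabilities clipped at 1e−12. The optimiser is SGD with
momentum (default 0.9) and decoupled weight decay that skips LayerNorm
parameters, biases, the class token, and the position table. The learning
rate follows a cosine decline r_t = 0.5·r₀·(1 + cos(tπ/T)) over
T = epochs × batches-per-epoch total steps, floored at `end_lr` (the raw
formula reaches 0 at t = T). All shuffling, initialisation and dropout are
driven by a single integer seed; two runs with the same seed produce
bit-identical histories.

Two presets are shipped:

| | full | desk |
|---|---|---|
| patch_size P | 16 | 16 |
| depth | 12 | 2 |
| embed_dim D | 192 | 32 |
| n_heads | 3 | 2 |
| mlp_ratio | 4 | 2 |
| classifier hidden | (128, 64) | (64, 32) |
| dropout | 0.1 | 0.1 |
| input_dropout | 0.0 | 0.3 |
| epochs / batch | 50 / 64 | 30 / 32 |
| initial_lr / end_lr | 1e−3 / 1e−5 | 0.05 / 1e−4 |
| weight_decay | 1e−4 | 1e−2 |

The full preset is the reference architecture scale (12 encoder blocks,
patch 16, SGD with the 50-epoch cosine schedule). The desk preset is sized
for hundreds of cells and ~1,000 genes on one CPU: a two-block encoder and a
larger SGD step with stronger decay, which is the workable optimisation
scale for a small model trained from scratch. Embedding width, head count,
MLP ratio and classifier widths are free configuration everywhere; only the
depth-12/patch-16 pairing is fixed as the reference preset.

### Initialisation and regularisation choices

Linear weights are fan-in scaled gaussians (std 1/√fan_in); ViT-style
constant-std initialisation left the network unable to move the loss off
ln K under plain SGD at this scale. The position table is initialised at
unit scale: position embeddings much smaller than token magnitudes make
patches indistinguishable to early attention, which measurably stalls
learning when N is large (small P). `input_dropout` applies dropout to the
gene vector itself during training (inverted scaling, disabled at
inference); it emulates the capture dropout already present in the data and
is the single most effective regulariser on small training sets. Standard
dropout (0.1) is applied to embeddings, attention probabilities and MLP
activations.

## Evaluation

Metrics come from the K×K confusion matrix (rows = truth). Per class,
one-vs-rest TP/FP/FN/TN give precision, recall, F1 = 2PR/(P+R) and the
binary Matthews coefficient; macro scores are unweighted means over classes
present in the truth, and "mean MCC" is the mean of the per-class binary
MCCs (a single multiclass MCC is available separately as
`multiclass_mcc`). Zero denominators (e.g. a never-predicted class) yield 0
with a warning — this deliberately penalises constant predictors and is the
convention used throughout. Datasets whose truth contains a single class
report accuracy only; macro F1 and MCC are undefined there and returned as
None. Replicate spread is the sample standard deviation (n−1).

## Synthetic data

The generator emulates the target regime — sparse, overdispersed,
imbalanced labelled counts — with a zero-inflated negative binomial: gene g
in a type-k cell has NB mean base_mean·marker_fold if g is one of type k's
markers, base_mean otherwise, shared dispersion r (p = r/(r+m)), and each
count is independently zeroed with probability dropout_rate. Marker sets
are disjoint and scattered randomly over the gene list (the input gene
ordering carries no biological signal, as in real data where gene order is
alphabetical or arbitrary). Cells are allocated to types by exact
largest-remainder apportionment so preset sizes are reproducible.

Preset conditions: `separable` — 400 cells, 1,024 genes, 4 equal types, 100
markers/type at 10-fold, ~82% zeros; distinct cell types plausibly differ in
hundreds of genes, and 10-fold marker elevation models clearly separated
lineages. `imbalanced` — 500 cells with proportions (0.47, 0.28, 0.20,
0.05), weaker markers (2.5-fold) and heavier dropout (0.4), so the minority
type (≤25 training cells after an 8:2 split) is genuinely under-trained.
`sparse` — the separable conditions at 80% extra zero-inflation.
`single_class` — one type, exercising the accuracy-only metric path.

What the simulator does **not** model: batch effects, library-size
variation beyond NB noise, cell-cycle or trajectory structure, correlated
gene programs, or ambient contamination. Passing tests therefore show the
pipeline learns marker-driven class structure from sparse counts — not that
it matches real-atlas accuracy.

## Experimental protocols (desk scale)

All protocols derive per-run seeds from a base seed via
`np.random.SeedSequence`, train a fresh model per condition × replicate on
an 8:2 uniform random split, and summarise mean ± sample-std accuracy per
condition.

* **Replicated splits** (default 5): the headline accuracy estimate.
* **Permutation robustness** (4 patterns × 3 replicates): each pattern is a
  fixed random gene permutation applied to the whole matrix before
  splitting, so train and test share the layout; pattern 0 is the identity.
  A model whose accuracy is insensitive to the input ordering demonstrates
  that the attention mechanism, not the gene layout, carries the signal.
* **Patch-size ablation** (default sizes 4, 8, 16): everything fixed but P.
  The protocol uses a shared 60-epoch schedule for every condition because
  small patches mean many tokens (P=4 → 64 patches at 1,024 genes) and the
  class-token routing converges more slowly per step; the schedule is a
  protocol constant, identical across conditions.

## Numerical notes

* All computation is float64; forward passes are deterministic, and
  checkpoints (weights + JSON metadata) round-trip bit-exactly.
* Attention softmax and the loss use max-subtraction for stability;
  probabilities are clipped at 1e−12 before logs.
* LayerNorm uses eps = 1e−6 on the feature axis.
* Degenerate inputs fail loudly: zero-count cells, single-class training
  sets, unaligned gene orders and out-of-range labels all raise errors
  rather than propagating NaN or silent misbehaviour.

## Known limitations

* The desk preset is tuned for the synthetic regime; annotating a real
  atlas requires the full-scale preset, far more cells, and hours of CPU
  (the implementation is pure numpy and single-threaded beyond BLAS).
* No early stopping or validation-based model selection: final-epoch
  weights are used.
* Gene matching is exact string equality; synonym resolution is out of
  scope and must happen upstream.
* Class imbalance is reported, not corrected (an inverse-frequency loss
  weighting flag exists but is off by default, matching the reference
  protocol).
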