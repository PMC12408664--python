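# Methods

## Model

`scdrp` treats single-cell drug-response prediction as domain-adapted binary
classification. Bulk cell lines (domain g) carry labels; single cells
(domain t) do not. Both domains are embedded by denoising autoencoders
(DAEs) and the bulk-trained predictor is transferred after the two latent
distributions are aligned.

**Denoising autoencoder.** The corruption model zeroes each matrix entry
independently with probability `noise_rate` (a Bernoulli mask; the masked
entry is set to 0, never resampled). The encoder applies ReLU after each
hidden layer and a linear map into the bottleneck; the decoder mirrors the
encoder widths in reverse with ReLU hidden activations and a linear output.
Training minimizes mean squared error between the clean input and the
reconstruction of the corrupted input, full-batch Adam, fixed epoch budget.
Dropout (inverted, training-only) follows encoder hidden layers. Inference
paths (`encode`) are noise- and dropout-free.

**Predictor.** A sample's bottleneck vector is reshaped into `n_tokens`
tokens of width `token_dim` (`n_tokens · token_dim = bottleneck`). Each of
`n_heads` heads projects tokens to queries/keys/values of width
`d_k = token_dim / n_heads` and applies softmax(QKᵀ/√d_k)V; head outputs are
concatenated and mixed by W^O. No positional encoding is used — latent
features are unordered, and the block is permutation-equivariant across
tokens. The flattened result feeds an MLP ending in one sigmoid unit, so the
output is a single probability of sensitivity; the loss is mean binary
cross-entropy with scores clipped to [1e−7, 1−1e−7]. `n_heads = 0` bypasses
attention entirely (the zero-head arm of the head-count sweep).

**Alignment losses.** The squared MMD between latent samples uses the biased
V-statistic mean k(x,x′) + mean k(y,y′) − 2 mean k(x,y). The default kernel
is a multi-scale RBF: bandwidths are the median pooled pairwise *squared*
distance scaled by {0.25, 0.5, 1, 2, 4}, recomputed per mini-batch and
treated as constants in the gradient (standard practice). A linear kernel
(closed form ‖mean difference‖²) is available for testing and ablation. The
cluster regularizer assigns each cell to a Louvain community of the kNN
graph (k = 15, symmetrized connectivity, Euclidean metric in latent space)
computed **once** after the single-cell DAE stage and held fixed — the
regularizer is the mean over cells of 1 − cos(embedding, cluster centroid),
bounded in [0, 2]. Recomputing clusters during training would make the
objective non-stationary and the run non-deterministic.

**Joint phase.** The composite objective L_class + ω·MMD² + θ·R_cluster is
minimized over E_g, E_t and P (decoders frozen) by mini-batch Adam; each
step draws independent same-size batches from the two domains. Defaults
ω = 0.25, θ = 0.1: ω large enough that the MMD term visibly closes a planted
domain gap, small enough not to crush the class signal; θ an order of
magnitude below the class loss scale. Both are exposed and swept in tests.
The logged per-step trace satisfies total = class + ω·mmd + θ·regularizer
exactly (the three scalars are logged from the same tensors that form the
summed loss).

**Warm start.** With independently initialized DAEs the two latent spaces
are related by an arbitrary rotation; MMD aligns *distributions*, not class
correspondence, so transfer can land the predictor on a flipped or rotated
embedding. `transfer_adapt(..., warm_start=True)` initializes E_t/D_t from
the trained E_g/D_g before the single-cell reconstruction fitting, keeping
the two encoders in a shared basis so the MMD term only has to close the
domain gap. The core API defaults to independent initialization; the
synthetic pipeline wiring (`scdrp.pipeline`) enables warm start because the
generator plants a genuine affine domain shift that alignment is meant to
close, not an arbitrary basis change.

**Binarization.** Scores ≥ 0.5 → sensitive (the boundary value is assigned
to the sensitive side; a tie rule must be pinned and the sensitive interval
is written as the closed upper interval). Binarization is interpretation-
only: AUC and average precision are computed from raw scores.

## Preprocessing

QC on raw single-cell counts, strict thresholds, fixed order: (1) drop cells
detecting < 200 genes, (2) drop genes detected in < 3 cells, (3) drop cells
with > 10% mitochondrial counts (gene-id prefix match, default `MT-`,
case-insensitive). The order is pinned because it changes the marginal
removal counts; the QCReport records order, thresholds and counts.
Normalization scales each cell to `target_sum` (default 1e4, the community
convention) and applies ln(1+x). Class balancing (bulk training data only,
never test data, never single-cell data) offers duplication oversampling and
SMOTE (synthetic points x_i + u·(x_nn − x_i), u ~ U(0,1), among the k = 5
Euclidean nearest minority neighbors). Splits are stratified 80/20.

## Evaluation

Precision, recall and F1 are reported for the sensitive class at threshold
0.5 with a metric = 0 convention (plus warning) for empty denominators.
AUC-ROC uses the Mann–Whitney rank statistic with midrank tie correction;
average precision is the step-sum Σ_k (R_k − R_{k−1}) P_k over descending
score thresholds with ties grouped. Both are verified against brute-force
pair-counting / threshold-enumeration oracles to 1e−12 in the test suite.
The harness offers repeated stratified k-fold cross-validation (mean ± std
across repeats) and an attention-head sweep on identical splits and seeds.

## Interpretation

DEGs between predicted classes: two-sided Wilcoxon rank-sum per gene,
Benjamini–Hochberg adjustment, ranked by adjusted p then |Δ mean log
expression|, with a 0.25 minimum absolute log-fold-change. Gene-set score:
per-cell mean of per-gene z-scored expression (zero-variance genes
contribute 0 with a warning). The random-gene-set null recomputes the
predicted-vs-true gene-score Pearson correlation for `n_trials` (default
1,000) size-matched uniform random gene sets and reports the add-one
estimator p = (1 + #{null ≥ observed}) / (1 + n_trials) — valid, never
exactly zero, and able to reach p < 0.001 at 1,000 trials.

Integrated gradients attribute F(x) = P(E_t(x)) to genes along the straight
path from a zero-expression baseline, approximated by a composite trapezoid
rule. The trapezoid rule (not a one-sided Riemann sum) is a deliberate
numerical choice: between ReLU kinks the integrand is smooth and the
trapezoid error falls as O(1/m²), whereas a one-sided sum carries an O(1/m)
endpoint bias that would need ~10⁴ steps to meet a 1% completeness
tolerance; in practice m = 1000 keeps every cell's completeness residual
|ΣIG − (F(x) − F(b))| under 1%·|ΔF| + 1e−4, and the default m = 50 suffices
for ranking. Key genes per predicted class are ranked by class-oriented
signed mean attribution (descending for sensitive, ascending for resistant):
a magnitude ranking would conflate the two directions, since a strongly
resistance-associated gene has a large-magnitude *negative* attribution in
sensitive cells.

## Synthetic data

The generator emulates the structure the method assumes, not a full
scRNA-seq simulator. K latent factors per sample; factor 0 is the
sensitivity axis and loads **only** the planted marker genes (+`effect_size`
for sensitive markers, −`effect_size` for resistant); remaining factors load
sparsely (30% density, N(0,1)) on non-marker genes, so `effect_size = 0`
leaves no label signal anywhere. Labels threshold factor 0 plus N(0, 0.1²)
noise at the empirical quantile hitting the target class share exactly
(rounding aside) — the small label noise is the generator's definition of
"the label follows the planted axis". Bulk expression is loadings·factors +
per-gene baseline U(2, 6) + N(0, 1) noise, clipped at 0, on a continuous
log-expression scale. Single-cell expression applies a per-gene affine
distortion (shift ~ `domain_shift`·N(0,1), scale ~ exp(0.1·`domain_shift`·
N(0,1))) to the shared signal, then Poisson count noise and Bernoulli
dropout at `dropout_rate` — integer counts ready for QC/normalization.

What this does *not* emulate: realistic library-size variation, batch
effects beyond the single planted shift, doublets, gene–gene correlation
structure beyond the factor model. Passing recovery tests therefore show
the pipeline recovers the structure it assumes under controlled noise — not
performance on real tumor data.

Reference conditions used by the tests and the acceptance script: 300
genes, 400 bulk samples, 400 cells, 10 latent factors, 10 markers per
class, effect size 3, domain shift 1 (2 for the ablation contrast), dropout
0.3, balanced classes. The pipeline architecture for these runs (bottleneck
32, one 64-unit encoder layer, 4 tokens × 4 heads, 150/200/40 DAE /
pretrain / joint epochs) is sized to the 300-gene problem; the real-data
defaults in `scdrp.config` (bottleneck 512, encoder [256, 128], predictor
[128, 64], dropout 0.3, 500 epochs) follow the published hyperparameter
table for the primary cisplatin dataset.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` seeded per stage
  (`config.stage_seed` hashes master seed + stage name); identical seeds
  give bit-identical runs, including SMOTE, noise masks, batch draws and
  Louvain clustering.
- The corruption probability is read as "probability of zeroing" — the
  natural reading for masking noise on expression data.
- Degenerate inputs are errors, not silent fixes: zero-total cells at
  normalization (QC first), empty matrices after QC, empty gene
  intersections, single-class inputs to balancing/AUC/AP, non-finite
  training losses (reported with epoch and component values).
- Gene alignment between domains is an exact-id inner join in bulk order;
  no case folding or symbol mapping is attempted.
- Checkpoints store parameter arrays plus a JSON config; save/load
  round-trips are bit-exact.

## Limitations

- MMD aligns marginal latent distributions; with strong class-ratio mismatch
  between domains the aligned map can still mislabel a minority mode.
  Warm start mitigates but does not remove this.
- The cluster regularizer assumes Louvain communities computed once on the
  initial single-cell latents remain meaningful as E_t trains; drastic
  latent drift during the joint phase would stale them.
- The numpy autodiff core is single-threaded and full-precision; it is sized
  for hundreds-of-genes problems and the published architecture scale, not
  genome-wide matrices with tens of thousands of cells.
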