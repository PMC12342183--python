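# Methods

## Preprocessing

Raw counts (cells × genes) pass through three stages.

*Quality control* removes cells expressing fewer than 5 genes and genes
expressed in fewer than 5 cells. Both filters are evaluated on the input
matrix and applied **jointly in one pass** — filtering is deliberately
not iterated to a fixed point, so a gene that drops below threshold only
because low-coverage cells were removed is still kept. A consequence is
that QC is idempotent.

*Normalization* scales each cell to the median pre-scaling library size
and applies log1p. The median target makes normalization
scale-equivariant across datasets without introducing an arbitrary
constant.

*Variable-gene selection* ranks genes by normalized dispersion on the
log data: moments are computed on the de-logged values, dispersion =
variance/mean is z-scored within equal-frequency mean bins (at most 20
bins, at least 10 genes per bin), and the top 3000 genes are kept in
input order. Two numerical safeguards matter in small or degenerate
inputs: each bin's dispersion spread is floored at 5% of the global
spread, so bins of near-identical dispersions cannot amplify noise into
large z-scores, and zero-variance genes score −∞, so a constant gene can
never displace a variable one. Ties break toward the lower gene index.

*Graph construction* connects each cell to its k = 15 nearest other
cells by cosine distance and symmetrizes by union (A ∨ Aᵀ), zero
diagonal. Union keeps every cell's own choices as positives in both
directions; note that a popular "hub" cell may end with degree above 2k
(the mean degree is bounded by 2k, each row by ≥ k). Cosine distance
makes the graph invariant to per-cell scaling. Ties in distance break
toward the lower cell index, so construction is deterministic.

## Augmentation

Each training step draws two independent Bernoulli(0.5) zero-masks of
the expression matrix; surviving entries are rescaled by 1/(1−rate)
(inverted dropout), which keeps every entry's expectation equal to its
observed value. Plain zero-masking is available via `rescale=False`.
Masks are keyed on (seed, epoch, view): deterministic under a fixed
seed, fresh every epoch. The graph is never perturbed. At evaluation
time (final embeddings, APS refresh, attribution) the mask rate is
treated as zero.

## Encoder and heads

The encoder input is a learned linear projection of the p-dimensional
expression row to d = 32 (the attention operator is defined on
d-dimensional inputs, so the first layer needs an input embedding).
One multi-head graph attention layer (4 heads, d_k = 8) follows: per
head, node i attends over its neighbors plus itself with scaled
dot-product weights; self-loops exist **only inside attention** — the
contrastive neighborhoods keep the zero-diagonal adjacency, so an anchor
is not double-counted as its own positive. Head outputs are
concatenated, linearly mixed, and passed through residual + LayerNorm,
a 2d-wide ReLU feed-forward block, and a second residual + LayerNorm.

Both views are encoded by structurally identical encoders sharing
parameters (a Siamese pair; `tied_encoders=False` gives independent
copies). Two 2-layer ReLU perceptrons sit on the encoder output: the
instance head d → d → 32 producing z, and the cluster head d → d → M
ending in a row softmax producing soft labels Y. The head widths are a
design choice — the architecture is stated here precisely so deviations
are visible. Initialization is fan-in uniform, seeded.

Because there is no GPU framework underneath, the package carries its
own reverse-mode autodiff engine (`autodiff.py`) over float64 numpy
arrays, with exactly the primitives the model needs, plus Adam. All
gradients are finite-difference checked in the test suite.

## Losses

Instance level (anchor z_i in one view, temperature τ = 0.5): the
numerator holds the cross-view self plus every graph neighbor in both
views; the denominator sums over all cells in both views **including the
anchor's same-view self term** (cosine 1). That self term is kept
because the objective is implemented exactly as defined; the
conventional variant that drops it is available via `exclude_self`.
No normalization by the number of positives is applied. The loss is
averaged over cells and views.

Cluster level: the M columns of Y act as cluster representations; each
column is contrasted against its counterpart in the other view, with the
denominator spanning both views' columns (again including the same-view
self term, same flag). Averaged over clusters and views.

Entropy regularizer: L_reg = log M − H(Y) where H is the entropy of the
per-view normalized cluster masses, averaged over the two views. Under
this convention L_reg ∈ [0, log M], equals 0 exactly at uniform masses
and log M when all mass sits in one cluster — matching the stated
purpose of the bound. A variant normalizing the 2M masses of both views
jointly as one distribution is available via `joint_view_entropy`; as a
single distribution over 2M outcomes its entropy can exceed log M, so
the value can then be negative at uniformity.

All softmax-style ratios are evaluated in log space with
max-subtraction (`masked_logsumexp`), so extreme temperatures do not
overflow. Total loss: L = α·L_ins + (1−α)·(L_cls + L_reg), α = 0.5.

## Adaptive positive sampling

Smoothed soft labels g = Ã·(Y⁽¹⁾+Y⁽²⁾)/2, where Ã is the row-stochastic
random-walk normalization of (A + I). Normalization is a deliberate
choice: an unnormalized summation would scale g by node degree, pushing
the cosine similarities of high-degree nodes together and breaking the
simplex interpretation of g (argmax assignment). The unnormalized
variant is exposed as `normalize="none"`.

The agreement graph Â keeps pairs with cos(g_i, g_j) ≥ λ (default
λ = 0.9 — a deliberately strict threshold appropriate for
probability-simplex vectors, where same-cluster pairs concentrate near
cosine 1; configurable, and worth re-examining on data with many
clusters). Â is evaluated lazily on KNN edges only; after the
intersection A_final = A ⊙ Â the result is identical to the dense
evaluation. λ = −1 recovers A exactly; the edge set is monotone
non-increasing in λ.

Schedule: during the first 20% of the epoch budget the unfiltered A
supplies positives (early soft labels are uninformative); afterwards
A_final is recomputed once per epoch from a mask-free full-graph forward
pass. Warm-up fraction and refresh period are configuration keys; the
schedule is a declared design choice, not a property of the objective.

Pair-sampling quality is scored over the universe of KNN-candidate pairs
(i < j, A_ij = 1) — the only pairs APS adjudicates: PPV is the fraction
of kept pairs that are truly same-type, NPV the fraction of dropped
pairs that are truly different-type; empty denominators yield NaN.

## Training

Adam, learning rate 0.001, no weight decay or schedule, up to 500
epochs by default. Cells are shuffled each epoch into induced-subgraph
mini-batches (64 below 1000 cells, 256 to 2000, 512 to 10 000, 1024
above; a trailing singleton merges into its predecessor). Contrastive
denominators are **batch-local**, so the loss scale depends on batch
size, and full-batch and mini-batch training coincide exactly once the
batch covers all cells. Final labels are the argmax of the smoothed g
(lowest index on ties), not of the raw Y — smoothing is what makes the
assignment robust to single-cell noise. All randomness (initialization,
masks, batching) derives from one root seed, so runs are bit-for-bit
reproducible.

Model selection: the cluster number M is chosen by training a
short-budget model (100 epochs) per candidate and picking the M with the
highest mean silhouette of the hard labels on the encoder embeddings h
(Euclidean; space configurable to z or g); ties prefer smaller M. The
neighbor count k is chosen unsupervised as the candidate minimizing the
final training loss.

## Interpretation

Integrated gradients attribute the **pre-softmax** cluster-head score of
each cell's assigned cluster (pre-softmax avoids saturation) to its
genes, integrating along the straight path from a zero-expression
baseline (a mean-cell baseline is available) with a right Riemann sum,
50 steps by default. Only the focal cell's row is interpolated; the
graph and all other cells stay fixed. With a single attention layer only
the focal cell's encoder row feeds its score, so all steps batch as rows
of one star-attention forward pass — exact, and two orders of magnitude
faster than per-step subgraph passes (which remain the fallback for
deeper encoders and are tested to agree to machine precision).

The completeness identity Σ_genes IG = F_c(x) − F_c(baseline) holds in
the many-steps limit with O(1/T) error; it is exact at any step count
for a linear model. For cells whose score difference is near zero the
*relative* residual is not meaningful, so aggregate completeness is
reported as Σ|residual| / Σ|ΔF| over cells (≈0.7% at 200 steps on the
trained benchmark model).

Reference markers come from a one-vs-rest Wilcoxon rank-sum test per
gene with Benjamini–Hochberg adjustment within each group, filtered at
q ≤ 0.01 and log fold-change ≥ 1 (difference of group means on the log
scale), ranked by fold-change, top 200 per group. This is an in-package
implementation of the classic marker recipe; it is not expected to
reproduce any particular external tool's output numerically. Attribution
and marker lists are compared by plain intersection counts.

## Synthetic benchmark

The generator plants recoverable structure in a splatter-like skeleton:
uniform cluster assignment; per-gene baseline mean multiplied by 2^lfc
on the cluster's markers (marker sets disjoint across clusters, so
attribution tests are unambiguous); a lognormal per-cell library factor;
negative-binomial counts via a Gamma–Poisson mixture (variance
μ + μ²/r); independent Bernoulli dropout. The canonical benchmark is
400 cells × 500 genes, 4 clusters, 25 markers/cluster at lfc 2.5, 30%
dropout, seed 7. The unpinned parameters were fixed once at base mean
2.0, dispersion 2.0, library CV 0.3, giving ≈48% zeros — droplet-like
sparsity — while keeping every cell and gene above the QC thresholds.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, trajectories/continuous states, gene–gene correlation beyond
cluster structure, or empirically calibrated mean–dispersion
relationships. Passing the benchmark therefore demonstrates that the
implementation optimizes its objective and recovers well-separated
discrete populations; it does not certify performance on real tissue
atlases.

Benchmark experiments (tests and the acceptance script) train for 200
epochs — on this 400-cell problem the metrics saturate well before that,
so the shorter budget is the package's declared problem size for its own
experiments; the `TrainConfig` default remains 500.

## Known limitations

- The numpy autodiff engine is single-threaded and dense; attention is
  O(n²) per batch. Practical up to a few thousand cells per batch, not a
  GPU replacement.
- λ is fixed, not learned; positives are binary, not
  confidence-weighted.
- The entropy regularizer balances cluster masses; on datasets with
  genuinely rare populations a milder weight may be needed.
- Silhouette-based M selection inherits silhouette's bias toward
  compact, balanced clusters.
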