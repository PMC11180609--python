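# Methods

This note documents the modeling and numerical choices in `perturbgraph`,
what the bundled simulator does and does not emulate, and the known
limitations. It complements the README's model overview; nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and normalization

A `PerturbDataset` holds an N×K log-normalized expression matrix, one
perturbation set per cell, and canonical condition keys (`"ctrl"`, or the
sorted `"+"`-join of target names, so `A+B ≡ B+A`; the public
`"GENE+ctrl"` dialect for singles is accepted on input). Loading accepts
H5AD (AnnData: X, an `obs` condition column, `var` gene names) and
MatrixMarket triplet directories. Integer-valued matrices are treated as
raw counts and normalized to counts-per-10k per cell followed by log1p —
standard scRNA-seq practice; float matrices are taken as already
normalized, because double-normalizing is a worse failure mode than
trusting the provider. Perturbation targets without an expression column
(possible for activation screens) are retained in perturbation sets and
receive perturbation embeddings, but are excluded from expression-space
metrics.

Differential expression for a condition is the mean expression of its
cells minus the control mean ("delta"), and DE ranking is by |delta| with
ties broken by gene index. This is deliberately the simplest rule
consistent with "most differentially expressed"; a rank-test-based
definition would change which genes enter the top-20 metric sets but not
the machinery, and the ranking function is isolated in one place
(`data.rank_de_genes`).

## Splits

Splits hold out whole conditions (never individual cells of a kept
condition). `mode="single"` holds out single-gene conditions;
`mode="combo"` additionally holds out two-gene conditions. Each two-gene
test condition is labeled by how many of its genes appear as targets
anywhere in the realized training set (0/1/2 of 2 unseen); a held-out
single's gene is guaranteed not to appear inside any training combo
(such combos are dropped from training). Splits are pure functions of
the dataset and a seed.

## Graphs

* Coexpression: Pearson correlations over training cells only; per gene,
  edges from the top `H_gene` correlated genes with ρ > δ, edge weight ρ.
  Zero-variance genes correlate 0 by definition (never NaN).
* Pathway similarity: Jaccard index of shared pathway-term annotations
  from any two-column gene↔term TSV; per gene, top `H_pert` neighbors,
  zero-weight edges dropped. Real GO slim exports plug into the same
  interface; the simulator provides a synthetic ontology so nothing needs
  downloading.

Defaults `H_gene = H_pert = 20`, `δ = 0.1`: moderate connectivity that
keeps one-hop message passing informative at the bundled scale; all
config-exposed. Top-H selection tie-breaks by (−similarity, gene index)
for bit-reproducibility. Edges are stored directed (u → its selected
neighbors) and aggregation flows neighbor → u.

## Network architecture

Defaults: embedding dimension d = 64; one graph-convolution layer per
graph, `h_u = ReLU(W_self x_u + Σ_v a_uv W_nbr x_v + b)` with `a_uv` the
edge weights normalized to sum to 1 over u's neighbors (a flag ignores
weights); MLPs are 2-layer ReLU with hidden width d. One layer matches
the one-hop semantics of both graphs and keeps the forward pass simple
enough to verify against a hand-rolled oracle; depth is configurable.
The per-gene decoder heads follow the README: scalar effect, cross-gene
conditioning (w ∈ ℝ^{d+1} over the concatenation of the gene's scalar
and the cell embedding), and a log-variance head.

Control conditions bypass the network entirely — the prediction for
`"ctrl"` is the control profile itself — because the network models
perturbation effects, not baseline expression.

The scalar uncertainty of a prediction is the mean log-variance over the
20 genes with the largest predicted |effect| (mirroring the autofocus
emphasis on DE genes); mean over all genes is available behind a config
switch.

## Losses and training

* Autofocus: `|g − ĝ|^(2+γ)`, γ ≥ 0, default γ = 1. The magnitude
  convention is required: raw signed powers are ill-defined for
  fractional γ and sign-canceling for odd integer γ, and a loss must be
  non-negative. γ = 0 recovers exact MSE (asserted to 1e-12).
* Direction: squared sign mismatch of the delta over control, per-gene
  terms ∈ {0, 1, 4}, `sign(0) = 0`, weight λ = 0.1 default. The
  normalizer is per-gene (1/K), the same averaging as the other losses.
  Being piecewise constant it contributes no gradient; it acts as a
  monitored value-level penalty.
* Uncertainty: `exp(−s)·|g − ĝ|^(2+γ)` plus a `mean(s)` regularizer;
  without the regularizer the objective is unbounded below in s (the
  heteroscedastic Gaussian formulation this mirrors carries the same
  term). Enabled via `use_uncertainty`; the default objective is
  autofocus + λ·direction, with the heteroscedastic variant supported as
  an alternative since either reading is defensible.

Optimization is Adam (lr 1e-3) on a tape-based reverse-mode autodiff
engine over numpy (float64). Gradients of every loss are verified against
central finite differences through the full network. Minibatches sample
perturbation conditions, then 8 cells per condition, pairing each
perturbed cell with a random control cell. Training is seeded and
single-thread deterministic; optional early stopping restores the best
validation parameters.

**Node-embedding dropout.** With probability 0.3 per step, a
perturbation node's raw embedding is zeroed before message passing.
A dropped node must be predicted from its pathway neighbors alone —
exactly the regime a never-perturbed gene faces at test time. Without
this, the network overfits each trained perturbation to its own
embedding and generalizes poorly to unseen targets; with it, held-out
recovery roughly doubles in the bundled benchmark. Defaults (600 epochs,
full-condition batches) were sized so one training run takes seconds to
tens of seconds on one CPU core at the simulator's default scale.

## Evaluation

Metrics compare predicted and measured condition summaries: MSE over the
measured condition's top-20 DE genes (also normalized per condition to
the no-perturbation baseline, which therefore scores exactly 1); Pearson
correlation of deltas over all genes (zero-variance guard returns 0);
fraction of top-20 DE genes with the wrong predicted sign; Jaccard
overlap of predicted vs true top-20 DE sets. DE gene sets for metrics
always come from measured data, except the predicted side of the DE-set
Jaccard, which is model-derived by definition. Normalization is per
condition (a global-ratio variant is flagged). Aggregates are mean ±
1.96·SEM across conditions, stratified by generalization class, and
`aggregate_reports` pools multiple trained models the same way.

## Baselines

* No-perturbation: predicts the control mean everywhere.
* Additive: combo delta = sum of the two measured single deltas.
* Linear GRN propagation: per-target ridge regression of each gene on
  all others over training cells, keeping the top-20 coefficients per
  gene; a perturbation is an initial shift of +1 training SD on each
  target (sign-flippable for knockdown screens) propagated as
  `(I + W + … + W^p)·shift`, p = 3 by default to capture second-order
  effects. This is a self-contained linear surrogate in the
  shift-then-propagate style of network-based simulators; it is not a
  reimplementation of any specific published GRN inference method.

## Genetic-interaction scoring

Each pair is fit by least squares, `δ_ab ≈ c_a·δ_a + c_b·δ_b`, over the
union of the three conditions' top-20 DE genes. The subtype scores are
reconstructions of the regression-based interaction framework used for
combinatorial CRISPRa screens — magnitude, model fit, equality of
contribution, dominance — with every formula isolated in one function
(`gi._subtype_scores`) and all thresholds config-exposed so alternative
definitions drop in:

* synergy = ‖(c_a, c_b)‖₂, suppression = its negative;
* neomorphism = −corr(fitted, actual);
* redundancy = corr(δ_a, δ_b) − max(0, ‖(c_a,c_b)‖ − √2), i.e. similar
  singles penalized when the combo is super-additive;
* epistasis = |‖c_a‖ − ‖c_b‖| / ‖(c_a, c_b)‖ (dominance).

Pairs with near-zero or collinear singles (|corr| > 0.995) are flagged
degenerate and excluded from rankings rather than scored unstably. Truth
labels for ranking benchmarks default to each score's upper decile
across measured pairs (config-exposed); rankings are assessed by
precision@k, top-k accuracy and PR curves, calibrated against a
1,000-draw random-ranking null whose precision@k matches the analytic
m/n expectation.

## The simulator

`simulate(SimConfig())` draws: a synthetic ontology (12 pathways, each
gene annotated to one pathway by default, density configurable); a
latent effect direction per pathway; per-gene true effect vectors
`√s·(pathway latent) + √(1−s)·private` with neighbor-sharing s = 0.9 by
default, entries on the scale of 0.2 log-units; 40 single and 30 double
conditions (50 cells each), 500 control cells, and Gaussian log-scale
noise σ = 0.2. Five pairs per subtype are planted among the doubles
(synergy 2×, suppression 0.25×, neomorphism 0.5× plus an equal-norm
novel direction, redundancy as same-pathway near-duplicate singles with
a 0.55× combo, epistasis as the name-sorted first gene masking the
other); the rest are exactly additive. The default sizes train in
seconds-to-minutes on one CPU; the default sharing strength makes the
pathway graph genuinely informative, which is the regime the
graph-based generalization claim is about — at s = 0 the graph carries
no signal and no method could recover unseen effects.

What the simulator does **not** emulate: dropout/zero inflation, batch
effects, cell-cycle structure, guide-assignment errors, heterogeneous
postperturbation distributions, or library-size variation (an optional
negative-binomial counts layer exists only to exercise the raw-counts
reader). Passing the bundled benchmarks therefore demonstrates that the
machinery is correct and that the inductive bias works when the
assumed gene–pathway structure holds; it does not guarantee comparable
accuracy on real screens, where that structure is noisier and the
confounders above are present.

## Numerical conventions and degenerate inputs

float64 throughout; correlations guard zero variance by returning 0;
DE ties break by gene index; top-H graph ties break by (−similarity,
index); `sign(0) = 0`; empty perturbation sets are valid only as
controls; a dataset without control cells records a warning and refuses
delta computations; checkpoint loading verifies a hash of the gene list.
Seeds fully determine the simulator, splits, initialization, and
training on a single thread.

## Known limitations

* Transfer across cell types or experimental conditions is out of scope;
  train and predict within one screen.
* The direction loss is gradient-free by construction; it shapes model
  selection only through its monitored value.
* GI subtype formulas are reasonable reconstructions, not canonical
  definitions; treat absolute scores as rankings, not calibrated
  quantities.
* The GRN baseline's inference is a deliberately simple ridge surrogate;
  it bounds what linear propagation can do here but should not be read
  as representative of the best network-inference methods.
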