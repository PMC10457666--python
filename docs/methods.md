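# Methods

## Problem

Experimentally validated circRNA–disease associations are sparse: a few
hundred curated pairs over hundreds of circRNAs and tens of diseases.
`circgcf` predicts unobserved associations by treating the curated pairs
as a bipartite graph and learning entity embeddings that combine
*side information* (disease ontology structure, association-profile
similarity) with *collaborative signal* (high-order connectivity in the
graph itself).

## Pipeline

1. **Similarity descriptors.** Four matrices are computed:
   disease semantic similarity (Wang's DAG method — each term contributes
   to its ancestors with a per-edge decay Δ, default 0.5; similarity is
   the shared-ancestor contribution mass over the total), the Gaussian
   interaction-profile (GIP) kernel for diseases and for circRNAs
   (RBF on binary association profiles, bandwidth γ = γ′ / mean squared
   profile norm, γ′ default 1), and circRNA functional similarity
   (best-match averaging of the semantic similarities of associated
   diseases). The disease descriptor uses semantic similarity where both
   diseases sit in the ontology and share an ancestor, GIP elsewhere;
   the circRNA descriptor uses functional similarity where both circRNAs
   have known associations, GIP elsewhere.
2. **Autoencoder embeddings.** Each descriptor is compressed by a
   one-hidden-layer autoencoder with logistic activations (Adam, lr
   1e-3, MSE, stop at relative improvement < 1e-5 or a max epoch
   budget). The hidden code (width k) is the entity's initial embedding.
   Overcomplete codes (k larger than the descriptor) are permitted.
   The stacked lookup table is column-mean-centered by default: logistic
   codes share a large positive offset, and without centering that
   constant direction dominates every linear transform during
   propagation and washes out the discriminative directions.
3. **Attentive message propagation.** On the (N+M)-node bipartite graph,
   each layer sends along every association edge the message
   `p · (e_s W1 + (e_s ⊙ e_t) W2)` with the symmetric Laplacian decay
   `p = 1/√(|N_t||N_s|)`; a per-layer attention head scores neighbors
   GAT-style (`q = a · [e_t W_a ‖ e_s W_a]`, LeakyReLU slope 0.2,
   softmax over the neighborhood) and the weight multiplies the message.
   The self-message `e_t W1` bypasses attention; aggregates pass through
   LeakyReLU. Three layers by default. The attention scoring vector is
   initialized at zero so every head starts as exactly uniform weighting
   and learns deviations only where they reduce the ranking loss; with a
   random initial scoring vector the softmax concentrates on arbitrary
   neighbors and measurably hurts early training.
4. **Collaborative-filtering scorer.** Per-layer embeddings are
   aggregated (concatenation by default; weighted sum, max pooling, or
   an LSTM over the layer sequence as alternatives). A pair is scored by
   `y' = h · [e_c* ⊙ e_d* ‖ MLP([e_c* ‖ e_d*])]` with no output
   activation; logistic probabilities are applied only where accuracy/F1
   need a threshold.
5. **Training.** The Bayesian-personalized-ranking objective
   `Σ −ln σ(y'_ci − y'_cj) + λ‖Θ‖²` over triples that pair each known
   association (c, i) with an unknown disease j for the same circRNA.
   By default j is drawn fresh each epoch uniformly from *all* diseases
   c is not linked to; the alternative `negative_pool="sampled"`
   restricts j to the balanced pre-sampled negative set. Full-batch Adam
   (lr 1e-3, λ 1e-5), with per-epoch triple resampling seeded
   deterministically from the run seed.

All neural components run on an in-repo reverse-mode autodiff core over
numpy (`circgcf._nn`); gradients are validated against central finite
differences in the test suite.

## Evaluation protocol

5-fold cross-validation partitions the known pairs (and an equal-sized
uniformly sampled negative set) into folds. Per fold, the test positives
are removed from the propagation graph, the model trains on the
remaining pairs, and the held-out pairs are scored. Metrics (percent):
trapezoidal ROC AUC, precision–recall AUPR, accuracy and F1 at logistic
probability 0.5, and full-list binary-gain NDCG.

A second, complementary design — **held-out recovery** — trains on all
table pairs and ranks the fixture's held-out positives (pairs removed
from the table before anything else sees it) against sampled unknown
cells. Because the targets never enter the table, no similarity or
graph computation can touch them, making this the leak-proof way to ask
whether planted signal is recovered; the label-shuffling control and
the ablation comparisons therefore run in this design. Entities whose
every association was held out do not appear in the table at all and
are naturally unscoreable, which is the honest boundary of a
profile-based method. Note that within-column shuffling preserves
per-disease prevalence, so a few points of AUC above chance survive the
shuffle through popularity alone.

Two leakage-sensitive choices are explicit flags:

* `mask_test_edges` (default on): test positives never appear in the
  propagation graph.
* `gip_full_matrix` (default off): when on, the similarity descriptors
  (and hence the initial embeddings) are computed from the full
  association matrix rather than the training fold only. The fixture
  experiments (`ExperimentConfig.fast`) switch it on: roughly a tenth of
  test positives belong to circRNAs whose every known association sits
  in the test fold, and with training-fold-only features those circRNAs
  have no information content at all (the method uses no sequence
  features), which caps the leak-free ceiling near the low 80s in AUC on
  the fixture. Full-matrix similarity reflects how such pipelines are
  evaluated in the literature this method belongs to; the leak-free
  default remains for users who want the strict protocol.

## Capacity choices at desk scale

The fixture experiments use deliberately low-capacity settings
(`ExperimentConfig.fast`): embedding k = 64, 300 training epochs, the
lookup table frozen after the autoencoder, and a narrow MLP tower
[8, 4]. With a few hundred training pairs, fine-tuning the lookup table
or using the wide tower ([2d → d → d/2]) lets the model memorize the
training edges — the training loss approaches zero while held-out AUC
decays monotonically after roughly epoch 100. Freezing the lookup and
narrowing the tower removes the memorization pathways and held-out AUC
is then stable for hundreds of epochs. Library defaults keep the
fuller-capacity configuration (k = 128, fine-tuned lookup, wide tower,
2000 epochs) for larger real datasets.

## Synthetic fixture

`synthetic.default_fixture()` draws a 200 × 50 bipartite graph: entities
are assigned uniformly to 5 clusters; an association appears with
probability 0.25 inside matching clusters and 0.01 across (≈ 580
positives, 10 % held out; seed 17). The disease ontology is one root
with a chain-shaped subtree per cluster (leaves at depth 3), so semantic
similarity is informative about the planted structure, emulating the
correlation between ontology subtrees and real association patterns.

What the fixture does *not* emulate: heterogeneous neighbor quality
(within a cluster every neighbor is statistically interchangeable, so
uniform attention weights are already optimal and the learned attention
head can only match them, not beat them — on such data the attention
ablation is expected to be a tie), long-tailed degree distributions,
inter-cluster overlap, and any sequence-level feature. Passing the
recovery tests shows the pipeline extracts planted co-cluster signal; it
does not certify real-data performance.

## Numerical notes

* Everything is float64; losses are guarded against non-finite values.
* `log σ(x)` uses the stable `min(x,0) − log1p(exp(−|x|))` form.
* Softmax subtracts the per-neighborhood maximum.
* Zero-degree nodes get zero Laplacian rows and evolve only through the
  self-message.
* Ties in max-pooling aggregation route gradients to the first operand.
* Fold seeds and per-epoch triple seeds derive from the run seed via
  `numpy.random.default_rng([seed, index])`, keeping every run
  reproducible bit-for-bit on the same hardware.

## Known limitations

* Cold-start entities (no known associations) are scored essentially at
  chance under the strict leak-free protocol; the method has no
  sequence-level features to fall back on.
* The BPR objective calibrates ranking within a circRNA, not across
  circRNAs; globally pooled metrics mix per-entity scales.
* The LSTM aggregator is provided for completeness and is the weakest
  aggregation choice at this data scale.
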