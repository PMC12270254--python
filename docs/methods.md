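# Methods

This note documents the model and procedures implemented by `trigat`, the
choices made where the design was genuinely open, the synthetic benchmark
conditions, and what the synthetic experiments can and cannot show.

## Network integration

Per-database edge lists are cleaned independently and then unioned:

1. undirected networks (PPIs) become two reverse directed edges per pair;
2. scored networks are filtered — numeric mode keeps edges with score
   *strictly greater* than the threshold; categorical mode keeps edges whose
   confidence label is in the retained set;
3. duplicate ordered pairs and self-loops are deleted (first-occurrence score
   kept; scores are only used for pre-union filtering, so the tie-break is
   inconsequential);
4. the union digraph assigns each edge a d-dimensional 0/1
   database-membership vector: column k is 1 iff cleaned database k contains
   that ordered edge.

Edges are stored sorted by (source, target) so integration is bit-for-bit
reproducible and independent of database input order (permuting the
databases only permutes the feature columns). Gene identifiers are treated
as opaque case-normalized strings — uppercased and whitespace-stripped;
mapping between identifier namespaces (symbol vs. Entrez etc.) is the
caller's responsibility and must happen before loading.

A consequence of the literal union rule: when a PPI database is symmetrized,
*both* directions of a pair receive that database's membership bit, even if a
regulatory database records only one direction. The two directed edges then
differ in their feature vectors only through the directional databases.

## Omics features and graph assembly

Expression matrices are preprocessed by averaging duplicate gene rows and
removing genes whose expression is zero in every sample; the all-zero rule is
applied to expression only, since zeros are informative in mutation or
methylation matrices. Multiple omics types are combined by concatenating
feature columns over the intersection of covered genes (no imputation).

The training graph intersects network and omics coverage: genes without
omics data are dropped with their edges, and known disease genes absent from
the surviving graph are discarded (warned). Feature columns are scaled after
the overlap; the default is per-column z-scoring because attention logits
are scale-sensitive (configurable: `none`, `zscore`, `minmax`). Whether the
raw values were log-transformed beforehand is left to the caller.

## The classifier

A node's update at one GAT view is

    α_ij = softmax_{j ∈ N_in(i) ∪ {i}} LeakyReLU( aᵀ [W x_i ‖ W x_j ‖ W_e e_ij] )
    x′_i = σ( Σ_j α_ij W x_j )

with the neighborhood = in-neighbors plus self. Conventions:

- **Self-loop edge feature.** The self term's edge vector is all-zero: a
  self-interaction is recorded in no database, and the zero vector is
  exactly that statement. Consequently the self logit has no edge term.
- **Edge orientation.** Attention at node i runs over in-edges j→i and
  `e_ij` denotes that in-edge's feature.
- **Aggregation** uses the current layer's input features (the same `x_j`
  that enter the attention logits).

A triGAT layer runs three independent (untied) parameter sets on the
original digraph G1, the reversed digraph G2 and the bidirectional graph G3,
and concatenates the three outputs. G2 edges keep the feature row of the
edge they reverse; in G3, an edge already present in G1 keeps its own row
and an added reverse edge inherits its source edge's row (reciprocated pairs
with different features each keep their own). Restricting the view set to
`("G1",)` yields the plain single-direction GAT used as the ablation
comparator.

Multi-head handling follows the standard convention: hidden layers
concatenate the K head outputs, the last layer averages them, and a final
linear map plus sigmoid produces one probability per node.

### Defaults

| parameter | default | notes |
|---|---|---|
| triGAT layers | 2 | two hops of context in each direction |
| heads K | 4 | |
| hidden width F′ | 16 | per head, per view |
| edge map width F′ₑ | = F′ | |
| LeakyReLU slope | 0.2 | attention logits |
| hidden nonlinearity | ELU | |
| dropout | 0.1 | on layer inputs, training only |
| optimizer | ADAM, lr 1e-3 | full-batch |
| early stopping | patience 20, max 1000 epochs | min-mode validation loss |

Depth, width and optimizer settings are package choices — the method itself
does not prescribe them — and all are configurable via `ModelConfig`/YAML.
"Failed to decrease" means no strict improvement over the best validation
loss so far (tolerance 0); the best checkpoint is restored at stop.

### Numerical choices

- Softmax logits are stabilized by subtracting the per-neighborhood maximum
  (treated as a constant in differentiation).
- Loss probabilities are clamped to [1e-7, 1−1e-7].
- The engine underneath is a small reverse-mode autodiff over numpy arrays;
  scatter-adds are cached sparse-matrix products, and gradients are verified
  against central finite differences in the test suite.
- Ranking ties are broken by gene id ascending, so rankings are reproducible
  regardless of hash order.

## Training protocol

Negatives equal in number to the positives are sampled uniformly from the
unlabeled genes (classes are therefore balanced and no class weighting is
used). The labeled set is split 80/20 stratified; the training part is
divided into five stratified folds; member m trains on train-minus-fold-m
and early-stops on fold m. The test set is fixed before cross-validation and
is never seen by training or early stopping. The five members' sigmoid
outputs are averaged for prediction. Re-sampling negatives under different
seeds (the replication protocol) changes only the negative labels, never the
positives.

AUROC is the Mann–Whitney statistic (ties count one half); AUPR is step-wise
average precision with no interpolation (the scikit-learn convention) — the
convention is fixed and documented here because different interpolations
give different areas on small test sets.

External validation scores a disease-gene set disjoint from everything seen
in training/testing: positives are the external genes present in the graph
minus all train/test genes; negatives are an equal-size seeded sample of the
remaining genes. Sampled training negatives remain eligible for the
whole-graph ranking by default (only known positives are excluded); a flag
can remove them.

## Synthetic benchmarks

The generator emulates the statistical structure the method assumes, not any
real database's topology or transcriptomic covariance.

**Standard benchmark** (defaults): a ground-truth digraph (Erdős–Rényi by
default, preferential attachment available) of 2000 edges over 400 genes;
40 planted disease genes chosen as a connected module (BFS core ≈ 70%) plus
a decaying sample of its 1-hop out-neighborhood; 25% of the planted genes
withheld from the known-positive list as novel-gene ground truth. Four
pseudo-databases each sample 60% of the true edges and add 5% uniformly
random false edges; alternating databases are emitted as undirected
PPI-style lists (losing direction, restored as edge pairs on integration).
Expression is iid standard Gaussian over 20 samples with an additive mean
shift of 1.0 SD on disease genes, decaying by 0.5 per directed hop up to
depth 1. Gaussian noise plus an additive shift is the simplest structure in
which the classifier's signal strength is a single controllable number.
These scales train a full five-member ensemble in well under a minute on one
CPU, which is what makes the replicated experiments below affordable.

**Upstream/downstream scenario**: genes are arranged in layers
(background-A → upstream stratum → positive module → downstream stratum →
background-B) with every edge pointing to a strictly higher layer (same-layer
edges only inside A, the module, and B). Edge orientation alone then
guarantees that upstream held-out genes reach the positives but are
unreachable from them, and symmetrically downstream — verified by explicit
graph search in the tests. All pseudo-databases in this scenario are emitted
directed, and false edges are suppressed, because either could silently
create a path that breaks the strict stratification. Conditions: 300 genes,
1500 edges, 3 databases at 70% coverage, 60 planted genes with 40% held out
(12 upstream, 12 downstream), effect size 0.75 over 12 samples — the signal
is kept moderate so that neighborhood information, not per-gene expression
alone, carries part of the decision.

**Database-count ablation**: 400 genes, 2000 edges, 4 databases at 12%
coverage each with 5% false edges, 80 planted genes, effect size 0.5 over
10 samples. Coverage is set so low that a *single* database (mean degree
≈ 1.2) leaves a large fraction of genes isolated — dropping them and their
labels from the graph — while the 4-database union restores most coverage.
That is the mechanism by which integrating databases helps: more usable
labeled genes and denser message passing. The ablation trains the full
pipeline for k = 1..4 integrated databases across 5 seeds and reports median
test AUROC per k; both ablations use a compact model (2 heads, width 8,
≤ 200 epochs) to keep the many runs cheap.

## What passing these experiments does and does not show

The synthetic experiments demonstrate mechanism, not clinical performance:
that the pipeline recovers a planted, withheld signal; that single-direction
message passing is biased toward genes downstream of the training positives
and the three-view model removes most of that bias; and that integrating
partial-coverage databases improves accuracy. Real transcriptomes have
correlated genes, batch effects and heavy tails; real databases have
hub-dominated topology and correlated (not independent) coverage. None of
these are emulated.

One behavior deserves emphasis: because planted disease genes form a
connected module, the graph *itself* carries label information. Even with
the expression shift removed entirely, held-out module members score well
above chance — they aggregate the features of adjacent training positives,
and the transductive classifier learns to recognize that neighborhood. This
guilt-by-association through network proximity is precisely the signal a
network-based prioritizer is designed to exploit, so a "no-signal" control
that only removes the expression effect is not a chance-level control; a
true null would also have to scatter the positives randomly over the graph.

## Known limitations

- Full-batch training on one CPU: graphs beyond ~10⁵ edges per view will be
  slow; there is no minibatching or GPU path.
- Negative sampling is uniform; informed negative selection strategies are
  out of scope.
- Identifier harmonization across databases is the caller's job.
- The generator's false edges are uniform random pairs, which is a weak
  model of database-specific error modes.
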