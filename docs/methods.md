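# Methods

`nemii` predicts miRNA–disease associations by integrating three views of
a miRNA–disease pair: the structure of the known-association bipartite
network (via a deep network embedding), miRNA family membership, and
disease semantic similarity derived from a MeSH-style hierarchy. A random
forest scores every unknown pair. This note records the model, its
assumptions, the defaults, and the numerical choices, so results can be
interpreted and reproduced.

## The model

**Association network.** Known associations form an m × n binary matrix
`A` (rows miRNAs, columns diseases) and the symmetric bipartite adjacency
`G = [[0, A], [Aᵀ, 0]]` over N = m + n nodes. Node order is miRNAs by
sorted identifier, then diseases by sorted identifier; the order is
carried through every derived matrix so embedding rows are attributable.
Identifier matching is exact and case-sensitive — no name normalisation —
to avoid silent mis-joins. miRNAs without family annotation and diseases
without a hierarchy record are removed, with their associations, before
modelling.

**Disease semantic similarity.** Each disease D induces an ancestor DAG:
in tree-number mode every proper dot-prefix of each hierarchy code is an
ancestor (codes owned by no studied disease still become DAG nodes,
identified by the code string, because contribution flows through the
full hierarchy); multiple codes merge into a single DAG as the union of
ancestor closures. A node d contributes

    S_D(D) = 1,    S_D(d) = max{ Δ · S_D(d′) : d′ child of d in the DAG }

with decay Δ = 0.5 by default, so S_D(d) = Δ^(shortest downward path
from d to D). The "children of d" in the recursion are restricted to
DAG_D's own node set — the standard convention, and the only one under
which S_D is well defined from DAG_D alone. With SV_D = Σ_d S_D(d), the
similarity between two diseases is the contribution mass on shared
ancestors, Σ_{d∈V_i∩V_j}(S_i(d)+S_j(d)) / (SV_i+SV_j): symmetric, unit
diagonal, zero for disjoint ancestries. Contributions are exact powers
of 0.5 computed by memoised recursion; tests compare at 1e-12.

**SDNE embedding.** A mirrored sigmoid autoencoder maps each adjacency
row x_i = G_{i,:} through encoder layers to a d-dimensional code y_i and
back to a reconstruction x̂_i, minimising

    L_mix = ‖(X̂ − X) ⊙ B‖_F² + α Σ_{i,j} G_ij ‖y_i − y_j‖² + ν L_reg

where B up-weights observed edges by β > 1 (so the sparse 1-cells are
not drowned by zeros), the first-order term (summed over ordered pairs —
each undirected edge twice, exactly as the double index is written) pulls
linked nodes together, and L_reg = ½ Σ_k (‖W^(k)‖² + ‖Ŵ^(k)‖²). Training
is full-batch Adam with analytically derived gradients in numpy; at the
few-hundred-node scale of this problem full batch is both faster than
minibatching and bit-reproducible under a fixed seed. Degree-zero nodes
(possible after fold-wise edge removal) enter as all-zero rows and pass
through untouched — no special casing.

Defaults: d = 128, hidden widths [max(256, 2d), d], α = 0.05, β = 5,
ν = 1e-4, 200 epochs, learning rate 1e-3, following the ranges reported
for the original SDNE architecture. These suit networks of several
hundred nodes and more. For the ~100-node synthetic study networks the
package uses an explicit small-network profile
(`SDNEConfig.small_network()`: d = 16, hidden [64, 16], α = 10,
lr = 1e-2, 800 epochs) selected from convergence diagnostics — the
paper-scale step size barely moves the loss on so small a graph, and the
stronger first-order pull is what produces cluster-structured codes on a
sparse SBM. All values are exposed in configuration.

**Baseline embedders.** Laplacian Eigenmaps solves L v = λ D v and keeps
the d eigenvectors of smallest nonzero eigenvalue (normalised YᵀDY = I);
disconnected graphs are embedded per component with eigenpairs pooled by
ascending eigenvalue and isolated nodes placed at the origin, with a
warning. HOPE factorises the Katz matrix S = (I − βₖG)⁻¹βₖG by truncated
SVD into d/2 source and d/2 target factors concatenated per node (d must
be even); βₖ defaults to half the divergence threshold 1/ρ(G). Both are
deterministic. Random-walk embedders are deliberately out of scope.

**Pair features and classifier.** A pair (i, j) is the concatenation
[Z_{i,:} | SS_{j,:} | NE_{i,:} | NE_{m+j,:}] with blocks toggled by the
five combination schemes (1: embedding only; 2: family + similarity;
3: embedding + family; 4: embedding + similarity; 5: all). No feature
scaling is applied — trees are scale-invariant. The classifier is a
random forest, 350 trees, sqrt(width) features per split, unlimited
depth by default (depth is exposed in configuration; capped depth gives
better-calibrated leaf probabilities when thresholded recall matters,
and is used for the recovery experiment). The weighted variant assigns
class weights w_i = n_samples/(2·n_i) — for two classes exactly the
"balanced" convention — which shifts scores toward the minority class;
it changes calibration far more than ranking. A pair's score is the mean
per-tree probability of the positive class.

## Evaluation protocol

The setting is positive–unlabeled: known associations are positives and
*every* other pair is treated as negative during training — no negative
subsampling — even though held-out positives hide among them. Per run,
positives are randomly split into five near-equal folds; for each fold
the held-out cells are zeroed, the network rebuilt, the embedding
retrained (no leakage through the embedding), the forest retrained, and
every pair absent from the training matrix is scored. A scored pair
counts as positive iff it was held out. Fold scores are pooled per run
(per-fold averaging is available as an option); runs aggregate as
mean ± std, with per-run seeds derived as master_seed + run_index.

Because every scored pair was a training row (almost always a negative),
scores are taken **out-of-bag**: the full forest would score memorised
in-bag rows near zero, whereas the OOB estimate is the standard unbiased
score for training points. Ranking metrics are nearly unchanged by this
choice; thresholded metrics (REC, PRE, F1) become meaningful instead of
degenerate.

Metrics: AUC as the rank statistic with tie averaging; AUPR as step-wise
average precision (interpolated trapezoids are optimistic under heavy
imbalance); F1/ACC/REC/SPEC/PRE from the confusion matrix at a
configurable threshold, default 0.5. When nothing is called positive,
PRE = F1 = 0 with a warning.

Experiments: feature-combination comparison; sparsification (remove
10/20/30% of associations, re-run CV); recovery (remove 10%, retrain
once, measure the recall of removed pairs at the threshold, with a
Mann-Whitney rank test of removed-pair scores against the remaining
unknown pairs); per-disease metrics on the restriction of pooled CV
scores to one disease's column (undefined — reported missing — when the
disease has no held-out positives); and full-data candidate ranking with
ties broken lexicographically.

## Synthetic study data

The generator emulates the three real inputs with controllable planted
structure: miRNAs and diseases partition into matched blocks; a pair is
associated with probability p_in inside a matched block and p_out
outside (a bipartite stochastic block model); each miRNA joins its
block's family with probability `family_purity`, else a random family;
each disease receives a tree number rooted at its block's code, so
same-block diseases share ancestors and cross-block ancestries are
disjoint. Every node is guaranteed at least one association so no row of
the training network is empty. Defaults: m = 60, n = 40, 6 blocks,
p_in = 0.3, p_out = 0.01, family_purity = 0.8, dag_depth = 3.
`family_purity < 1` reflects that family membership is an informative
but imperfect proxy for functional grouping; it is also the regime in
which network-derived features can in principle add information beyond
the biological ones.

What the generator does **not** reproduce: the heavy-tailed degree
distribution, hub diseases, and correlated annotation noise of real
HMDD/miRBase/MeSH data. Passing tests on this data demonstrate protocol
correctness and relative behaviour (trends, orderings), not the absolute
performance levels reported on real data.

### A measured limitation

At the default study conditions the fold-training network has mean
degree ≈ 2.3. That is close to the community-detectability limit for a
6-block SBM of this size: dedicated detectors (spectral co-clustering,
Leiden) recover the planted blocks at only ~0.45–0.65 purity, and even
an oracle that reads each miRNA's block from its 2–3 edges plus perfect
disease blocks tops out near 0.80 accuracy. Consequently the embedding
of so sparse a network carries limited information, and on this
synthetic data the all-features model does not outperform the
biological-features model — the opposite of the ordering observed on the
much denser real network (≈ 11 edges per miRNA). The acceptance tests
that assert network-feature dominance at these fixed conditions fail
honestly and are retained as-is; the sparsification trend, recovery
mechanics, oracle equivalences, and determinism checks all pass. Users
applying the package to denser networks should expect the embedding's
contribution to grow with degree.

## Numerical choices and conventions

- Ties in candidate ranking break by (miRNA id, disease id).
- Fold sizes differ by at most one; folds partition the positives.
- The F1/threshold metrics use score ≥ threshold.
- Loss components are compared to hand values at 1e-9; similarity
  oracles at 1e-12; eigen-normalisation at 1e-8.
- Seeds: one master seed derives run seeds additively; the SDNE seed
  controls weight initialisation; the forest seed controls bootstraps
  and split sampling. Identical seeds give byte-identical metric JSON.
- Problem sizes in tests and the acceptance script (one or two CV runs,
  d = 16, 350 trees) are the package's default study scale; the
  protocol itself supports the full 10-run × 5-fold design.
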