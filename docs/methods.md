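# Methods

## The model

Each term *i* of a rooted interaction ontology carries a latent binary
variable *X_i* per gene pair ("the pair truly interacts in this way")
and an observed variable *Y_i*, the discretized score of that term's
classifier. The Bayesian network is the ontology tree "decorated" with
one observation node per term: *Y_i* depends only on *X_i*, and *X_i*
depends only on the term's children. The structural conditionals encode
the true-path rule exactly:

    P(X_i = 1 | any child = 1)        = 1
    P(X_i = 1 | all children = 0)     = p_i        (learned)

Terms without children are the network's root nodes and carry prior
probabilities. Note the direction of conditioning: annotation semantics
flow upward (a child annotation implies the parent), so the ontology's
*leaves* are the Bayesian network's roots. A single-term ontology
degenerates to plain Bayes' rule with the root's prior.

### Exact inference

The structural factor depends on a term's children only through the
indicator "all children off". Writing A_c(x) for the upward message of
child c, S0 = Π_c A_c(0) and T = Π_c (A_c(0) + A_c(1)),

    A_i(1) = L_i(1) · (S0·p_i + (T − S0))
    A_i(0) = L_i(0) · S0·(1 − p_i)

with L_i the observation likelihood; the downward pass has analogous
closed forms using exclusive products (prefix/suffix, no division).
Inference is therefore exact and linear in the number of terms at any
fan-in — no fan-in cap is needed, and no approximation is ever used.
Messages are renormalized per node to avoid underflow. Correctness is
established against brute-force enumeration of all 2^n latent
assignments on random trees (agreement within 1e−9; observed agreement
is at machine precision).

Posterior marginals are the primary output; hierarchical monotonicity
(parent posterior ≥ child posterior) follows from the constraint and is
asserted, not assumed. A max-product mode returns the most probable
joint assignment, which is always an upward-closed set of terms.

### Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| bins per term | 10, clipped at mean ± 5 sd | one bin per training-score sd over the clipped range; configurable |
| Laplace pseudocount α | 1 | smoothing for observation CPTs, structural entries and priors |
| ensemble size | 10 | bagged linear SVMs per term |
| SVM regularization | structural C = 20, mapped to per-example C = 100·20/n | keeps effective regularization size-invariant across standards |
| bootstrap | stratified, full size | with-replacement per class, so every member sees both classes |
| gene holdout | 30 % | evaluation pairs touch at least one never-trained-on gene |
| negative:positive ratio | 1:1 | uniform sampling from unannotated pairs, per term |

### Calibration of the observation model

P(Y|X) is learned from training labels by maximum likelihood. Scoring
the training pairs with the very ensemble fitted to them produces
overconfidently separated scores at desk-scale sample sizes, which
flattens the likelihood ratios of the middle bins — precisely where
held-out evidence concentrates. The CPTs (and the discretizer) are
therefore fitted to 5-fold cross-validated bagged scores: each fold is
scored by a full-size ensemble trained on the other folds, so the
calibration distribution matches what the deployed ensemble produces on
unseen pairs. Out-of-bag scores are also available
(`BaggedClassifier.training_oob_table`) but average fewer members than
the deployed ensemble and are correspondingly noisier.

## Gold standards

Positives propagate to all ancestors (an ordered pair contributed to an
undirected ancestor is canonicalized; an unordered pair never acquires
a direction, so it is skipped, with a logged count, if an ancestor is
directed — a configuration we allow but flag). Negatives are sampled
uniformly from unannotated pairs at 1:1, excluding only the term's own
positives by default (`exclude_scope` semantics beyond the term would
be stricter than the stated per-term wording). Directed terms get
orientation-flipped negatives for directionality evaluation;
bidirectional positives are excluded from flipping and reported.
Train/test splits hold out *genes*, not pairs; a shared holdout across
terms keeps the base-vs-reconciled comparison honest, since a test pair
is then unseen by every classifier feeding the network.

## The synthetic world

The generator emulates the statistical shape of a curated compendium,
not its content: a complete ontology (default: root + 7 leaves, a
quarter of leaves directed), leaf positives planted independently per
pair at rate 0.004 over 500 genes (≈ 500 positives per leaf) and
propagated, and a per-pair Gaussian feature matrix in which each term
owns 3 informative columns shifted by its effect size δ on its
positives, plus 20 shared noise columns (sd 1).

Two deliberate design choices:

- **Per-term feature views.** Each term's classifier sees only its own
  informative columns plus the noise columns, mirroring how per-type
  data exclusion partitions real evidence. This is what makes
  hierarchical reconciliation meaningful: evidence is complementary
  across terms, not shared. (Giving every classifier all columns makes
  isolated classifiers already near-optimal and reconciliation can only
  lose information to discretization.)
- **Effect sizes.** Leaves cycle δ ∈ {0.5, 1, 2}; internal terms take
  the maximum. Aggregate terms pool their subtree's annotations and are
  the best-predicted terms on real compendia, and in a two-level tree
  they are the only channel through which weak terms can borrow
  strength.

Directed terms' informative columns are antisymmetric: +δ in the
planted orientation, −δ flipped, with the noise component negated on
orientation swap — the analogue of signed expression-difference
features.

What a green end-to-end test establishes: the machinery (training,
calibration, exact inference, evaluation) extracts the planted signal
and the hierarchy adds the predicted information. What it does not
establish: performance on real compendia, whose feature correlations,
annotation biases and label noise the generator does not attempt to
mimic, nor any biological claim.

## Evaluation

AUC uses the Mann–Whitney rank statistic with midrank ties, which is
identical to the trapezoidal area under the tie-aware ROC curve (both
are computed; their agreement is asserted to 1e−12). Directionality AUC
ranks correct orientations against the flips of the same pairs. Per-term
AUCs are macro-averaged; the improvement report gives per-term deltas
plus the macro summary. Reconciled posteriors are bin-limited, so on
near-saturated terms (base AUC ≥ 0.98) they can lose a few thousandths
of AUC to ties — visible in the worked example — while under-informed
terms gain an order of magnitude more.

## Topology

Binarization keeps edges strictly above mean + k·sd of the weight
distribution; k = 5 follows the original methods text, k = 3 (exposed
as a flag, and used in the demo script) the original figure protocol.
On bounded, bimodal posterior distributions the retained fraction is
meaningful only over a genome-style pair population (all pairs among a
gene set), which is what the demo script binarizes.

Graphlet machinery is generated, not transcribed: all 30 connected
2–5-node graphlets and their 73 automorphism orbits are derived at
first use by brute force over adjacency bitmasks, with orbit numbering
matching the conventional 0–14 for sizes ≤ 4 (asserted in tests against
networkx automorphisms) and a deterministic package convention for
5-node graphlets. Counting enumerates every connected induced subgraph
exactly once (ESU-style exclusive-neighborhood extension) and
classifies by bitmask lookup; a configurable size cap (5000 nodes /
50000 edges) guards the exhaustive algorithm. GDD agreement normalizes
each orbit's degree distribution by 1/k scaling, takes 1 −
(1/√2)·Euclidean distance per orbit and averages arithmetically
(geometric mean available). An orbit empty in both networks agrees
perfectly; empty in one, it is compared against the zero distribution.

Triad censuses cover the 13 connected directed classes; enrichment
z-scores compare against degree-preserving double-edge-swap null
networks (default 10·|E| accepted swaps; in- and out-degree sequences
preserved exactly; classes with zero null variance report z = NaN and
an empirical p as the fraction of nulls ≥ observed). Exhaustive search
is the default at desk scale; a probabilistic search-tree descent with
the customary retention parameters (0.6/0.5/0.4) provides unbiased
estimates for large graphs. Four-node directed motifs are out of scope.

## Numerical notes and limitations

- Score discretization is lossy by design; with 10 bins, terms whose
  classifiers are already near-perfect gain nothing from
  reconciliation and may lose ~0.005–0.015 AUC to binning ties.
- Zero score variance degenerates to a single, uninformative bin
  (warned); zero weight variance binarizes to an empty network.
- k-NN imputation uses plain Euclidean distance on mutually observed
  conditions within each dataset, eligible neighbors must be observed
  in the target condition, and it falls back to column means when no
  neighbor qualifies; observed entries are never modified.
- Similarity E-values enter as −log10 with a floor of 1e−200; absent
  scores default to E = 1 (feature 0).
- DAG ontologies are rejected, not coerced; the model is a tree by
  construction.
- All stochastic steps (sampling, bootstraps, folds, swaps, the
  generator) are driven by explicit integer seeds; reruns are
  bit-reproducible.
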