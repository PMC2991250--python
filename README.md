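# ontoweave

Simultaneous prediction of many biomolecular interaction types —
physical binding, post-translational modification, regulation, pathway
co-membership, genetic interaction — as *hierarchically consistent*
probabilistic networks over an interaction ontology.

Biological interaction types are not independent labels: a
phosphorylation is also a physical interaction, which is also a
functional relationship. ontoweave exploits this structure. One bagged
linear SVM is trained per interaction type on heterogeneous per-pair
features (expression differences, shared localization/family
indicators, binding-profile distances, sequence-similarity scores); the
per-type scores are then reconciled by a Bayesian network whose
skeleton is the ontology itself, yielding, for every gene pair, a set
of posterior probabilities that can never violate the hierarchy. The
predicted interactomes are then compared structurally: degree
distributions, shared hubs, graphlet degree distributions (73 orbits of
all 2–5-node graphlets) with the GDD agreement metric, and 3-node motif
enrichment against degree-preserving edge-swap null models.

## Model

For each ontology term *i* and gene pair, let *X<sub>i</sub>* ∈ {0,1}
be the true label and *Y<sub>i</sub>* the bagged SVM score, discretized
into 10 equal-width bins clipped at the training mean ± 5 sd. The
"decorated tree" Bayesian network factorizes

- *P(Y<sub>i</sub> | X<sub>i</sub>)* — observation CPTs, learned by
  maximum likelihood with Laplace smoothing from cross-validated
  training scores;
- *P(X<sub>i</sub> | X<sub>j</sub>, …, X<sub>k</sub>)* over the
  term's children, constrained so that any positive child forces
  *X<sub>i</sub>* = 1 (the true-path rule), with the all-children-off
  entry learned from label frequencies; childless terms carry smoothed
  prior frequencies.

Because the structural factor depends on the children only through the
"all off" indicator, sum-product messages have closed forms and exact
posterior marginals cost O(#terms) per pair at any fan-in. Parent
posteriors provably dominate child posteriors. A max-product mode
returns the single most probable consistent label assignment instead.

Directed interaction types (e.g. kinase → substrate) use signed,
antisymmetric features; their quality is measured by the
directionality AUC — how often the correct orientation of a known
interaction outranks its flip.

No external data are required: `ontoweave.synth` generates complete
worlds (ontology, hierarchy-consistent labels, planted per-term feature
signal) so every stage is testable offline.

## Worked example

```sh
ontoweave run --n-genes 500 --seed 1 --out runs/demo
```

trains 10-member ensembles for the 8 terms of the default synthetic
ontology (one root, seven leaves with effect sizes cycling 0.5/1/2 sd),
reconciles them, and evaluates on pairs touching a held-out 30% of
genes:

```
    term  auc_base  auc_reconciled   delta  n_pos  n_neg
    root    0.9924          0.9773 -0.0151   1686   1703
      t0    0.7458          0.9279  0.1822    246    241
      t1    0.8750          0.9451  0.0701    241    241
      t2    0.9854          0.9917  0.0064    235    218
      t3    0.6765          0.9231  0.2466    243    235
      t4    0.8882          0.9583  0.0701    260    268
      t5    0.9762          0.9853  0.0091    237    234
      t6    0.6980          0.9429  0.2449    250    268
__mean__    0.8547          0.9565  0.1018   3398   3408
```

`auc_base` is each isolated classifier's held-out ROC AUC;
`auc_reconciled` scores the same pairs by their reconciled posterior.
Weakly informed terms (t0, t3, t6 — planted effect 0.5 sd) gain the
most because they borrow strength from the data-rich root term through
the hierarchy; the mean improves by ≈ +0.10. The same run writes the
fitted model bundle and per-term posterior edge lists.

From Python:

```python
from ontoweave.experiment import run_end_to_end
from ontoweave.synth import SynthConfig

res = run_end_to_end(SynthConfig(seed=1))
print(res.report())                      # the table above
col = res.posteriors.column("t2")        # per-pair posteriors for one term
```

Topology analysis of a predicted interactome:

```python
from ontoweave.topology import binarize, orbit_counts, gdd_agreement
net = binarize(col, k_sd=3.0)            # keep edges above mean + 3 sd
oc = orbit_counts(net)                   # node x 73 graphlet orbit counts
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete system from scratch under the given seed — the
synthetic world, per-term training, Bayesian reconciliation, held-out
ROC and directionality evaluation, and the systems-level analyses
(binarization at mean + 3 sd over all pairs of a gene subsample, degree
structure, GDD agreement between leaf interactomes, hub overlap, triad
census with edge-swap nulls) — printing a summary and writing the
results file.
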