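"""End-to-end synthetic experiments: plant, train, reconcile, evaluate.

One function runs the whole pipeline on a synthetic world — generate an
ontology and hierarchy-consistent labels, hold out a shared fraction of
genes, train per-term bagged classifiers, fit the decorated-tree model,
and compare held-out AUC of the isolated classifiers against the
reconciled posteriors.  A second runs the directionality protocol on a
directed term (correct orientation vs flipped orientation ranking).

A single shared gene holdout is used for all terms so that a test pair
is unseen by *every* classifier feeding the Bayesian network, keeping
the base-vs-reconciled comparison honest across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_learner import (BaggedClassifier, ScoreTable, cross_val_scores,
                           predict_scores, train_bagged)
from .evaluation import RocResult, directionality_auc, improvement_report, roc_auc_pairs
from .gold_standard import PairLabelSet, draw_holdout_genes, split_by_gene_set
from .ontology import InteractionOntology
from .reconcile import HierarchicalModel, PosteriorTable, fit_hierarchical_model, infer_posteriors
from .synth import SynthConfig, SynthFeatures, make_features, make_ontology, plant_labels


@dataclass
class ExperimentResult:
    config: SynthConfig
    ontology: InteractionOntology
    labels: dict[str, PairLabelSet]
    train: dict[str, PairLabelSet]
    test: dict[str, PairLabelSet]
    classifiers: dict[str, BaggedClassifier]
    model: HierarchicalModel
    features: SynthFeatures
    test_scores: dict[str, ScoreTable]
    posteriors: PosteriorTable
    base_auc: dict[str, RocResult]
    reconciled_auc: dict[str, RocResult]

    def report(self):
        return improvement_report(self.base_auc, self.reconciled_auc)

    def mean_base_auc(self) -> float:
        return float(np.mean([r.auc for r in self.base_auc.values()]))

    def mean_reconciled_auc(self) -> float:
        return float(np.mean([r.auc for r in self.reconciled_auc.values()]))


def run_end_to_end(
    cfg: SynthConfig,
    n_members: int = 10,
    holdout_fraction: float = 0.3,
    n_bins: int = 10,
) -> ExperimentResult:
    """Full pipeline on one synthetic world."""
    o = make_ontology(cfg)
    labels = plant_labels(o, cfg)
    feats = make_features(o, labels, cfg)
    genes = sorted(set().union(*[ls.genes for ls in labels.values()]))
    holdout = draw_holdout_genes(genes, holdout_fraction, seed=cfg.seed + 1)
    train: dict[str, PairLabelSet] = {}
    test: dict[str, PairLabelSet] = {}
    for t, ls in labels.items():
        train[t], test[t] = split_by_gene_set(ls, holdout)

    classifiers: dict[str, BaggedClassifier] = {}
    train_scores: dict[str, ScoreTable] = {}
    for i, t in enumerate(o.topological_order()):
        ft = feats.featurize(train[t].labeled_pairs(), term=t)
        classifiers[t] = train_bagged(ft, train[t], n_members=n_members,
                                      seed=cfg.seed * 1000 + i)
        # cross-validated scores match the deployed ensemble's score
        # distribution on unseen pairs, giving honest observation CPTs
        train_scores[t] = cross_val_scores(ft, train[t], n_members=n_members,
                                           seed=cfg.seed * 1000 + i)
    model = fit_hierarchical_model(o, train_scores, train, n_bins=n_bins)

    # one inference instance per distinct test pair across all terms
    all_test_pairs = sorted(
        {p for ls in test.values() for p in ls.labeled_pairs()},
        key=lambda p: (p.a, p.b, p.ordered),
    )
    test_scores = {
        t: predict_scores(classifiers[t], feats.featurize(all_test_pairs, term=t))
        for t in o.terms
    }
    posteriors = infer_posteriors(model, test_scores, pairs=all_test_pairs)

    base_auc = {t: roc_auc_pairs(test_scores[t], test[t]) for t in o.terms}
    reconciled_auc = {t: roc_auc_pairs(posteriors.column(t), test[t]) for t in o.terms}
    return ExperimentResult(
        config=cfg, ontology=o, labels=labels, train=train, test=test,
        classifiers=classifiers, model=model, features=feats,
        test_scores=test_scores, posteriors=posteriors,
        base_auc=base_auc, reconciled_auc=reconciled_auc,
    )


def run_directionality(
    cfg: SynthConfig,
    n_members: int = 10,
    holdout_fraction: float = 0.3,
) -> RocResult:
    """Directionality AUC for the first directed leaf of a synthetic world.

    Trains that term's bagged classifier on the gene-holdout training
    split and asks how often a held-out positive's correct orientation
    outranks its flip.
    """
    o = make_ontology(cfg)
    directed = [t for t in o.leaves() if o.is_directed(t)]
    if not directed:
        raise ValueError("configuration yields no directed leaf")
    term = directed[0]
    labels = plant_labels(o, cfg)
    feats = make_features(o, labels, cfg)
    train, test = split_by_gene_set(
        labels[term],
        draw_holdout_genes(sorted(labels[term].genes), holdout_fraction,
                           seed=cfg.seed + 1),
    )
    clf = train_bagged(feats.featurize(train.labeled_pairs(), term=term), train,
                       n_members=n_members, seed=cfg.seed)
    positives = sorted(test.positives, key=lambda p: (p.a, p.b))
    both = positives + [p.flipped() for p in positives]
    scores = predict_scores(clf, feats.featurize(both, term=term))
    return directionality_auc(scores, positives)
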