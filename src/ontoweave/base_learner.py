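"""Bagged linear maximum-margin classifiers, one ensemble per term.

Each interaction type gets an ensemble of linear SVMs, each trained on
a stratified bootstrap resample of the term's gold standard; the
averaged decision values are the continuous scores that the reconcile
module later treats as noisy observations of the true labels.

The regularization constant follows the original experiments, which set
the error parameter of a structural-SVM solver to 20.  That solver's C
scales the *total* slack and relates to the conventional per-example
hinge weight as ``C_per_example = 100 * C / n_train``; the default here
applies that mapping to scikit-learn's ``LinearSVC`` (whose C is per
example), so ensembles stay comparably regularized across standards of
very different sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from sklearn.svm import LinearSVC

from .features import FeatureVectorTable, standardize
from .gold_standard import GenePair, PairLabelSet

STRUCTURAL_C = 20.0  # solver-native error parameter; see module docstring


@dataclass
class LinearMember:
    """One trained linear decision function: score(x) = w . x + b."""

    weights: np.ndarray
    offset: float

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights + self.offset


@dataclass
class ScoreTable:
    """Bagged continuous scores for an ordered pair sequence at one term."""

    term: str
    pairs: list[GenePair]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pairs),):
            raise ValueError("scores must align 1:1 with pairs")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def as_dict(self) -> dict[GenePair, float]:
        return dict(zip(self.pairs, self.scores))


@dataclass
class BaggedClassifier:
    term: str
    members: list[LinearMember]
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    C: float
    seeds: list[int] = field(default_factory=list)
    # training pairs and their out-of-bag scores (honest in-sample scores for
    # calibrating the observation model); None for deserialized models
    training_pairs: list[GenePair] | None = None
    oob_scores: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def training_oob_table(self) -> ScoreTable:
        """Out-of-bag bagged scores on the training pairs.

        Each pair is scored only by ensemble members whose bootstrap
        resample did not contain it, so the scores behave like held-out
        scores; pairs in every resample (rare) fall back to the full
        bagged score.
        """
        if self.training_pairs is None or self.oob_scores is None:
            raise ValueError("model carries no out-of-bag information")
        return ScoreTable(self.term, list(self.training_pairs), self.oob_scores)


class SupportsDecision(Protocol):  # pluggable base-learner interface
    def fit(self, x: np.ndarray, y: np.ndarray) -> "SupportsDecision": ...
    def decision_function(self, x: np.ndarray) -> np.ndarray: ...


def effective_c(n_train: int, structural_c: float = STRUCTURAL_C) -> float:
    """Map the structural-SVM error parameter to a per-example C."""
    return 100.0 * structural_c / max(n_train, 1)


def train_bagged(
    features: FeatureVectorTable,
    labels: PairLabelSet,
    n_members: int = 10,
    seed: int = 0,
    C: float | None = None,
) -> BaggedClassifier:
    """Train ``n_members`` linear SVMs on stratified bootstrap resamples.

    Each resample draws, with replacement, as many positives and as many
    negatives as the training set holds (so every member sees both
    classes).  Features are standardized on the training pairs; the
    scaler is stored with the model and re-applied at prediction time.
    """
    if not labels.positives or not labels.negatives:
        raise ValueError(
            f"term {labels.term!r}: training needs both classes "
            f"({len(labels.positives)} pos / {len(labels.negatives)} neg)"
        )
    pairs = labels.labeled_pairs()
    y = labels.labels()
    table = features.subset_rows(pairs)
    table, mean, scale = standardize(table)
    x = table.values
    if C is None:
        C = effective_c(len(pairs))
    rng = np.random.default_rng(seed)
    pos_idx = np.where(y > 0)[0]
    neg_idx = np.where(y < 0)[0]
    members: list[LinearMember] = []
    member_seeds: list[int] = []
    oob_sum = np.zeros(len(pairs))
    oob_count = np.zeros(len(pairs))
    full_sum = np.zeros(len(pairs))
    for _ in range(n_members):
        s = int(rng.integers(2**31 - 1))
        member_seeds.append(s)
        mrng = np.random.default_rng(s)
        take = np.concatenate([
            mrng.choice(pos_idx, size=pos_idx.size, replace=True),
            mrng.choice(neg_idx, size=neg_idx.size, replace=True),
        ])
        clf = LinearSVC(C=C, random_state=s % (2**31 - 1))
        clf.fit(x[take], y[take])
        member = LinearMember(clf.coef_.ravel().copy(), float(clf.intercept_[0]))
        members.append(member)
        dv = member.decision_values(x)
        full_sum += dv
        out_of_bag = np.ones(len(pairs), dtype=bool)
        out_of_bag[np.unique(take)] = False
        oob_sum[out_of_bag] += dv[out_of_bag]
        oob_count[out_of_bag] += 1
    oob = np.where(oob_count > 0, oob_sum / np.maximum(oob_count, 1),
                   full_sum / n_members)
    return BaggedClassifier(
        term=labels.term, members=members, feature_names=list(features.names),
        mean=mean, scale=scale, C=C, seeds=member_seeds,
        training_pairs=list(pairs), oob_scores=oob,
    )


def cross_val_scores(
    features: FeatureVectorTable,
    labels: PairLabelSet,
    n_members: int = 10,
    seed: int = 0,
    n_folds: int = 5,
) -> ScoreTable:
    """Cross-validated bagged scores on the training pairs.

    Each fold's pairs are scored by a full-size ensemble trained on the
    remaining folds, so the score distribution matches what the deployed
    ensemble produces on unseen pairs — the right distribution for
    calibrating the observation model.  Folds are stratified by class.
    """
    pairs = labels.labeled_pairs()
    index = {p: i for i, p in enumerate(pairs)}
    rng = np.random.default_rng(seed)
    folds: list[list[GenePair]] = [[] for _ in range(n_folds)]
    for group in (sorted(labels.positives, key=lambda p: (p.a, p.b, p.ordered)),
                  sorted(labels.negatives, key=lambda p: (p.a, p.b, p.ordered))):
        order = rng.permutation(len(group))
        for j, gi in enumerate(order):
            folds[j % n_folds].append(group[gi])
    scores = np.empty(len(pairs))
    for f, held in enumerate(folds):
        held_set = set(held)
        fit_labels = PairLabelSet(
            labels.term,
            labels.positives - held_set,
            labels.negatives - held_set,
        )
        clf = train_bagged(features.subset_rows(fit_labels.labeled_pairs()),
                           fit_labels, n_members=n_members,
                           seed=int(rng.integers(2**31 - 1)))
        out = predict_scores(clf, features.subset_rows(held))
        for p, s in zip(held, out.scores):
            scores[index[p]] = s
    return ScoreTable(labels.term, pairs, scores)


def predict_scores(m: BaggedClassifier, features: FeatureVectorTable) -> ScoreTable:
    """Arithmetic mean of member decision values on standardized features."""
    if list(features.names) != list(m.feature_names):
        extra = set(features.names) - set(m.feature_names)
        missing = set(m.feature_names) - set(features.names)
        raise ValueError(
            f"feature space mismatch for term {m.term!r}: "
            f"missing={sorted(missing)} extra={sorted(extra)} (order must match too)"
        )
    x = (features.values - m.mean) / m.scale
    stacked = np.stack([mem.decision_values(x) for mem in m.members])
    return ScoreTable(m.term, list(features.pairs), stacked.mean(axis=0))


# -- serialization ---------------------------------------------------------


def save_classifier(m: BaggedClassifier, path: str | Path) -> None:
    blob = {
        "version": 1,
        "term": m.term,
        "feature_names": m.feature_names,
        "mean": m.mean.tolist(),
        "scale": m.scale.tolist(),
        "C": m.C,
        "seeds": m.seeds,
        "members": [
            {"weights": mem.weights.tolist(), "offset": mem.offset} for mem in m.members
        ],
    }
    Path(path).write_text(json.dumps(blob))


def load_classifier(path: str | Path) -> BaggedClassifier:
    blob = json.loads(Path(path).read_text())
    if blob.get("version") != 1:
        raise ValueError(f"unsupported model version {blob.get('version')!r}")
    return BaggedClassifier(
        term=blob["term"],
        members=[LinearMember(np.array(m["weights"]), float(m["offset"]))
                 for m in blob["members"]],
        feature_names=list(blob["feature_names"]),
        mean=np.array(blob["mean"]),
        scale=np.array(blob["scale"]),
        C=float(blob["C"]),
        seeds=list(blob["seeds"]),
    )
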