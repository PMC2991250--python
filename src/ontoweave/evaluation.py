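"""ROC evaluation of predicted interactomes.

AUC is computed with the Mann-Whitney rank statistic (ties get midranks,
counting half a concordance), which coincides exactly with the
trapezoidal area under the tie-aware ROC curve.  Directed interaction
types additionally get a directionality AUC: how often the correct
orientation of a known interaction outranks its flipped orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .base_learner import ScoreTable
from .gold_standard import GenePair, PairLabelSet


@dataclass
class RocResult:
    term: str
    auc: float
    curve: np.ndarray  # (k, 2) of (fpr, tpr), from (0,0) to (1,1)
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if np.any(np.diff(self.curve, axis=0) < -1e-12):
            raise ValueError("ROC curve must be monotone nondecreasing")


def roc_auc(scores: np.ndarray, labels: np.ndarray, term: str = "") -> RocResult:
    """Tie-aware ROC and its AUC from +1/-1 labels.

    AUC = (sum of positive midranks - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"both classes required (got {n_pos} pos / {n_neg} neg)")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # tie-aware curve: step through unique thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], pos[order]
    boundary = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[boundary]
    fp = np.cumsum(~y)[boundary]
    curve = np.column_stack([np.r_[0, fp / n_neg], np.r_[0, tp / n_pos]])
    return RocResult(term, float(auc), curve, n_pos, n_neg)


def roc_auc_pairs(
    scores: ScoreTable, labels: PairLabelSet
) -> RocResult:
    """ROC over a label set, looking scores up per pair."""
    lookup = scores.as_dict()
    pairs = labels.labeled_pairs()
    missing = [p for p in pairs if p not in lookup]
    if missing:
        raise KeyError(f"no scores for {len(missing)} labeled pairs, e.g. {missing[0]}")
    return roc_auc(np.array([lookup[p] for p in pairs]), labels.labels(),
                   term=labels.term)


def directionality_auc(
    scores: ScoreTable, positives: Sequence[GenePair]
) -> RocResult:
    """Correct-orientation scores as positives vs flipped-orientation scores.

    Every positive must be an ordered pair with both orientations
    present in the score table.
    """
    if any(not p.ordered for p in positives):
        raise ValueError("directionality requires ordered pairs (directed term)")
    lookup = scores.as_dict()
    missing = [p for p in positives
               if p not in lookup or p.flipped() not in lookup]
    if missing:
        raise KeyError(
            f"both orientations must be scored; {len(missing)} incomplete, "
            f"e.g. {missing[0]}"
        )
    fwd = np.array([lookup[p] for p in positives])
    rev = np.array([lookup[p.flipped()] for p in positives])
    return roc_auc(
        np.concatenate([fwd, rev]),
        np.concatenate([np.ones(len(fwd)), -np.ones(len(rev))]),
        term=scores.term,
    )


def improvement_report(
    base: Mapping[str, RocResult], reconciled: Mapping[str, RocResult]
) -> pd.DataFrame:
    """Per-term AUC deltas (reconciled - base) with a summary row.

    The summary row (term ``__mean__``) carries macro-averaged values.
    """
    if set(base) != set(reconciled):
        raise ValueError(
            f"term mismatch: {sorted(set(base) ^ set(reconciled))}"
        )
    rows = []
    for t in sorted(base):
        if (base[t].n_pos, base[t].n_neg) != (reconciled[t].n_pos, reconciled[t].n_neg):
            raise ValueError(f"term {t!r}: base and reconciled test sets differ in size")
        rows.append({
            "term": t, "auc_base": base[t].auc, "auc_reconciled": reconciled[t].auc,
            "delta": reconciled[t].auc - base[t].auc,
            "n_pos": base[t].n_pos, "n_neg": base[t].n_neg,
        })
    df = pd.DataFrame(rows)
    summary = {
        "term": "__mean__",
        "auc_base": df["auc_base"].mean(),
        "auc_reconciled": df["auc_reconciled"].mean(),
        "delta": df["delta"].mean(),
        "n_pos": df["n_pos"].sum(), "n_neg": df["n_neg"].sum(),
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
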