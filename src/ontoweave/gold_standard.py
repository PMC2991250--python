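"""Per-term gold standards of labeled gene pairs.

Positives annotated to a term are propagated to every ancestor (the
true-path rule), negatives are sampled uniformly from unannotated pairs
at a 1:1 ratio with positives, directed terms additionally get
orientation-flipped negatives for directionality evaluation, and
train/test splits hold out a fraction of *genes* (not pairs) so that
test pairs always touch a gene the classifiers never saw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import InteractionOntology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """A pair of distinct genes, ordered (a -> b) or unordered {a, b}.

    Unordered pairs are stored canonically with the lexicographically
    smaller gene first, so set membership is orientation-free.
    """

    a: str
    b: str
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self pair {self.a!r} is not a valid interaction")
        if not self.ordered and self.a > self.b:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.a, self.b))

    def flipped(self) -> "GenePair":
        if not self.ordered:
            return self
        return GenePair(self.b, self.a, ordered=True)

    def as_unordered(self) -> "GenePair":
        return self if not self.ordered else GenePair(*sorted((self.a, self.b)))


@dataclass
class PairLabelSet:
    """Positive and negative gene pairs for one ontology term."""

    term: str
    positives: set[GenePair] = field(default_factory=set)
    negatives: set[GenePair] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"term {self.term!r}: {len(overlap)} pairs labeled both ways")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.positives | self.negatives:
            out.update((p.a, p.b))
        return out

    def labeled_pairs(self) -> list[GenePair]:
        """Deterministic ordering: positives then negatives, each sorted."""
        key = lambda p: (p.a, p.b, p.ordered)
        return sorted(self.positives, key=key) + sorted(self.negatives, key=key)

    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives)), -np.ones(len(self.negatives))]
        )


# -- propagation -----------------------------------------------------------


def propagate_positives(
    o: InteractionOntology, raw: Mapping[str, Iterable[GenePair]]
) -> dict[str, set[GenePair]]:
    """Copy every positive annotation to all ancestor terms.

    An ordered pair contributed to an undirected ancestor is
    canonicalized; an unordered pair reaching a *directed* ancestor is
    skipped (it cannot honestly acquire a direction) and counted in a
    log warning.
    """
    for term in raw:
        if term not in o:
            raise KeyError(f"unknown term {term!r} in raw annotations")
    out: dict[str, set[GenePair]] = {t: set() for t in o.terms}
    skipped = 0
    for term, pairs in raw.items():
        for pair in pairs:
            for target in [term, *o.ancestors(term)]:
                if o.is_directed(target):
                    if not pair.ordered:
                        skipped += 1
                        continue
                    out[target].add(pair)
                else:
                    out[target].add(pair.as_unordered())
    if skipped:
        logger.warning(
            "%d unordered annotations could not propagate into directed ancestors",
            skipped,
        )
    return out


# -- negative construction -------------------------------------------------


def sample_negatives(
    positives: set[GenePair],
    universe: Sequence[str],
    n: int,
    seed: int,
    ordered: bool = False,
) -> set[GenePair]:
    """Draw ``n`` distinct non-positive pairs uniformly from ``universe``.

    Reproducible for a fixed seed.  Small pair spaces are materialized
    and sampled exactly; large ones use rejection sampling (still exact
    uniform over eligible pairs).
    """
    genes = sorted(set(universe))
    gene_set = set(genes)
    m = len(genes)
    total = m * (m - 1) if ordered else m * (m - 1) // 2
    pos = {(p.a, p.b) for p in positives}
    in_universe = {k for k in pos if k[0] in gene_set and k[1] in gene_set}
    available = total - len(in_universe)
    if n > available:
        raise ValueError(
            f"cannot sample {n} negatives: only {available} eligible pairs "
            f"({m} genes, {len(pos)} positives, ordered={ordered})"
        )
    rng = np.random.default_rng(seed)
    if total <= 500_000:
        eligible = []
        for i, a in enumerate(genes):
            for b in (genes if ordered else genes[i + 1:]):
                if a != b and (a, b) not in pos:
                    eligible.append((a, b))
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in idx]
    else:
        chosen_set: set[tuple[str, str]] = set()
        while len(chosen_set) < n:
            i = int(rng.integers(m))
            j = int(rng.integers(m))
            if i == j:
                continue
            if not ordered and i > j:
                i, j = j, i
            key = (genes[i], genes[j])
            if key in pos or key in chosen_set:
                continue
            chosen_set.add(key)
        chosen = sorted(chosen_set)
    return {GenePair(a, b, ordered=ordered) for a, b in chosen}


def make_direction_negatives(
    positives: set[GenePair],
) -> tuple[set[GenePair], set[GenePair]]:
    """Orientation-flipped copies of directed positives.

    Returns ``(negatives, excluded)`` where ``excluded`` holds positives
    whose flip is itself annotated positive (bidirectional interactions,
    which cannot serve as direction negatives).
    """
    if any(not p.ordered for p in positives):
        raise ValueError("direction negatives require ordered pairs (directed term)")
    excluded = {p for p in positives if p.flipped() in positives}
    negatives = {p.flipped() for p in positives - excluded}
    if excluded:
        logger.info("%d bidirectional positives excluded from direction negatives",
                    len(excluded))
    return negatives, excluded


# -- train/test splitting --------------------------------------------------


def split_by_gene(
    labels: PairLabelSet, holdout_fraction: float, seed: int
) -> tuple[PairLabelSet, PairLabelSet]:
    """Split by holding out genes, not pairs.

    A holdout set H of ``ceil(fraction * n_genes)`` genes is drawn;
    training keeps pairs touching no gene of H, test takes pairs
    touching at least one.  Every pair lands in exactly one side.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    genes = sorted(labels.genes)
    holdout = draw_holdout_genes(genes, holdout_fraction, seed)
    return split_by_gene_set(labels, holdout)


def draw_holdout_genes(
    genes: Sequence[str], holdout_fraction: float, seed: int
) -> set[str]:
    genes = sorted(genes)
    k = math.ceil(holdout_fraction * len(genes))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=k, replace=False)
    return {genes[i] for i in idx}


def split_by_gene_set(
    labels: PairLabelSet, holdout: set[str]
) -> tuple[PairLabelSet, PairLabelSet]:
    """Deterministic split given an explicit holdout gene set (shared splits)."""
    def part(pairs: set[GenePair]) -> tuple[set[GenePair], set[GenePair]]:
        tr = {p for p in pairs if p.a not in holdout and p.b not in holdout}
        return tr, pairs - tr

    pos_tr, pos_te = part(labels.positives)
    neg_tr, neg_te = part(labels.negatives)
    train = PairLabelSet(labels.term, pos_tr, neg_tr)
    test = PairLabelSet(labels.term, pos_te, neg_te)
    for side, ls in (("train", train), ("test", test)):
        if not ls.positives or not ls.negatives:
            logger.warning(
                "term %s: %s split degenerate (%d pos / %d neg)",
                labels.term, side, len(ls.positives), len(ls.negatives),
            )
    return train, test


# -- file formats ----------------------------------------------------------


def load_labels(path: str | Path, o: InteractionOntology) -> dict[str, PairLabelSet]:
    """Read a 4-column TSV: gene_a, gene_b, term_id, label (+1/-1).

    For directed terms the column order encodes the direction a -> b.
    """
    raw: dict[str, tuple[set[GenePair], set[GenePair]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            a, b, term, label = line.rstrip("\n").split("\t")
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields") from None
        if term not in o:
            raise KeyError(f"{path}:{lineno}: unknown term {term!r}")
        pair = GenePair(a, b, ordered=o.is_directed(term))
        pos, neg = raw.setdefault(term, (set(), set()))
        if label in {"+1", "1"}:
            pos.add(pair)
        elif label == "-1":
            neg.add(pair)
        else:
            raise ValueError(f"{path}:{lineno}: label must be +1 or -1, got {label!r}")
    return {t: PairLabelSet(t, pos, neg) for t, (pos, neg) in raw.items()}


def save_labels(labels: Mapping[str, PairLabelSet], path: str | Path) -> None:
    lines = []
    for term in sorted(labels):
        ls = labels[term]
        for pair, lab in [(p, "+1") for p in sorted(ls.positives, key=lambda p: (p.a, p.b))] + \
                         [(p, "-1") for p in sorted(ls.negatives, key=lambda p: (p.a, p.b))]:
            lines.append(f"{pair.a}\t{pair.b}\t{term}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")
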