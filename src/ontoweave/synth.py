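"""Synthetic worlds with planted hierarchical interaction signal.

The generator stands in for a real functional-genomics compendium: it
builds a complete interaction-type tree, plants leaf-level positive
pairs at a configurable rate (propagated upward so labels are
hierarchy-consistent by construction), and emits per-pair features in
which each term owns a few informative columns shifted by that term's
effect size on its positive pairs.  Directed terms get antisymmetric
informative columns (+delta in the correct orientation, -delta
flipped), mirroring the signed expression-difference features used for
real directed interaction types.  Effect sizes default to a spread
(0.5 / 1 / 2 noise-sd units) so that borrowing strength across the
hierarchy is observable: weakly informed terms sit next to strongly
informed relatives, as sparse specific interaction types do under
data-rich general ones in real standards.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import ExpressionCompendium, FeatureVectorTable
from .gold_standard import (GenePair, PairLabelSet, propagate_positives,
                            sample_negatives)
from .ontology import InteractionOntology, Term


@dataclass
class SynthConfig:
    """Stated world for the synthetic benchmark.

    ``deltas`` are cycled over terms in breadth-first order, so effect
    sizes are heterogeneous across the tree by default.  All randomness
    is derived from ``seed``.
    """

    n_genes: int = 500
    depth: int = 1
    branching: int = 7
    directed_fraction: float = 0.25
    positive_rate: float = 0.004
    deltas: tuple[float, ...] = (0.5, 1.0, 2.0)
    n_informative: int = 3
    noise_sd: float = 1.0
    n_noise_features: int = 20
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("directed_fraction", "positive_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be >= 1")

    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


def _stable_hash(text: str) -> int:
    # process-independent (unlike builtin hash), keeps derived seeds below 2**31
    return zlib.crc32(text.encode()) % (2**31)


def _seeds(cfg: SynthConfig, purpose: str, n: int) -> list[int]:
    ss = np.random.SeedSequence([cfg.seed, _stable_hash(purpose)])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def make_ontology(cfg: SynthConfig) -> InteractionOntology:
    """Complete tree of the configured depth and branching factor.

    The configured fraction of leaves (rounded up, chosen at random
    under the seed) is marked directed.
    """
    terms: dict[str, Term] = {"root": Term("root", name="functional relationship")}
    frontier = ["root"]
    for _ in range(cfg.depth):
        nxt = []
        for parent in frontier:
            for i in range(cfg.branching):
                tid = f"{parent}.{i}" if parent != "root" else f"t{i}"
                terms[tid] = Term(tid, name=f"synthetic type {tid}", parent=parent)
            nxt.extend(t for t in terms if terms[t].parent == parent)
        frontier = nxt
    o = InteractionOntology(terms)
    leaves = o.leaves()
    n_directed = math.ceil(cfg.directed_fraction * len(leaves))
    rng = np.random.default_rng(_seeds(cfg, "ontology", 1)[0])
    directed = set(rng.choice(len(leaves), size=n_directed, replace=False)) if n_directed else set()
    for j, leaf in enumerate(leaves):
        if j in directed:
            terms[leaf] = Term(leaf, terms[leaf].name, directed=True,
                               parent=terms[leaf].parent)
    return InteractionOntology(terms)


def term_deltas(o: InteractionOntology, cfg: SynthConfig) -> dict[str, float]:
    """Effect size per term: leaves cycle the configured spread.

    Internal terms (including the root) take the largest configured
    effect: aggregate interaction types pool the annotations of their
    whole subtree and are the best-predicted terms on real compendia,
    and they are the channel through which specific terms borrow
    strength.
    """
    out = {t: max(cfg.deltas) for t in o.terms if not o.is_leaf(t)}
    for i, leaf in enumerate(o.leaves()):
        out[leaf] = cfg.deltas[i % len(cfg.deltas)]
    return out


def plant_labels(o: InteractionOntology, cfg: SynthConfig) -> dict[str, PairLabelSet]:
    """Leaf positives at the configured rate, propagated, with 1:1 negatives."""
    genes = cfg.genes()
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    leaf_seeds = _seeds(cfg, "labels", len(o.leaves()) + len(o.terms))
    raw: dict[str, set[GenePair]] = {}
    for li, leaf in enumerate(o.leaves()):
        rng = np.random.default_rng(leaf_seeds[li])
        hit = np.where(rng.random(iu.size) < cfg.positive_rate)[0]
        pairs: set[GenePair] = set()
        directed = o.is_directed(leaf)
        for h in hit:
            a, b = genes[iu[h]], genes[ju[h]]
            if directed and rng.random() < 0.5:
                a, b = b, a
            pairs.add(GenePair(a, b, ordered=directed))
        raw[leaf] = pairs
    propagated = propagate_positives(o, raw)
    out: dict[str, PairLabelSet] = {}
    neg_seeds = _seeds(cfg, "negatives", len(o.terms))
    for ti, t in enumerate(o.topological_order()):
        pos = propagated[t]
        neg = (sample_negatives(pos, genes, len(pos), neg_seeds[ti],
                                ordered=o.is_directed(t))
               if pos else set())
        out[t] = PairLabelSet(t, pos, neg)
    return out


@dataclass
class SynthFeatures:
    """Frozen synthetic feature model: query features for any pair.

    Feature values are drawn once per unordered gene pair; directed
    terms' informative columns flip sign with orientation, all other
    columns are orientation-invariant.
    """

    ontology: InteractionOntology
    config: SynthConfig
    names: list[str]
    sources: list[str]
    term_columns: dict[str, list[int]]
    noise_columns: list[int]
    directed_columns: list[int]
    _cache: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    _positive_keys: dict[str, set[frozenset[str]]] = field(default_factory=dict)
    _positive_direction: dict[str, dict[frozenset[str], tuple[str, str]]] = field(default_factory=dict)
    _pair_seed: int = 0

    def _base_row(self, key: tuple[str, str]) -> np.ndarray:
        """Noise + planted shifts for the canonical orientation of a pair."""
        if key in self._cache:
            return self._cache[key]
        cfg = self.config
        mix = np.random.SeedSequence([self._pair_seed,
                                      _stable_hash("|".join(key))])
        rng = np.random.default_rng(mix)
        row = rng.normal(0.0, cfg.noise_sd, len(self.names))
        deltas = term_deltas(self.ontology, cfg)
        fkey = frozenset(key)
        for t, cols in self.term_columns.items():
            if fkey not in self._positive_keys.get(t, set()):
                continue
            if self.ontology.is_directed(t):
                a, b = self._positive_direction[t][fkey]
                sign = 1.0 if (a, b) == key else -1.0
                row[cols] += sign * deltas[t]
            else:
                row[cols] += deltas[t]
        self._cache[key] = row
        return row

    def featurize(self, pairs: Sequence[GenePair],
                  term: str | None = None) -> FeatureVectorTable:
        """Features for ``pairs``; with ``term`` given, that term's view.

        A term's view holds its own informative columns plus the shared
        noise columns — each interaction type works from its own slice
        of the data, the way per-type data exclusion partitions real
        evidence — so classifier evidence is complementary across the
        hierarchy rather than shared.  Without ``term`` the full column
        space is returned.
        """
        rows = np.empty((len(pairs), len(self.names)))
        for i, p in enumerate(pairs):
            key = tuple(sorted((p.a, p.b)))
            row = self._base_row(key)
            if p.ordered and (p.a, p.b) != key:
                row = row.copy()
                row[self.directed_columns] *= -1.0
            rows[i] = row
        cols = (None if term is None
                else self.term_columns[term] + self.noise_columns)
        if cols is None:
            return FeatureVectorTable(list(pairs), list(self.names), rows,
                                      list(self.sources))
        return FeatureVectorTable(
            list(pairs), [self.names[c] for c in cols], rows[:, cols],
            [self.sources[c] for c in cols],
        )

    def per_term(self, labels: Mapping[str, PairLabelSet]) -> dict[str, FeatureVectorTable]:
        return {t: self.featurize(ls.labeled_pairs(), term=t)
                for t, ls in labels.items()}


def make_features(
    o: InteractionOntology,
    labels: Mapping[str, PairLabelSet],
    cfg: SynthConfig,
) -> SynthFeatures:
    """Build the planted feature model for a labeled world.

    Each term owns ``n_informative`` columns; positives of the term are
    shifted by its delta on those columns (sign-flipped with orientation
    for directed terms), everything else is Gaussian noise.
    """
    order = o.topological_order()
    names: list[str] = []
    term_columns: dict[str, list[int]] = {}
    for t in order:
        term_columns[t] = list(range(len(names), len(names) + cfg.n_informative))
        names.extend(f"f:{t}:{i}" for i in range(cfg.n_informative))
    noise_columns = list(range(len(names), len(names) + cfg.n_noise_features))
    names.extend(f"noise:{i}" for i in range(cfg.n_noise_features))
    directed_cols = [c for t in order if o.is_directed(t) for c in term_columns[t]]
    pos_keys = {t: {p.genes for p in ls.positives} for t, ls in labels.items()}
    pos_dir = {
        t: {p.genes: (p.a, p.b) for p in ls.positives if p.ordered}
        for t, ls in labels.items()
    }
    return SynthFeatures(
        ontology=o, config=cfg, names=names,
        sources=["expression"] * len(names),
        term_columns=term_columns, noise_columns=noise_columns,
        directed_columns=directed_cols,
        _positive_keys=pos_keys, _positive_direction=pos_dir,
        _pair_seed=_seeds(cfg, "features", 1)[0],
    )


# -- mock per-gene data sources (for the feature-construction tests) -------


def make_expression_compendium(
    cfg: SynthConfig, n_conditions: int = 30, n_datasets: int = 2
) -> ExpressionCompendium:
    """Gaussian expression matrix with missing entries at ``missing_rate``."""
    rng = np.random.default_rng(_seeds(cfg, "expression", 1)[0])
    vals = rng.normal(size=(cfg.n_genes, n_conditions))
    if cfg.missing_rate > 0:
        vals = np.where(rng.random(vals.shape) < cfg.missing_rate, np.nan, vals)
    per = math.ceil(n_conditions / n_datasets)
    datasets = [f"d{j // per}" for j in range(n_conditions)]
    return ExpressionCompendium(
        cfg.genes(), [f"c{j}" for j in range(n_conditions)], vals, datasets
    )


def make_membership(cfg: SynthConfig, n_categories: int = 12,
                    mean_memberships: float = 1.5) -> dict[str, set[str]]:
    rng = np.random.default_rng(_seeds(cfg, "membership", 1)[0])
    cats = [f"cat{j}" for j in range(n_categories)]
    out: dict[str, set[str]] = {}
    for g in cfg.genes():
        k = rng.poisson(mean_memberships)
        if k:
            out[g] = set(rng.choice(cats, size=min(k, n_categories), replace=False))
    return out


def make_profiles(cfg: SynthConfig, length: int = 20) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(_seeds(cfg, "profiles", 1)[0])
    return {g: (rng.random(length) < 0.2).astype(float) for g in cfg.genes()}
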