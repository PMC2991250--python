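"""Hierarchical reconciliation of per-term classifier scores.

This is the heart of the system.  Each ontology term ``t`` contributes a
latent binary variable ``X_t`` ("the pair truly interacts in this way")
and an observed variable ``Y_t`` (the bagged classifier score,
discretized).  The Bayesian network is the ontology's "decorated tree":
``Y_t`` depends only on ``X_t``, and each ``X_t`` depends only on its
child terms.  The structural conditionals hard-code the true-path rule

    P(X_t = 1 | any child on)  = 1
    P(X_t = 1 | all children off) = p_t   (learned, Laplace-smoothed)

while terms without children (the network's root nodes) carry smoothed
prior label frequencies.  Because the structural table depends on the
children only through the indicator "all children off", sum-product
messages collapse to closed forms in the product of child messages, so
exact inference is linear in the number of terms with no fan-in limit.

Posterior marginals P(X_t = 1 | all Y) are the primary output; they are
hierarchically consistent by construction (a parent's posterior can
never fall below a child's).  A max-product mode returning the single
most probable joint label assignment is also provided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .base_learner import BaggedClassifier, ScoreTable, predict_scores
from .features import FeatureVectorTable
from .gold_standard import GenePair, PairLabelSet
from .ontology import InteractionOntology

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 10  # one bin per standard deviation over mean +/- 5 sd
DEFAULT_PSEUDOCOUNT = 1.0


# -- score discretization --------------------------------------------------


@dataclass
class DiscretizationScheme:
    """Equal-width bins spanning the training-score mean +/- 5 sd.

    Scores are clipped to the spanned range, so out-of-range values land
    in the end bins; bins are half-open on the right, hence a score at
    the mean falls in bin ``n_bins // 2``.
    """

    term: str
    mean: float
    sd: float
    n_bins: int
    edges: np.ndarray
    span_sds: float = 5.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) != self.n_bins + 1:
            raise ValueError("need n_bins + 1 edges")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")

    def bin_index(self, scores: np.ndarray | float) -> np.ndarray:
        s = np.clip(np.asarray(scores, dtype=float), self.edges[0], self.edges[-1])
        idx = np.floor(
            (s - self.edges[0]) / (self.edges[-1] - self.edges[0]) * self.n_bins
        ).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


def fit_discretizer(
    scores: ScoreTable, n_bins: int = DEFAULT_N_BINS, span_sds: float = 5.0
) -> DiscretizationScheme:
    """Fit the clipping range and bin edges to training scores."""
    vals = np.asarray(scores.scores, dtype=float)
    if vals.size < 2:
        raise ValueError(f"term {scores.term!r}: need >=2 training scores")
    mean = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0:
        logger.warning("term %s: zero score variance; single-bin scheme", scores.term)
        return DiscretizationScheme(scores.term, mean, 0.0, 1,
                                    np.array([mean - 0.5, mean + 0.5]), span_sds)
    lo, hi = mean - span_sds * sd, mean + span_sds * sd
    return DiscretizationScheme(scores.term, mean, sd, n_bins,
                                np.linspace(lo, hi, n_bins + 1), span_sds)


# -- conditional probability tables ---------------------------------------


@dataclass
class ObservationCPT:
    """P(Y = bin | X = x), one row per latent state (row 0: X=0, row 1: X=1)."""

    term: str
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2 or self.table.shape[0] != 2:
            raise ValueError("observation CPT must be 2 x n_bins")
        if not np.all(self.table > 0):
            raise ValueError("observation CPT must be strictly positive (smoothed)")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.table.shape[1]


def learn_observation_cpt(
    scores: ScoreTable,
    labels: PairLabelSet,
    d: DiscretizationScheme,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ObservationCPT:
    """Maximum-likelihood bin frequencies per class with Laplace smoothing:
    P(Y=b | X=x) = (count(b, x) + a) / (count(x) + a * n_bins)."""
    if not labels.positives or not labels.negatives:
        raise ValueError(f"term {labels.term!r}: both classes required to learn P(Y|X)")
    lookup = scores.as_dict()
    counts = np.zeros((2, d.n_bins))
    for x, pairs in ((0, labels.negatives), (1, labels.positives)):
        for p in pairs:
            if p not in lookup:
                raise KeyError(f"term {labels.term!r}: no training score for pair {p}")
            counts[x, int(d.bin_index(lookup[p]))] += 1
    a = pseudocount
    table = (counts + a) / (counts.sum(axis=1, keepdims=True) + a * d.n_bins)
    return ObservationCPT(labels.term, table)


@dataclass
class StructuralCPT:
    """Structural conditional for one term.

    Internal terms store ``p_all_off`` = P(X=1 | every child off); the
    any-child-on entry is identically 1 and therefore not stored.
    Childless terms (the Bayesian network's root nodes) store a prior.
    """

    term: str
    children: tuple[str, ...]
    p_all_off: float | None = None
    prior: float | None = None

    def __post_init__(self) -> None:
        if self.children:
            if self.p_all_off is None or not (0 < self.p_all_off < 1):
                raise ValueError(f"term {self.term!r}: p_all_off must be in (0, 1)")
        else:
            if self.prior is None or not (0 < self.prior < 1):
                raise ValueError(f"term {self.term!r}: leaf prior must be in (0, 1)")


def _unordered_keys(pairs: set[GenePair]) -> set[frozenset[str]]:
    return {p.genes for p in pairs}


def learn_structural_cpts(
    o: InteractionOntology,
    train_labels: Mapping[str, PairLabelSet],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, StructuralCPT]:
    """Learn P(X=1 | all children off) per internal term and priors for leaves.

    Counting is done over each term's own labeled training pairs; a pair
    counts as "on" at a child when its gene set appears among the
    child's positives (orientation is deliberately ignored here, since a
    directed child annotation asserts the undirected fact as well).
    Labels must be hierarchy-consistent (propagated) first.
    """
    pos_keys = {t: _unordered_keys(ls.positives) for t, ls in train_labels.items()}
    # hierarchy consistency: every child positive must appear in the parent
    for t, ls in train_labels.items():
        for anc in o.ancestors(t):
            if anc in pos_keys:
                stray = pos_keys[t] - pos_keys[anc]
                if stray:
                    example = sorted(next(iter(stray)))
                    raise ValueError(
                        f"labels violate hierarchy: {len(stray)} pairs positive at "
                        f"{t!r} but not at ancestor {anc!r} (e.g. {example})"
                    )
    a = pseudocount
    out: dict[str, StructuralCPT] = {}
    for t in o.topological_order():
        if t not in train_labels:
            raise KeyError(f"no training labels for modeled term {t!r}")
        ls = train_labels[t]
        kids = tuple(c for c in o.children[t] if c in train_labels)
        if not kids:
            n_pos, n_neg = len(ls.positives), len(ls.negatives)
            out[t] = StructuralCPT(t, (), prior=(n_pos + a) / (n_pos + n_neg + 2 * a))
            continue
        kid_pos: set[frozenset[str]] = set()
        for c in kids:
            kid_pos |= pos_keys[c]
        all_off = [p for p in ls.labeled_pairs() if p.genes not in kid_pos]
        n_on = sum(1 for p in all_off if p.genes in pos_keys[t])
        out[t] = StructuralCPT(t, kids,
                               p_all_off=(n_on + a) / (len(all_off) + 2 * a))
    return out


# -- the assembled model ---------------------------------------------------


@dataclass
class HierarchicalModel:
    ontology: InteractionOntology
    discretizers: dict[str, DiscretizationScheme]
    observation: dict[str, ObservationCPT]
    structure: dict[str, StructuralCPT]

    def __post_init__(self) -> None:
        terms = set(self.ontology.terms)
        for name, d in (("discretizer", self.discretizers),
                        ("observation CPT", self.observation),
                        ("structural CPT", self.structure)):
            missing = terms - set(d)
            if missing:
                raise ValueError(f"missing {name} for terms {sorted(missing)}")

    @property
    def terms(self) -> list[str]:
        return self.ontology.topological_order()


def fit_hierarchical_model(
    o: InteractionOntology,
    train_scores: Mapping[str, ScoreTable],
    train_labels: Mapping[str, PairLabelSet],
    n_bins: int = DEFAULT_N_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> HierarchicalModel:
    """Convenience: fit discretizers, observation CPTs and structural CPTs."""
    disc = {t: fit_discretizer(train_scores[t], n_bins) for t in o.terms}
    obs = {
        t: learn_observation_cpt(train_scores[t], train_labels[t], disc[t], pseudocount)
        for t in o.terms
    }
    struct = learn_structural_cpts(o, train_labels, pseudocount)
    return HierarchicalModel(o, disc, obs, struct)


@dataclass
class PosteriorTable:
    """P(X_term = 1 | all observations) per pair, one column per term."""

    pairs: list[GenePair]
    terms: list[str]
    posterior: np.ndarray

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.posterior.shape != (len(self.pairs), len(self.terms)):
            raise ValueError("posterior matrix must be pairs x terms")
        if self.posterior.min() < -1e-12 or self.posterior.max() > 1 + 1e-12:
            raise ValueError("posteriors must lie in [0, 1]")

    def column(self, term: str) -> ScoreTable:
        return ScoreTable(term, list(self.pairs),
                          self.posterior[:, self.terms.index(term)])

    def as_dict(self, term: str) -> dict[GenePair, float]:
        j = self.terms.index(term)
        return {p: float(v) for p, v in zip(self.pairs, self.posterior[:, j])}


# -- exact inference -------------------------------------------------------


def _likelihoods(
    m: HierarchicalModel,
    scores: Mapping[str, ScoreTable],
    pairs: Sequence[GenePair],
    on_missing: Literal["marginalize", "error"],
) -> dict[str, np.ndarray]:
    """Per-term likelihood arrays L[t][x, i] = P(Y_t = bin(score) | X_t = x)."""
    n = len(pairs)
    out: dict[str, np.ndarray] = {}
    for t in m.terms:
        if t not in scores:
            if on_missing == "error":
                raise KeyError(f"no scores for modeled term {t!r}")
            out[t] = np.ones((2, n))
            continue
        st = scores[t]
        if list(st.pairs) == list(pairs):
            vals = st.scores
        else:
            lookup = st.as_dict()
            missing = [p for p in pairs if p not in lookup]
            if missing:
                if on_missing == "error":
                    raise KeyError(
                        f"term {t!r}: missing scores for {len(missing)} pairs, "
                        f"e.g. {missing[0]}"
                    )
                vals = np.array([lookup.get(p, np.nan) for p in pairs])
            else:
                vals = np.array([lookup[p] for p in pairs])
        observed = np.isfinite(vals)
        bins = m.discretizers[t].bin_index(np.where(observed, vals, 0.0))
        lik = m.observation[t].table[:, bins]  # (2, n)
        lik = np.where(observed, lik, 1.0)
        out[t] = lik
    return out


def infer_posteriors(
    m: HierarchicalModel,
    scores: Mapping[str, ScoreTable],
    pairs: Sequence[GenePair] | None = None,
    on_missing: Literal["marginalize", "error"] = "error",
) -> PosteriorTable:
    """Exact marginal posteriors by sum-product on the decorated tree.

    All score tables must cover the same pair sequence (or ``pairs`` is
    given explicitly and looked up per table).  Missing observations are
    either an error or marginalized out, per ``on_missing``.

    The upward message for term ``t`` is A_t(x) proportional to
    P(evidence in t's subtree, X_t = x); with S0 the product of child
    A(0) values and T the product of child totals, the any-child-on
    constraint gives

        A_t(1) = L_t(1) * (S0 * p_t + (T - S0))
        A_t(0) = L_t(0) * S0 * (1 - p_t)

    and analogous closed forms for the downward pass, so runtime is
    linear in the number of terms regardless of fan-in.
    """
    if pairs is None:
        first = next(iter(scores.values()))
        pairs = list(first.pairs)
    n = len(pairs)
    lik = _likelihoods(m, scores, pairs, on_missing)
    order = m.terms
    up: dict[str, np.ndarray] = {}
    # child products, cached for the downward pass
    prods: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in reversed(order):
        cpt = m.structure[t]
        if not cpt.children:
            prior = float(cpt.prior)  # type: ignore[arg-type]
            a = np.stack([lik[t][0] * (1 - prior), lik[t][1] * prior])
        else:
            s0 = np.ones(n)
            tot = np.ones(n)
            for c in cpt.children:
                s0 = s0 * up[c][0]
                tot = tot * (up[c][0] + up[c][1])
            prods[t] = (s0, tot)
            p = float(cpt.p_all_off)  # type: ignore[arg-type]
            a = np.stack([
                lik[t][0] * s0 * (1 - p),
                lik[t][1] * (s0 * p + (tot - s0)),
            ])
        z = a.sum(axis=0)
        up[t] = a / z
    down: dict[str, np.ndarray] = {order[0]: np.ones((2, n))}
    for t in order:
        cpt = m.structure[t]
        if not cpt.children:
            continue
        p = float(cpt.p_all_off)  # type: ignore[arg-type]
        kids = cpt.children
        a0 = np.stack([up[c][0] for c in kids])          # (k, n)
        atot = np.stack([up[c][0] + up[c][1] for c in kids])
        s0_ex = _exclusive_product(a0)
        tot_ex = _exclusive_product(atot)
        bt = down[t]
        for j, c in enumerate(kids):
            b1 = lik[t][1] * bt[1] * tot_ex[j]
            b0 = (lik[t][1] * bt[1] * (s0_ex[j] * p + tot_ex[j] - s0_ex[j])
                  + lik[t][0] * bt[0] * s0_ex[j] * (1 - p))
            b = np.stack([b0, b1])
            z = b.sum(axis=0)
            z = np.where(z == 0, 1.0, z)
            down[c] = b / z
    post = np.empty((n, len(order)))
    for j, t in enumerate(order):
        num = up[t][1] * down[t][1]
        den = num + up[t][0] * down[t][0]
        post[:, j] = num / den
    return PosteriorTable(list(pairs), list(order), post)


def _exclusive_product(rows: np.ndarray) -> np.ndarray:
    """rows: (k, n) -> out[j] = product over i != j of rows[i] (stable, no division)."""
    k = rows.shape[0]
    prefix = np.ones_like(rows)
    suffix = np.ones_like(rows)
    for i in range(1, k):
        prefix[i] = prefix[i - 1] * rows[i - 1]
    for i in range(k - 2, -1, -1):
        suffix[i] = suffix[i + 1] * rows[i + 1]
    return prefix * suffix


def map_assignment(
    m: HierarchicalModel,
    scores: Mapping[str, ScoreTable],
    pairs: Sequence[GenePair] | None = None,
    on_missing: Literal["marginalize", "error"] = "error",
) -> PosteriorTable:
    """Most probable joint label assignment (max-product), 0/1 per term.

    Because any-on forces the parent on, the optimal assignment is an
    upward-closed set of terms; the max-product recursion mirrors the
    sum-product one with sums over child configurations replaced by
    maxima, tracked separately for the all-off and some-on cases.
    """
    if pairs is None:
        first = next(iter(scores.values()))
        pairs = list(first.pairs)
    n = len(pairs)
    lik = _likelihoods(m, scores, pairs, on_missing)
    order = m.terms
    # M[t][x] = max over subtree assignments consistent with X_t = x
    best: dict[str, np.ndarray] = {}
    choice: dict[str, dict[str, np.ndarray]] = {}
    for t in reversed(order):
        cpt = m.structure[t]
        if not cpt.children:
            prior = float(cpt.prior)  # type: ignore[arg-type]
            best[t] = np.stack([lik[t][0] * (1 - prior), lik[t][1] * prior])
            continue
        p = float(cpt.p_all_off)  # type: ignore[arg-type]
        all_off = np.ones(n)
        free = np.ones(n)   # each child free to take its better state
        for c in cpt.children:
            all_off = all_off * best[c][0]
            free = free * np.maximum(best[c][0], best[c][1])
        # X_t = 1: children unconstrained, but if all pick 0 the factor is p
        some_on = _best_with_one_on(cpt.children, best, n)
        m1 = np.maximum(all_off * p, some_on)
        m0 = all_off * (1 - p)
        best[t] = np.stack([lik[t][0] * m0, lik[t][1] * m1])
        choice[t] = {"all_off": all_off, "some_on": some_on}
    # decode downward
    states = np.zeros((n, len(order)), dtype=int)
    idx = {t: j for j, t in enumerate(order)}
    root = order[0]
    states[:, idx[root]] = np.argmax(best[root], axis=0)
    for t in order:
        cpt = m.structure[t]
        if not cpt.children:
            continue
        xt = states[:, idx[t]]
        p = float(cpt.p_all_off)  # type: ignore[arg-type]
        all_off = choice[t]["all_off"]
        some_on = choice[t]["some_on"]
        prefer_off = (xt == 0) | ((xt == 1) & (all_off * p >= some_on))
        if np.any(~prefer_off):
            on_child = _argbest_on_child(cpt.children, best, n)
        for j, c in enumerate(cpt.children):
            take_on = np.zeros(n, dtype=bool)
            if np.any(~prefer_off):
                # children free; force at least the best "on" child on
                free_on = best[c][1] >= best[c][0]
                take_on = (~prefer_off) & (free_on | (on_child == j))
            states[:, idx[c]] = take_on.astype(int)
    return PosteriorTable(list(pairs), list(order), states.astype(float))


def _best_with_one_on(children, best, n) -> np.ndarray:
    """max over child configs with >= 1 child on of the product of child bests."""
    free = np.ones(n)
    for c in children:
        free = free * np.maximum(best[c][0], best[c][1])
    # penalty of forcing child c on when off was better
    worst = np.full(n, -np.inf)
    for c in children:
        ratio = np.where(best[c][1] >= best[c][0], 1.0,
                         best[c][1] / np.maximum(best[c][0], 1e-300))
        worst = np.maximum(worst, ratio)
    return free * worst


def _argbest_on_child(children, best, n) -> np.ndarray:
    ratios = np.stack([
        np.where(best[c][1] >= best[c][0], 1.0,
                 best[c][1] / np.maximum(best[c][0], 1e-300))
        for c in children
    ])
    return np.argmax(ratios, axis=0)


# -- pipeline --------------------------------------------------------------


def predict_pipeline(
    m: HierarchicalModel,
    classifiers: Mapping[str, BaggedClassifier],
    features: Mapping[str, FeatureVectorTable],
    pairs: Sequence[GenePair] | None = None,
    mode: Literal["marginal", "map"] = "marginal",
) -> PosteriorTable:
    """Score -> discretize -> infer, for every modeled term at once.

    ``features[t]`` must cover the inference pairs in t's own feature
    space.  The inference instance is an ordered pair; undirected terms
    receive orientation-invariant features upstream, so their evidence
    (and hence the posterior) is identical for both orientations.
    """
    scores: dict[str, ScoreTable] = {}
    for t in m.terms:
        if t not in classifiers or t not in features:
            raise KeyError(f"classifier or features missing for modeled term {t!r}")
        table = features[t]
        if pairs is not None:
            table = table.subset_rows(list(pairs))
        scores[t] = predict_scores(classifiers[t], table)
    infer = infer_posteriors if mode == "marginal" else map_assignment
    return infer(m, scores, pairs=pairs)


# -- model bundle serialization -------------------------------------------


def save_model(m: HierarchicalModel, directory: str | Path) -> None:
    """Write a plain-text model bundle (ontology + per-term tables + manifest)."""
    from .ontology import save_ontology

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_ontology(m.ontology, d / "ontology.tsv")
    with open(d / "discretizers.tsv", "w") as fh:
        for t in m.terms:
            ds = m.discretizers[t]
            fh.write("\t".join([t, repr(float(ds.mean)), repr(float(ds.sd)), str(ds.n_bins),
                                ",".join(repr(float(e)) for e in ds.edges)]) + "\n")
    with open(d / "observation.tsv", "w") as fh:
        for t in m.terms:
            for x in (0, 1):
                row = ",".join(repr(float(v)) for v in m.observation[t].table[x])
                fh.write(f"{t}\t{x}\t{row}\n")
    with open(d / "structure.tsv", "w") as fh:
        for t in m.terms:
            s = m.structure[t]
            fh.write("\t".join([
                t, ",".join(s.children) or "-",
                repr(float(s.p_all_off)) if s.p_all_off is not None else "-",
                repr(float(s.prior)) if s.prior is not None else "-",
            ]) + "\n")
    (d / "manifest.json").write_text(json.dumps({"format": "ontoweave-model", "version": 1}))


def load_model(directory: str | Path) -> HierarchicalModel:
    from .ontology import load_ontology

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("version") != 1:
        raise ValueError(f"unsupported model bundle version {manifest.get('version')!r}")
    o = load_ontology(d / "ontology.tsv")
    disc: dict[str, DiscretizationScheme] = {}
    for line in (d / "discretizers.tsv").read_text().splitlines():
        t, mean, sd, n_bins, edges = line.split("\t")
        disc[t] = DiscretizationScheme(
            t, float(mean), float(sd), int(n_bins),
            np.array([float(e) for e in edges.split(",")]),
        )
    rows: dict[str, dict[int, np.ndarray]] = {}
    for line in (d / "observation.tsv").read_text().splitlines():
        t, x, row = line.split("\t")
        rows.setdefault(t, {})[int(x)] = np.array([float(v) for v in row.split(",")])
    obs = {t: ObservationCPT(t, np.stack([r[0], r[1]])) for t, r in rows.items()}
    struct: dict[str, StructuralCPT] = {}
    for line in (d / "structure.tsv").read_text().splitlines():
        t, kids, p_all_off, prior = line.split("\t")
        struct[t] = StructuralCPT(
            t, tuple(kids.split(",")) if kids != "-" else (),
            p_all_off=None if p_all_off == "-" else float(p_all_off),
            prior=None if prior == "-" else float(prior),
        )
    return HierarchicalModel(o, disc, obs, struct)


def save_posteriors(p: PosteriorTable, directory: str | Path) -> None:
    """Per-term weighted edge lists: gene_a, gene_b, posterior."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for j, t in enumerate(p.terms):
        with open(d / f"{t}.tsv", "w") as fh:
            for pair, v in zip(p.pairs, p.posterior[:, j]):
                fh.write(f"{pair.a}\t{pair.b}\t{v:.10g}\n")
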