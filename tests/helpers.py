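"""Independent oracles used across the test suite.

Everything here deliberately avoids the code paths it checks: posterior
marginals come from brute-force enumeration of the joint, AUC from
explicit concordant-pair counting, graphlet orbits from combination
enumeration plus networkx isomorphism matching, and triads from
canonical-code classification over node permutations.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from ontoweave.base_learner import ScoreTable
from ontoweave.gold_standard import GenePair
from ontoweave.ontology import InteractionOntology, Term
from ontoweave.reconcile import (DiscretizationScheme, HierarchicalModel,
                                 ObservationCPT, StructuralCPT)


# -- random decorated-tree models -----------------------------------------


def random_tree(n: int, rng: np.random.Generator) -> InteractionOntology:
    terms = {"t0": Term("t0")}
    for i in range(1, n):
        terms[f"t{i}"] = Term(f"t{i}", parent=f"t{int(rng.integers(i))}")
    return InteractionOntology(terms)


def random_model(o: InteractionOntology, rng: np.random.Generator,
                 n_bins: int = 4) -> HierarchicalModel:
    disc, obs, struct = {}, {}, {}
    for t in o.terms:
        disc[t] = DiscretizationScheme(t, 0.0, 0.4, n_bins,
                                       np.linspace(-2, 2, n_bins + 1))
        tab = rng.random((2, n_bins)) + 0.1
        tab /= tab.sum(axis=1, keepdims=True)
        obs[t] = ObservationCPT(t, tab)
        kids = tuple(o.children[t])
        if kids:
            struct[t] = StructuralCPT(t, kids, p_all_off=float(rng.uniform(0.05, 0.95)))
        else:
            struct[t] = StructuralCPT(t, (), prior=float(rng.uniform(0.05, 0.95)))
    return HierarchicalModel(o, disc, obs, struct)


def random_scores(m: HierarchicalModel, rng: np.random.Generator,
                  pair: GenePair) -> dict[str, ScoreTable]:
    return {t: ScoreTable(t, [pair], np.array([float(rng.uniform(-3, 3))]))
            for t in m.ontology.terms}


def enumerate_posteriors(m: HierarchicalModel, bins: dict[str, int]) -> np.ndarray:
    """Marginals by explicit summation over all 2^n latent assignments."""
    terms = m.terms
    n = len(terms)
    assign = np.array(list(itertools.product([0, 1], repeat=n)))  # (2^n, n)
    logp = np.zeros(len(assign))
    prob = np.ones(len(assign))
    for j, t in enumerate(terms):
        x = assign[:, j]
        s = m.structure[t]
        if s.children:
            kidx = [terms.index(c) for c in s.children]
            any_on = assign[:, kidx].any(axis=1)
            p1 = np.where(any_on, 1.0, s.p_all_off)
        else:
            p1 = np.full(len(assign), s.prior)
        prob *= np.where(x == 1, p1, 1 - p1)
        prob *= m.observation[t].table[x, bins[t]]
    z = prob.sum()
    del logp
    return (assign * prob[:, None]).sum(axis=0) / z


# -- rank statistics -------------------------------------------------------


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair counting over the positive x negative grid, ties 1/2."""
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


# -- graphlet orbits -------------------------------------------------------


def reference_graphlet_graphs():
    """The catalog's graphlets as networkx graphs, with their orbit labels.

    The per-graphlet orbit partition is re-derived here from networkx
    automorphisms and asserted against the catalog labels, so the
    catalog's partition is cross-checked by an independent library.
    """
    from ontoweave._graphlets import catalog

    graphlets, _ = catalog()
    out = []
    for gl in graphlets:
        g = nx.Graph()
        g.add_nodes_from(range(gl.size))
        g.add_edges_from(gl.edges)
        gm = nx.algorithms.isomorphism.GraphMatcher(g, g)
        orbit_sets: dict[int, set[int]] = {v: {v} for v in g}
        for mapping in gm.isomorphisms_iter():
            for a, b in mapping.items():
                orbit_sets[a].add(b)
        partition = {v: frozenset(orbit_sets[v]) for v in g}
        catalog_partition = {}
        for v in g:
            catalog_partition[v] = frozenset(
                u for u in g if gl.orbits[u] == gl.orbits[v]
            )
        assert partition == catalog_partition, (
            f"catalog orbit partition disagrees with automorphisms for G{gl.index}"
        )
        out.append((gl, g))
    return out


def brute_force_orbit_counts(g: nx.Graph) -> np.ndarray:
    """Orbit counts via exhaustive combination enumeration + isomorphism."""
    refs = reference_graphlet_graphs()
    nodes = sorted(g.nodes())
    node_index = {v: i for i, v in enumerate(nodes)}
    counts = np.zeros((len(nodes), 73), dtype=np.int64)
    # adjacency bitmasks for a fast connectivity prefilter
    bits = {v: 0 for v in nodes}
    for a, b in g.edges():
        bits[a] |= 1 << node_index[b]
        bits[b] |= 1 << node_index[a]
    for k in (2, 3, 4, 5):
        cands = [(gl, ref) for gl, ref in refs if gl.size == k]
        for combo in itertools.combinations(nodes, k):
            member = 0
            for v in combo:
                member |= 1 << node_index[v]
            # BFS on bitmasks
            frontier = 1 << node_index[combo[0]]
            seen = frontier
            while frontier:
                nxt = 0
                for v in combo:
                    if frontier >> node_index[v] & 1:
                        nxt |= bits[v] & member
                frontier = nxt & ~seen
                seen |= nxt
            if seen != member:
                continue
            sub = g.subgraph(combo)
            for gl, ref in cands:
                gm = nx.algorithms.isomorphism.GraphMatcher(ref, sub)
                if gm.is_isomorphic():
                    for ref_node, sub_node in gm.mapping.items():
                        counts[node_index[sub_node], gl.orbits[ref_node]] += 1
                    break
            else:  # pragma: no cover - catalog covers all connected graphs
                raise AssertionError("connected subgraph matched no graphlet")
    return counts, nodes


# -- directed triads -------------------------------------------------------

_TRIAD_PERMS = list(itertools.permutations(range(3)))


def _triad_code(edges: set[tuple[int, int]]) -> int:
    """Canonical 6-bit code of a labeled 3-node digraph (min over relabelings)."""
    slots = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    best = None
    for perm in _TRIAD_PERMS:
        code = 0
        for bit, (i, j) in enumerate(slots):
            if (perm[i], perm[j]) in edges:
                code |= 1 << bit
        if best is None or code < best:
            best = code
    return best


#: canonical codes of known triad classes, from defining examples
TRIAD_EXAMPLES = {
    "021D": {(0, 1), (0, 2)},
    "021U": {(1, 0), (2, 0)},
    "021C": {(0, 1), (1, 2)},
    "030T": {(0, 1), (0, 2), (1, 2)},          # feed-forward loop
    "030C": {(0, 1), (1, 2), (2, 0)},          # 3-cycle
    "111D": {(0, 1), (1, 0), (2, 0)},
    "111U": {(0, 1), (1, 0), (0, 2)},
    "201": {(0, 1), (1, 0), (0, 2), (2, 0)},
    "120D": {(0, 1), (1, 0), (2, 0), (2, 1)},
    "120U": {(0, 1), (1, 0), (0, 2), (1, 2)},
    "120C": {(0, 1), (1, 0), (2, 0), (1, 2)},
    "210": {(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)},
    "300": {(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)},
}


def brute_force_triad_census(g: nx.DiGraph) -> dict[int, int]:
    """Connected-triad counts keyed by canonical code."""
    counts: dict[int, int] = {}
    nodes = sorted(g.nodes())
    for combo in itertools.combinations(nodes, 3):
        local = {v: i for i, v in enumerate(combo)}
        edges = {(local[a], local[b]) for a, b in g.subgraph(combo).edges()}
        und = nx.Graph()
        und.add_nodes_from(range(3))
        und.add_edges_from((a, b) for a, b in edges)
        if not nx.is_connected(und):
            continue
        code = _triad_code(edges)
        counts[code] = counts.get(code, 0) + 1
    return counts
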