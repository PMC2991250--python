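"""Catalog of the 30 connected 2-5 node graphlets and their 73 orbits.

Everything here is generated at first use by brute force over all
labeled graphs on up to five nodes, so the catalog is correct by
construction rather than transcribed: isomorphism classes come from
minimizing the adjacency bitmask over node permutations, and orbits are
the equivalence classes of nodes under the automorphism group.

Graphlets are numbered by (size, edge count, lexicographic sorted
degree sequence, canonical mask); for sizes up to four this reproduces
the conventional numbering (G0 edge; G1 path, G2 triangle; G3 path, G4
star, G5 cycle, G6 paw, G7 diamond, G8 clique), giving the familiar
orbit ids 0 (edge endpoint), 1/2 (path end/middle) and 3 (triangle).
Within a graphlet, orbits are ordered by increasing node degree, then
by the sorted multiset of neighbor degrees, then by canonical position.
Five-node numbering is this package's own deterministic convention;
both networks of any comparison use the same catalog, which is all the
degree-distribution agreement metric requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

SIZES = (2, 3, 4, 5)
_PAIRS = {k: list(itertools.combinations(range(k), 2)) for k in SIZES}
_PAIR_INDEX = {k: {p: i for i, p in enumerate(_PAIRS[k])} for k in SIZES}


@dataclass(frozen=True)
class Graphlet:
    index: int                  # G0 .. G29
    size: int
    mask: int                   # canonical adjacency bitmask
    edges: tuple[tuple[int, int], ...]
    orbits: tuple[int, ...]     # global orbit id per canonical node position


def _adj(k: int, mask: int) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(k)]
    for bit, (i, j) in enumerate(_PAIRS[k]):
        if mask >> bit & 1:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def _connected(adj: list[set[int]]) -> bool:
    seen = {0}
    stack = [0]
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == len(adj)


def _permute(k: int, mask: int, perm: tuple[int, ...]) -> int:
    """Relabeled mask: new graph has edge (i, j) iff old has (perm[i], perm[j])."""
    out = 0
    index = _PAIR_INDEX[k]
    for bit, (i, j) in enumerate(_PAIRS[k]):
        a, b = perm[i], perm[j]
        if a > b:
            a, b = b, a
        if mask >> index[(a, b)] & 1:
            out |= 1 << bit
    return out


@lru_cache(maxsize=None)
def _perms(k: int) -> tuple[tuple[int, ...], ...]:
    return tuple(itertools.permutations(range(k)))


def _canonical(k: int, mask: int) -> int:
    return min(_permute(k, mask, p) for p in _perms(k))


def _degrees(k: int, mask: int) -> list[int]:
    return [len(a) for a in _adj(k, mask)]


@lru_cache(maxsize=1)
def catalog() -> tuple[tuple[Graphlet, ...], dict[int, dict[int, tuple[int, ...]]]]:
    """Return (graphlets, lookup) where lookup[k][mask] maps every labeled
    connected adjacency bitmask on k nodes to the global orbit id of each
    node position."""
    reps: list[tuple[int, int]] = []  # (k, canonical mask)
    members: dict[tuple[int, int], list[int]] = {}
    for k in SIZES:
        seen: set[int] = set()
        for mask in range(1 << len(_PAIRS[k])):
            if not _connected(_adj(k, mask)):
                continue
            c = _canonical(k, mask)
            members.setdefault((k, c), []).append(mask)
            if c not in seen:
                seen.add(c)
                reps.append((k, c))
    reps.sort(key=lambda kc: (
        kc[0], bin(kc[1]).count("1"),
        tuple(sorted(_degrees(kc[0], kc[1]), reverse=True)), kc[1],
    ))
    assert len(reps) == 30, f"expected 30 graphlets, built {len(reps)}"

    graphlets: list[Graphlet] = []
    next_orbit = 0
    canon_orbits: dict[tuple[int, int], tuple[int, ...]] = {}
    for gi, (k, c) in enumerate(reps):
        auts = [p for p in _perms(k) if _permute(k, c, p) == c]
        # node v and p[...]: position i of the relabeled graph holds node p[i];
        # automorphisms identify v with p.index(v)
        orbit_of = list(range(k))
        for p in auts:
            for i in range(k):
                a, b = orbit_of[i], orbit_of[p[i]]
                if a != b:
                    lo, hi = min(a, b), max(a, b)
                    orbit_of = [lo if o == hi else o for o in orbit_of]
        deg = _degrees(k, c)
        adj = _adj(k, c)
        classes = sorted(
            set(orbit_of),
            key=lambda o: (
                deg[orbit_of.index(o)],
                tuple(sorted(deg[u] for u in adj[orbit_of.index(o)])),
                orbit_of.index(o),
            ),
        )
        remap = {o: next_orbit + r for r, o in enumerate(classes)}
        next_orbit += len(classes)
        final = tuple(remap[o] for o in orbit_of)
        canon_orbits[(k, c)] = final
        graphlets.append(Graphlet(
            index=gi, size=k, mask=c,
            edges=tuple(p for bit, p in enumerate(_PAIRS[k]) if c >> bit & 1),
            orbits=final,
        ))
    assert next_orbit == 73, f"expected 73 orbits, built {next_orbit}"

    lookup: dict[int, dict[int, tuple[int, ...]]] = {k: {} for k in SIZES}
    for (k, c), masks in members.items():
        corb = canon_orbits[(k, c)]
        for mask in masks:
            for p in _perms(k):
                if _permute(k, mask, p) == c:
                    # position i of canonical graph holds node p[i] of mask
                    orbits = [0] * k
                    for i in range(k):
                        orbits[p[i]] = corb[i]
                    lookup[k][mask] = tuple(orbits)
                    break
    return tuple(graphlets), lookup


N_ORBITS = 73
N_GRAPHLETS = 30
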