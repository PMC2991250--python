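"""Interaction ontology: a rooted tree of interaction types.

The ontology plays two roles.  First, it organizes gene-pair labels:
annotation to a term implies annotation to every ancestor (the true-path
rule), so the hierarchy defines how gold standards are propagated.
Second, its tree is the skeleton of the Bayesian network used to
reconcile per-term classifier scores into consistent posteriors: each
term contributes one latent label variable whose distribution is
conditioned on its child terms.

Terms carry a ``directed`` flag: pairs annotated to a directed term
(e.g. kinase -> substrate phosphorylation) are ordered, while pairs of
an undirected term (e.g. physical interaction) are unordered.  A
directed term may sit below an undirected parent; the reverse is legal
but flagged, since an unordered annotation cannot acquire a direction
when propagated upward into a directed term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class OntologyError(ValueError):
    """Structural problem in an ontology definition (cycle, double root, ...)."""


@dataclass(frozen=True)
class Term:
    """One interaction type.

    Parameters
    ----------
    id : str
        Unique term identifier.
    name : str
        Human-readable description.
    directed : bool
        Whether gene pairs of this type are ordered.
    parent : str or None
        Parent term id; ``None`` for the root.
    """

    id: str
    name: str = ""
    directed: bool = False
    parent: str | None = None


@dataclass
class InteractionOntology:
    """A validated rooted tree of :class:`Term` objects.

    ``children`` preserves the order in which child terms were declared,
    which keeps downstream iteration (and file round-trips) deterministic.
    """

    terms: dict[str, Term]
    children: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {tid: [] for tid in self.terms}
            for t in self.terms.values():
                if t.parent is not None and t.parent in self.children:
                    self.children[t.parent].append(t.id)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def validate(self) -> None:
        for t in self.terms.values():
            if t.parent is not None and t.parent not in self.terms:
                raise OntologyError(f"term {t.id!r}: dangling parent {t.parent!r}")
        # every node must reach a root without revisiting a node
        for tid in self.terms:
            seen = {tid}
            cur = self.terms[tid].parent
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle through term {cur!r}")
                seen.add(cur)
                cur = self.terms[cur].parent
        roots = [t.id for t in self.terms.values() if t.parent is None]
        if len(roots) == 0:
            raise OntologyError("no root term (every term has a parent)")
        if len(roots) > 1:
            raise OntologyError(f"multiple roots: {sorted(roots)}")
        self._root = roots[0]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term {term_id!r}") from None

    def is_directed(self, term_id: str) -> bool:
        return self._require(term_id).directed

    def is_leaf(self, term_id: str) -> bool:
        self._require(term_id)
        return not self.children[term_id]

    def leaves(self) -> list[str]:
        return [tid for tid in self.topological_order() if self.is_leaf(tid)]

    def topological_order(self) -> list[str]:
        """Terms in breadth-first order from the root (parents before children)."""
        order, frontier = [], [self.root]
        while frontier:
            nxt: list[str] = []
            for tid in frontier:
                order.append(tid)
                nxt.extend(self.children[tid])
            frontier = nxt
        return order

    def ancestors(self, term_id: str) -> list[str]:
        """Path from ``term_id``'s parent up to the root, exclusive of the term."""
        t = self._require(term_id)
        path: list[str] = []
        cur = t.parent
        while cur is not None:
            path.append(cur)
            cur = self.terms[cur].parent
        return path

    def depth(self, term_id: str) -> int:
        return len(self.ancestors(term_id))


# -- loading / saving ------------------------------------------------------


def load_ontology(path: str | Path) -> InteractionOntology:
    """Read an ontology from the 4-column TSV dialect.

    One term per line: ``term_id <TAB> parent_id|- <TAB> directed(0/1)
    <TAB> name``.  ``-`` marks the root.  Child order follows file order.
    Files whose first non-blank line is ``[Term]`` or starts with
    ``format-version`` are dispatched to the OBO-subset reader.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("[Term]") or stripped.startswith("format-version"):
        return _parse_obo(text)
    terms: dict[str, Term] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise OntologyError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        tid, parent, directed = parts[0], parts[1], parts[2]
        name = parts[3] if len(parts) > 3 else ""
        if tid in terms:
            raise OntologyError(f"{path}:{lineno}: duplicate term id {tid!r}")
        if directed not in {"0", "1"}:
            raise OntologyError(f"{path}:{lineno}: directed flag must be 0 or 1")
        terms[tid] = Term(
            id=tid,
            name=name,
            directed=directed == "1",
            parent=None if parent == "-" else parent,
        )
    try:
        return InteractionOntology(terms)
    except OntologyError as e:
        raise OntologyError(f"{path}: {e}") from None


def save_ontology(o: InteractionOntology, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_ontology` (file order = BFS)."""
    lines = []
    for tid in o.topological_order():
        t = o.terms[tid]
        lines.append(
            "\t".join([t.id, t.parent if t.parent is not None else "-",
                       "1" if t.directed else "0", t.name])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_obo(text: str) -> InteractionOntology:
    """Minimal OBO subset: [Term] stanzas with id / name / is_a lines and an
    optional ``property_value: directed "true"`` tag."""
    terms: dict[str, Term] = {}
    cur: dict[str, object] | None = None

    def flush() -> None:
        if cur is None or "id" not in cur:
            return
        tid = str(cur["id"])
        if tid in terms:
            raise OntologyError(f"duplicate term id {tid!r}")
        terms[tid] = Term(
            id=tid,
            name=str(cur.get("name", "")),
            directed=bool(cur.get("directed", False)),
            parent=cur.get("is_a"),  # type: ignore[arg-type]
        )

    for raw in text.splitlines():
        line = raw.strip()
        if line == "[Term]":
            flush()
            cur = {}
        elif cur is not None and ":" in line:
            key, _, val = line.partition(":")
            val = val.strip()
            if key == "id":
                cur["id"] = val
            elif key == "name":
                cur["name"] = val
            elif key == "is_a":
                cur["is_a"] = val.split("!")[0].strip()
            elif key == "property_value" and "directed" in val:
                cur["directed"] = "true" in val.lower()
    flush()
    if not terms:
        raise OntologyError("no [Term] stanzas found")
    return InteractionOntology(terms)


# -- term selection --------------------------------------------------------


def filter_terms(
    o: InteractionOntology,
    positive_counts: Mapping[str, int],
    min_annotations: int = 70,
) -> set[str]:
    """Terms with strictly more than ``min_annotations`` positive labels.

    The retained set is closed upward: every ancestor of a retained term
    is retained.  After true-path propagation ancestor counts dominate
    descendant counts, so closure is a no-op on propagated standards —
    it is enforced anyway so the modeled subtree is always a valid tree.
    """
    missing = [t for t in o.terms if t not in positive_counts]
    if missing:
        raise KeyError(f"no positive counts for terms {sorted(missing)}")
    kept = {t for t in o.terms if positive_counts[t] > min_annotations}
    for t in list(kept):
        kept.update(o.ancestors(t))
    return kept


def subtree(o: InteractionOntology, keep: Iterable[str]) -> InteractionOntology:
    """Restrict the ontology to ``keep`` (must be upward-closed)."""
    keep = set(keep)
    for t in keep:
        missing = [u for u in o.ancestors(t) if u not in keep]
        if missing:
            raise OntologyError(f"term set not upward-closed: {t!r} kept, {missing} not")
    terms = {tid: o.terms[tid] for tid in keep}
    children = {tid: [c for c in o.children[tid] if c in keep] for tid in keep}
    return InteractionOntology(terms, children)
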