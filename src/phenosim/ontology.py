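"""Ontology loading, extension and DAG queries.

An :class:`Ontology` is a directed acyclic graph of terms linked by is-a
edges (child -> parent).  The reflexive-transitive ancestor closure is
precomputed at construction time: every term is an ancestor of itself, so
the most-informative-common-ancestor similarity of a term with itself
equals its own information content.

Only ``id``, ``name``, ``is_a``, ``alt_id`` and ``is_obsolete`` tags of the
OBO 1.2/1.4 flat format are interpreted; other relationship types
(``part_of`` etc.) are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "Ontology",
    "OntologyError",
    "load_obo",
    "extend_ontology",
    "ancestors",
    "summary_subgraph",
    "SummarySubgraph",
]


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, dangling edge, bad id)."""


@dataclass(frozen=True)
class Term:
    """A single ontology class."""

    id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class Ontology:
    """Immutable DAG of terms with precomputed reflexive ancestor closure.

    Parameters
    ----------
    terms
        Iterable of :class:`Term`.  Parent references must resolve to terms
        in the same iterable; the graph must be acyclic.
    aliases
        Optional mapping of alternative ids (``alt_id`` in OBO) to
        canonical ids.
    """

    def __init__(self, terms: Iterable[Term], aliases: Mapping[str, str] | None = None):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t
        self.aliases: dict[str, str] = dict(aliases or {})
        self._warned_aliases: set[str] = set()

        dangling = sorted(
            p for t in self.terms.values() for p in t.parents if p not in self.terms
        )
        if dangling:
            raise OntologyError(f"is_a targets not present in ontology: {dangling}")

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.id, p)  # child -> parent
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            member = next(iter(nx.find_cycle(g)))[0]
            raise OntologyError(f"cycle in is-a graph involving {member!r}") from None
        self.graph = g

        # parents precede children when we walk the reversed topological order
        closure: dict[str, frozenset[str]] = {}
        for tid in reversed(order):
            acc: set[str] = {tid}
            for p in self.terms[tid].parents:
                acc |= closure[p]
            closure[tid] = frozenset(acc)
        self.ancestor_closure: dict[str, frozenset[str]] = closure
        self.roots: frozenset[str] = frozenset(
            tid for tid, t in self.terms.items() if not t.parents
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.aliases

    def resolve(self, term_id: str) -> str:
        """Return the canonical id for ``term_id``, resolving alt_id aliases."""
        if term_id in self.terms:
            return term_id
        if term_id in self.aliases:
            if term_id not in self._warned_aliases:
                self._warned_aliases.add(term_id)
                logger.warning(
                    "alias %s resolved to canonical id %s", term_id, self.aliases[term_id]
                )
            return self.aliases[term_id]
        raise OntologyError(f"unknown term id {term_id!r}")

    def parents_of(self, term_id: str) -> frozenset[str]:
        return self.terms[self.resolve(term_id)].parents

    def ancestors_of(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive is-a closure of a single term."""
        return self.ancestor_closure[self.resolve(term_id)]

    def closure_to_json(self) -> str:
        return json.dumps(
            {tid: sorted(anc) for tid, anc in self.ancestor_closure.items()},
            indent=2,
            sort_keys=True,
        )


def _parse_obo_stanzas(text: str):
    """Yield (tag, value) lists for each [Term] stanza of an OBO document."""
    stanza: list[tuple[str, str]] | None = None
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if stanza is not None:
                yield stanza
            stanza = [] if line == "[Term]" else None
            continue
        if stanza is None or ":" not in line:
            continue
        tag, value = line.split(":", 1)
        stanza.append((tag.strip(), value.strip()))
    if stanza is not None:
        yield stanza


def load_obo(path, keep_obsolete: bool = False) -> Ontology:
    """Load an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Obsolete terms are dropped (with their edges) unless ``keep_obsolete``;
    ``alt_id`` entries are recorded as aliases resolving to the canonical id.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()

    terms: list[Term] = []
    aliases: dict[str, str] = {}
    for stanza in _parse_obo_stanzas(text):
        tags: dict[str, list[str]] = {}
        for tag, value in stanza:
            tags.setdefault(tag, []).append(value)
        tid = tags.get("id", [None])[0]
        if tid is None:
            continue
        obsolete = tags.get("is_obsolete", ["false"])[0].lower() == "true"
        if obsolete and not keep_obsolete:
            continue
        parents = frozenset(v.split()[0] for v in tags.get("is_a", []))
        terms.append(
            Term(
                id=tid,
                name=tags.get("name", [""])[0],
                parents=parents,
                obsolete=obsolete,
            )
        )
        for alt in tags.get("alt_id", []):
            aliases[alt] = tid
    return Ontology(terms, aliases=aliases)


def extend_ontology(
    onto: Ontology, new_terms: Sequence[tuple[str, str, Iterable[str]]]
) -> Ontology:
    """Return a new ontology enlarged with ``(id, name, parent_ids)`` triples.

    Closure is recomputed from scratch; the result is identical to building
    the enlarged ontology in one pass.
    """
    existing = dict(onto.terms)
    added: list[Term] = []
    for tid, name, parent_ids in new_terms:
        if tid in existing or any(t.id == tid for t in added):
            raise OntologyError(f"duplicate term id {tid!r}")
        parents = frozenset(parent_ids)
        missing = sorted(
            p
            for p in parents
            if p not in existing and not any(t.id == p for t in added)
        )
        if missing:
            raise OntologyError(f"parent terms not found: {missing}")
        added.append(Term(id=tid, name=name, parents=parents))
    return Ontology(list(existing.values()) + added, aliases=onto.aliases)


def ancestors(onto: Ontology, term_ids: Iterable[str]) -> set[str]:
    """Union of reflexive-transitive ancestor sets of ``term_ids``."""
    out: set[str] = set()
    for tid in term_ids:
        out |= onto.ancestors_of(tid)
    return out


@dataclass
class SummarySubgraph:
    """Condensed view of the is-a relations among a set of displayed terms.

    ``direct`` edges connect a node to a displayed parent; ``indirect``
    edges connect a node to a displayed proper ancestor whose path runs
    only through omitted nodes.  Both edge sets are transitively reduced
    over the displayed node set.
    """

    nodes: set[str]
    direct: set[tuple[str, str]]
    indirect: set[tuple[str, str]]

    def to_dot(self, onto: Ontology | None = None) -> str:
        def label(n: str) -> str:
            if onto is not None and n in onto.terms and onto.terms[n].name:
                return f"{n}\\n{onto.terms[n].name}"
            return n

        lines = ["digraph summary {", "  rankdir=BT;"]
        for n in sorted(self.nodes):
            lines.append(f'  "{n}" [label="{label(n)}"];')
        for x, y in sorted(self.direct):
            lines.append(f'  "{x}" -> "{y}";')
        for x, y in sorted(self.indirect):
            lines.append(f'  "{x}" -> "{y}" [style=dashed];')
        lines.append("}")
        return "\n".join(lines)


def summary_subgraph(
    onto: Ontology,
    term_ids: Iterable[str],
    display_nodes: Iterable[str] | None = None,
) -> SummarySubgraph:
    """Summarise the ancestor graph of ``term_ids``.

    Nodes default to the full reflexive ancestor set of ``term_ids``;
    passing ``display_nodes`` restricts the drawing to a subset, in which
    case relations through omitted intermediates become indirect (dashed)
    edges.  An empty term set yields an empty subgraph.
    """
    term_ids = {onto.resolve(t) for t in term_ids}
    if not term_ids:
        return SummarySubgraph(set(), set(), set())
    full = ancestors(onto, term_ids)
    nodes = set(full) if display_nodes is None else {onto.resolve(d) for d in display_nodes}

    direct: set[tuple[str, str]] = set()
    indirect: set[tuple[str, str]] = set()
    for x in nodes:
        proper_anc = onto.ancestors_of(x) - {x}
        shown = proper_anc & nodes
        for y in shown:
            # transitive reduction: keep (x, y) only if no displayed node
            # lies strictly between x and y
            covered = any(
                z != y and y in (onto.ancestors_of(z) - {z}) for z in shown
            )
            if covered:
                continue
            if y in onto.parents_of(x):
                direct.add((x, y))
            else:
                indirect.add((x, y))
    return SummarySubgraph(nodes, direct, indirect)
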