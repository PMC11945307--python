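"""Ontology DAG construction from OBO flat files.

Terms connected by ``is_a`` edges form a rooted directed acyclic graph.
Edges are stored child -> parent throughout the package. Each node carries a
*level*: 1 + the number of edges on the longest path from the root, so the
root sits at level 1 and more specific terms at higher levels. Nodes on one
level never share an edge, which lets the enrichment traversal process a
level's nodes independently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import AnnotationTable

logger = logging.getLogger(__name__)

_QUOTED = re.compile(r'"(.*?)(?<!\\)"')


@dataclass
class Term:
    """A single ontology term as read from one ``[Term]`` stanza."""

    id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False


class OboParseError(ValueError):
    pass


def parse_obo(path) -> list[Term]:
    """Parse an OBO 1.2/1.4 flat file into a list of :class:`Term`.

    Only ``[Term]`` stanzas are read; ``[Typedef]`` and other stanza types
    are skipped. Synonym lines keep the quoted surface string only; trailing
    ``!`` comments on ``is_a`` targets are stripped. A stanza without an
    ``id`` raises :class:`OboParseError` naming the stanza index.
    """
    terms: list[Term] = []
    current: dict | None = None
    in_term = False
    stanza_index = 0

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise OboParseError(f"[Term] stanza #{current['_index']} has no id")
        terms.append(
            Term(
                id=current["id"],
                name=current.get("name", ""),
                synonyms=current.get("synonyms", []),
                parents=current.get("parents", []),
                obsolete=current.get("obsolete", False),
            )
        )
        current = None

    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line.startswith("["):
                flush()
                if line == "[Term]":
                    stanza_index += 1
                    current = {"_index": stanza_index}
                    in_term = True
                else:
                    in_term = False
                continue
            if not in_term or current is None or not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "synonym":
                match = _QUOTED.search(value)
                if match:
                    current.setdefault("synonyms", []).append(match.group(1))
            elif key == "is_a":
                target = value.split("!", 1)[0].strip()
                if target:
                    current.setdefault("parents", []).append(target)
            elif key == "is_obsolete":
                current["obsolete"] = value.split("!", 1)[0].strip().lower() == "true"
    flush()
    if not terms:
        raise OboParseError(f"no [Term] stanzas found in {path}")
    return terms


class OntologyGraph:
    """Rooted, leveled DAG over non-obsolete terms (edges child -> parent)."""

    def __init__(self, dag: nx.DiGraph, root: str, names: dict[str, str]):
        self._dag = dag
        self.root = root
        self.names = names
        self.level = assign_levels(self)

    # -- structure ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._dag.nodes)

    @property
    def n_nodes(self) -> int:
        return self._dag.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._dag.number_of_edges()

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Set of (child, parent) pairs."""
        return set(self._dag.edges)

    def __contains__(self, term: str) -> bool:
        return term in self._dag

    def parents(self, term: str) -> list[str]:
        return sorted(self._dag.successors(term))

    def children(self, term: str) -> list[str]:
        return sorted(self._dag.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All proper ancestors of ``term`` up to (and including) the root."""
        return nx.descendants(self._dag, term)

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self._dag, term)

    @property
    def max_level(self) -> int:
        return max(self.level.values())

    def nodes_at_level(self, level: int) -> list[str]:
        return sorted(t for t, l in self.level.items() if l == level)

    def name(self, term: str) -> str:
        return self.names.get(term, "")


def build_graph(terms: Iterable[Term], root_id: str) -> OntologyGraph:
    """Build the is_a DAG of non-obsolete terms reachable from ``root_id``.

    Obsolete terms and their incident edges are dropped. Terms not reachable
    from the root are dropped with a logged warning (real ontologies carry
    disconnected deprecated clusters). A cycle raises an error listing one
    offending cycle.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no terms supplied")
    by_id: dict[str, Term] = {}
    for term in terms:
        if term.id in by_id:
            raise ValueError(f"duplicate term id {term.id}")
        by_id[term.id] = term
    if root_id not in by_id:
        raise ValueError(f"root term {root_id} not present")
    if by_id[root_id].obsolete:
        raise ValueError(f"root term {root_id} is obsolete")

    active = {tid for tid, t in by_id.items() if not t.obsolete}
    dag = nx.DiGraph()
    dag.add_nodes_from(active)
    for tid in active:
        for parent in by_id[tid].parents:
            if parent in active:
                dag.add_edge(tid, parent)  # child -> parent
            else:
                logger.debug("dropping is_a edge %s -> %s (target missing/obsolete)", tid, parent)

    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"is_a relation contains a cycle: {cycle}")

    reachable = {root_id} | nx.ancestors(dag, root_id)
    dropped = active - reachable
    if dropped:
        logger.warning("dropping %d terms not reachable from root %s", len(dropped), root_id)
    sub = dag.subgraph(reachable).copy()
    names = {tid: by_id[tid].name for tid in reachable}
    return OntologyGraph(sub, root_id, names)


def assign_levels(graph: OntologyGraph | nx.DiGraph, root: str | None = None) -> dict[str, int]:
    """Longest-path levels: level(root)=1, level(t)=1+max over parents.

    Raises if a node is unreachable from the root (it would have no level).
    """
    if isinstance(graph, OntologyGraph):
        dag, root = graph._dag, graph.root
    else:
        dag = graph
        if root is None:
            raise ValueError("root required when passing a raw DiGraph")
    level: dict[str, int] = {root: 1}
    # reversed topological order of child->parent edges == parents first
    for node in reversed(list(nx.topological_sort(dag))):
        if node == root:
            continue
        parents = list(dag.successors(node))
        if not parents:
            raise ValueError(f"node {node} is unreachable from root {root}")
        missing = [p for p in parents if p not in level]
        if missing:  # parent itself unreachable
            raise ValueError(f"node {missing[0]} is unreachable from root {root}")
        level[node] = 1 + max(level[p] for p in parents)
    return level


def prune_unannotated(graph: OntologyGraph, annotations: "AnnotationTable") -> OntologyGraph:
    """Iteratively remove leaves whose expanded gene set is empty.

    Expects true-path-expanded annotations. Levels are recomputed on the
    pruned graph, because pruning can remove longest paths. Raises if the
    root itself would be pruned (no annotations anywhere).
    """
    if annotations.expanded is None:
        raise ValueError("annotations must be true-path expanded before pruning")
    dag = graph._dag.copy()
    while True:
        leaves = [t for t in dag.nodes if dag.in_degree(t) == 0]
        empty = [t for t in leaves if not annotations.genes(t)]
        if not empty:
            break
        if graph.root in empty:
            raise ValueError("empty annotation set: root has no annotated genes")
        dag.remove_nodes_from(empty)
    names = {t: graph.names.get(t, "") for t in dag.nodes}
    return OntologyGraph(dag, graph.root, names)


def write_obo(terms: Iterable[Term], path) -> None:
    """Serialize terms as a minimal OBO flat file (round-trips via parse_obo)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        for term in terms:
            handle.write("\n[Term]\n")
            handle.write(f"id: {term.id}\n")
            if term.name:
                handle.write(f"name: {term.name}\n")
            for syn in term.synonyms:
                handle.write(f'synonym: "{syn}" EXACT []\n')
            for parent in term.parents:
                handle.write(f"is_a: {parent}\n")
            if term.obsolete:
                handle.write("is_obsolete: true\n")


def graph_summary(graph: OntologyGraph, annotations: "AnnotationTable | None" = None):
    """One row per node: id, name, level, n_parents, n_children, n_genes."""
    import pandas as pd

    rows = []
    for term in sorted(graph.nodes):
        n_genes = len(annotations.genes(term)) if annotations is not None else 0
        rows.append(
            {
                "term": term,
                "name": graph.name(term),
                "level": graph.level[term],
                "n_parents": len(graph.parents(term)),
                "n_children": len(graph.children(term)),
                "n_genes": n_genes,
            }
        )
    return pd.DataFrame(rows)
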