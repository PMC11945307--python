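"""Gene-term annotations: loading, true-path expansion, dictionary matching.

Direct annotations link a gene to the most specific term it was observed
with. The true-path rule then implies annotation to every ancestor of that
term, so the expansion records, per (term, gene), the *origin distance*: the
minimum number of levels the annotation was inherited upward to reach the
term (0 for a direct annotation). The enrichment core turns this distance
into the initial gene weight.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from .ontology import OntologyGraph, Term

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"term", "term_id", "termid", "doid", "do_id", "ontology_term"}


@dataclass
class AnnotationTable:
    """Direct (gene, term) pairs plus, after expansion, per-term gene maps.

    ``expanded[term][gene]`` holds the origin distance in levels (0 = direct).
    """

    direct: set[tuple[str, str]] = field(default_factory=set)
    expanded: dict[str, dict[str, int]] | None = None
    n_dropped: int = 0

    def genes(self, term: str) -> dict[str, int]:
        """Expanded gene -> origin-distance map for one term."""
        if self.expanded is None:
            raise ValueError("annotations not yet true-path expanded")
        return self.expanded.get(term, {})

    @property
    def background(self) -> set[str]:
        """All genes in the expanded annotation universe."""
        if self.expanded is None:
            raise ValueError("annotations not yet true-path expanded")
        genes: set[str] = set()
        for gene_map in self.expanded.values():
            genes.update(gene_map)
        return genes

    def direct_gene_counts(self) -> Counter:
        """term -> number of directly annotated genes."""
        counts: Counter = Counter()
        for _, term in self.direct:
            counts[term] += 1
        return counts

    def direct_term_counts(self) -> Counter:
        """gene -> number of terms it is directly annotated to."""
        counts: Counter = Counter()
        for gene, _ in self.direct:
            counts[gene] += 1
        return counts


def load_annotations(path, graph: OntologyGraph) -> AnnotationTable:
    """Read a 2+ column TSV (gene, term) of direct annotations.

    Duplicate pairs are collapsed; rows referencing terms absent from the
    graph are dropped with a counted warning. An optional single header line
    is recognized by a conventional term-column label. Expansion is *not*
    applied; call :func:`propagate_true_path`.
    """
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    n_rows = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"malformed annotation row at line {lineno}: {line!r}")
            gene, term = fields[0].strip(), fields[1].strip()
            if lineno == 1 and term not in graph and term.lower() in _HEADER_TOKENS:
                continue  # header line
            n_rows += 1
            if term not in graph:
                dropped += 1
                continue
            pairs.add((gene, term))
    if n_rows == 0:
        raise ValueError(f"no annotation rows in {path}")
    if dropped:
        logger.warning("dropped %d annotation rows with terms absent from the graph", dropped)
    return AnnotationTable(direct=pairs, n_dropped=dropped)


def propagate_true_path(table: AnnotationTable, graph: OntologyGraph) -> AnnotationTable:
    """Expand direct annotations to all ancestors, keeping minimum distances.

    For a direct pair (g, t) and ancestor a, the candidate distance is
    level(t) - level(a); a gene reaching an ancestor through several
    annotated descendants keeps the smallest distance (strongest evidence).
    A direct annotation at the ancestor itself forces distance 0. Rebuilding
    from ``direct`` makes the operation idempotent.
    """
    expanded: dict[str, dict[str, int]] = {t: {} for t in graph.nodes}
    for gene, term in table.direct:
        if term not in graph:
            continue
        t_level = graph.level[term]
        for anc in {term} | graph.ancestors(term):
            dist = t_level - graph.level[anc]
            prev = expanded[anc].get(gene)
            if prev is None or dist < prev:
                expanded[anc][gene] = dist
    return AnnotationTable(direct=set(table.direct), expanded=expanded, n_dropped=table.n_dropped)


def write_annotations(table: AnnotationTable, path) -> None:
    """Write direct pairs back out in the 2-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as handle:
        for gene, term in sorted(table.direct):
            handle.write(f"{gene}\t{term}\n")


# -- dictionary-based free-text annotation ---------------------------------

_MIN_SURFACE_LEN = 3
_WS = re.compile(r"\s+")


@dataclass
class DiseaseDictionary:
    """Normalized surface string -> term id, for concept matching in text."""

    entries: dict[str, str] = field(default_factory=dict)


def _normalize(text: str) -> str:
    return _WS.sub(" ", text.casefold()).strip()


def build_dictionary(terms: list[Term]) -> DiseaseDictionary:
    """Index names and synonyms of non-obsolete terms.

    Surface strings are case-folded and whitespace-normalized; strings
    shorter than 3 characters are excluded. When two terms share a surface
    string, the lexicographically smallest term id wins and a collision is
    logged.
    """
    entries: dict[str, str] = {}
    for term in terms:
        if term.obsolete:
            continue
        for surface in [term.name, *term.synonyms]:
            key = _normalize(surface)
            if len(key) < _MIN_SURFACE_LEN:
                continue
            if key in entries and entries[key] != term.id:
                winner = min(entries[key], term.id)
                logger.warning(
                    "dictionary collision on %r: %s vs %s, keeping %s",
                    key, entries[key], term.id, winner,
                )
                entries[key] = winner
            else:
                entries[key] = term.id
    return DiseaseDictionary(entries=entries)


def annotate_text(dictionary: DiseaseDictionary, text: str) -> set[str]:
    """Case-insensitive longest-match phrase scan at word boundaries.

    A shorter dictionary phrase fully inside an already-chosen longer match
    is suppressed, so "colorectal carcinoma" wins over "carcinoma". This is
    a deliberately simple exact-phrase matcher, not a full concept
    recognizer.
    """
    if not text:
        raise ValueError("empty text")
    haystack = _normalize(text)
    candidates: list[tuple[int, int, str]] = []  # (start, end, term)
    for surface, term in dictionary.entries.items():
        pattern = r"(?<!\w)" + re.escape(surface) + r"(?!\w)"
        for match in re.finditer(pattern, haystack):
            candidates.append((match.start(), match.end(), term))
    # longest spans first; ties resolved left-to-right then by term id
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int]] = []
    hits: set[str] = set()
    for start, end, term in candidates:
        if any(start < e and s < end for s, e in chosen):
            continue
        chosen.append((start, end))
        hits.add(term)
    return hits
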