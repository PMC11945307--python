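"""Double-weighted DAG enrichment: the package's central algorithm.

Classic term-for-term ORA ignores the true-path rule, so ancestors of a
genuinely enriched term look enriched merely because they inherit its
genes. This module counteracts that in two ways:

* **Initial weights** — a gene directly annotated to a term has weight 1
  there; an inherited annotation loses ``weight_step`` (default 0.1) per
  level it travelled upward, floored at ``min_init_weight`` (default 0.5).
* **Dynamic re-weighting** — nodes are visited bottom-up (deepest level
  first). When a child c is locally more significant than its parent t
  (dynamic weight w_d = log p(c) / log p(t) > 1), the weights of c's genes
  at t and all of t's ancestors are divided by w_d times a penalty factor;
  when t dominates, c's own gene weights are multiplied by w_d (< 1) and
  divided by the penalty. The penalty max(0.1 * log(xmin) / (log p(t) +
  log p(c)), 1) bites when parent and child p-values are similar, where
  w_d alone would barely discriminate.

Each node's significance score is the hypergeometric upper tail computed on
floors of weight sums instead of raw counts. Weights only ever decrease
after initialization, and the whole traversal is deterministic (nodes in
lexicographic order within a level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import AnnotationTable
from .ontology import OntologyGraph
from .stats import XMIN, bh_adjust, hypergeom_upper_tail, weighted_significance

logger = logging.getLogger(__name__)

#: scores of exactly 1 are nudged below 1 inside the weight formulas only,
#: because log(1) = 0 would divide by zero; reported p-values are untouched.
_ONE_MINUS = 1.0 - 1e-16

#: guard against float drift when flooring weight sums (1.0 sums are exact,
#: but products of many factors can land at k - 1e-12)
_FLOOR_EPS = 1e-9


@dataclass(frozen=True)
class EnrichmentParams:
    """Tunable parameters of the weighted traversal.

    threshold        raw-p significance cutoff driving the traversal (0.01).
    weight_step      initial-weight decay per inherited level (0.1).
    min_init_weight  floor of initial weights (0.5).
    penalty_scale    scale factor in the penalty formula (0.1).
    min_genes / max_genes
                     optional per-term annotated-gene bounds; terms outside
                     the bounds are skipped entirely (no score). None/0 = off.
    max_refine_iters safety cap on the refinement loop per node.
    reweight         False disables the dynamic/penalty steps (debug flag;
                     with weight_step=0 and min_init_weight=1 the run
                     reduces to classic ORA).
    """

    threshold: float = 0.01
    weight_step: float = 0.1
    min_init_weight: float = 0.5
    penalty_scale: float = 0.1
    min_genes: int | None = None
    max_genes: int | None = None
    max_refine_iters: int = 50
    reweight: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not 0.0 <= self.weight_step < 1.0:
            raise ValueError("weight_step must be in [0, 1)")
        if not 0.0 < self.min_init_weight <= 1.0:
            raise ValueError("min_init_weight must be in (0, 1]")
        if self.penalty_scale <= 0.0:
            raise ValueError("penalty_scale must be positive")


#: parameters reproducing plain term-for-term ORA exactly
CLASSIC_PARAMS = EnrichmentParams(weight_step=0.0, min_init_weight=1.0, reweight=False)


class WeightLedger:
    """Mutable per-(term, gene) weights in (0, 1]; the algorithm's state.

    Every mutation goes through :meth:`shrink` or :meth:`scale`, both of
    which enforce that weights never increase and never reach zero.
    """

    def __init__(self, weights: dict[str, dict[str, float]]):
        self._w = weights

    def get(self, term: str, gene: str) -> float:
        return self._w[term][gene]

    def term_weights(self, term: str) -> dict[str, float]:
        return self._w[term]

    def shrink(self, term: str, gene: str, divisor: float) -> None:
        if divisor < 1.0:
            raise ValueError(f"shrink divisor must be >= 1, got {divisor}")
        self._w[term][gene] = max(self._w[term][gene] / divisor, XMIN)

    def scale(self, term: str, gene: str, factor: float) -> None:
        if not 0.0 < factor <= 1.0:
            raise ValueError(f"scale factor must be in (0, 1], got {factor}")
        self._w[term][gene] = max(self._w[term][gene] * factor, XMIN)


def initial_weights(annotations: AnnotationTable, params: EnrichmentParams) -> WeightLedger:
    """w(t, g) = max(1 - weight_step * origin_distance(t, g), min_init_weight)."""
    if annotations.expanded is None:
        raise ValueError("annotations must be true-path expanded")
    weights = {
        term: {
            gene: max(1.0 - params.weight_step * dist, params.min_init_weight)
            for gene, dist in gene_map.items()
        }
        for term, gene_map in annotations.expanded.items()
    }
    return WeightLedger(weights)


def _clamp_score(p: float) -> float:
    return min(max(p, XMIN), _ONE_MINUS)


def dynamic_weight(p_child: float, p_parent: float) -> float:
    """log p(child) / log p(parent); > 1 iff the child is more significant."""
    if p_child <= 0.0 or p_parent <= 0.0:
        raise ValueError("dynamic_weight requires positive probabilities")
    return math.log(_clamp_score(p_child)) / math.log(_clamp_score(p_parent))


def penalty(p_parent: float, p_child: float, scale: float = 0.1) -> float:
    """max(scale * log(xmin) / (log p_parent + log p_child), 1)."""
    if not 0.0 < p_parent < 1.0 or not 0.0 < p_child < 1.0:
        raise ValueError("penalty requires probabilities in (0, 1)")
    ratio = scale * math.log(XMIN) / (math.log(p_parent) + math.log(p_child))
    return max(ratio, 1.0)


@dataclass
class NodeResult:
    term: str
    name: str
    level: int
    p: float
    p_adjust: float
    gene_ratio: tuple[int, int]  # (r, n), unweighted
    bg_ratio: tuple[int, int]  # (m, N), unweighted
    genes: list[str]


@dataclass
class EnrichmentResult:
    """Per-term results sorted by ascending p (ties broken by term id)."""

    nodes: list[NodeResult]
    params: EnrichmentParams
    background_size: int
    interest_size: int
    warnings: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "term": nd.term,
                "name": nd.name,
                "level": nd.level,
                "p": nd.p,
                "p_adjust": nd.p_adjust,
                "geneRatio": f"{nd.gene_ratio[0]}/{nd.gene_ratio[1]}",
                "bgRatio": f"{nd.bg_ratio[0]}/{nd.bg_ratio[1]}",
                "genes": "/".join(nd.genes),
            }
            for nd in self.nodes
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("DOID\tDOTerm\tlevel\tp\tp_adjust\tgeneRatio\tbgRatio\tgenes\n")
            for nd in self.nodes:
                handle.write(
                    f"{nd.term}\t{nd.name}\t{nd.level}\t{nd.p:.6g}\t{nd.p_adjust:.6g}\t"
                    f"{nd.gene_ratio[0]}/{nd.gene_ratio[1]}\t"
                    f"{nd.bg_ratio[0]}/{nd.bg_ratio[1]}\t"
                    f"{'/'.join(nd.genes)}\n"
                )

    def pvalue(self, term: str) -> float:
        for nd in self.nodes:
            if nd.term == term:
                return nd.p
        raise KeyError(term)

    def rank(self, term: str) -> int:
        """1-based rank of a term in the p-sorted table."""
        for i, nd in enumerate(self.nodes, start=1):
            if nd.term == term:
                return i
        raise KeyError(term)

    def top_terms(self, k: int, significant_only: bool = False) -> list[str]:
        nodes = self.nodes
        if significant_only:
            nodes = [nd for nd in nodes if nd.p <= self.params.threshold]
        return [nd.term for nd in nodes[:k]]


def _floored_score(
    ledger: WeightLedger, term: str, interest_genes: set[str], N: int, n: int
) -> float:
    weights = ledger.term_weights(term)
    m_w = int(math.floor(sum(weights.values()) + _FLOOR_EPS))
    r_sum = sum(weights[g] for g in interest_genes)
    r_w = int(math.floor(r_sum + _FLOOR_EPS))
    return weighted_significance(N, n, m_w, min(r_w, m_w))


def run_enrichment(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    interest: list[str],
    params: EnrichmentParams | None = None,
) -> EnrichmentResult:
    """Run the full bottom-up weighted enrichment over a leveled DAG.

    Levels are processed from the deepest upward; within a level, nodes in
    lexicographic id order. For each node t with score p(t) <= threshold,
    already-scored children with p <= threshold are compared via the
    dynamic weight; locally dominant children trigger weight division at t
    and its ancestors, the node score is refined, and finally dominated
    children are down-weighted in place. BH adjustment is applied once over
    all recorded scores.
    """
    if params is None:
        params = EnrichmentParams()
    if annotations.expanded is None:
        raise ValueError("annotations must be true-path expanded")

    background = annotations.background
    interest_in_bg = sorted(set(interest) & background)
    n_outside = len(set(interest)) - len(interest_in_bg)
    if n_outside:
        logger.warning("%d interesting genes absent from the annotation background", n_outside)
    if not interest_in_bg:
        raise ValueError("no interesting genes in the annotation background")

    N = len(background)
    n = len(interest_in_bg)
    interest_set = set(interest_in_bg)

    genes_of = {t: set(annotations.genes(t)) for t in graph.nodes}
    hits_of = {t: genes_of[t] & interest_set for t in graph.nodes}
    ledger = initial_weights(annotations, params)
    ancestors_of = {t: sorted(graph.ancestors(t)) for t in graph.nodes}

    scores: dict[str, float] = {}
    warnings: list[str] = []

    def score(term: str) -> float:
        return _floored_score(ledger, term, hits_of[term], N, n)

    for level in range(graph.max_level, 0, -1):
        for t in graph.nodes_at_level(level):
            m = len(genes_of[t])
            if params.min_genes and m < params.min_genes:
                continue
            if params.max_genes and m > params.max_genes:
                continue
            p_t = score(t)
            scores[t] = p_t
            if not params.reweight:
                continue
            if p_t > params.threshold:
                continue
            # children that already hold scores; insignificant ones excluded
            children = [
                c for c in graph.children(t)
                if c in scores and scores[c] <= params.threshold
            ]
            iters = 0
            capped = False
            while children:
                iters += 1
                if iters > params.max_refine_iters:
                    warnings.append(f"refinement cap reached at node {t}")
                    logger.warning("refinement cap reached at node %s", t)
                    capped = True
                    break
                sig: list[tuple[str, float]] = []
                remaining: list[str] = []
                for c in children:
                    w_d = dynamic_weight(scores[c], p_t)
                    if w_d > 1.0:
                        sig.append((c, w_d))
                    else:
                        remaining.append(c)
                if not sig:
                    break
                for c, w_d in sig:
                    pen = penalty(_clamp_score(p_t), _clamp_score(scores[c]), params.penalty_scale)
                    divisor = w_d * pen
                    for a in (t, *ancestors_of[t]):
                        for g in genes_of[c]:
                            ledger.shrink(a, g, divisor)
                p_t = score(t)
                scores[t] = p_t
                children = remaining
            # remaining children are locally dominated by t
            for c in children:
                w_d = dynamic_weight(scores[c], p_t)
                if capped:
                    w_d = min(w_d, 1.0)
                pen = penalty(_clamp_score(p_t), _clamp_score(scores[c]), params.penalty_scale)
                factor = min(w_d, 1.0) / pen
                for g in genes_of[c]:
                    ledger.scale(c, g, factor)
                scores[c] = score(c)
                p_t = score(t)
                scores[t] = p_t

    recorded = sorted(scores)
    adjusted = bh_adjust([scores[t] for t in recorded])
    adj_map = dict(zip(recorded, adjusted))

    nodes = [
        NodeResult(
            term=t,
            name=graph.name(t),
            level=graph.level[t],
            p=scores[t],
            p_adjust=max(adj_map[t], scores[t]),
            gene_ratio=(len(hits_of[t]), n),
            bg_ratio=(len(genes_of[t]), N),
            genes=sorted(hits_of[t]),
        )
        for t in recorded
    ]
    nodes.sort(key=lambda nd: (nd.p, nd.term))
    return EnrichmentResult(
        nodes=nodes,
        params=params,
        background_size=N,
        interest_size=n,
        warnings=warnings,
    )


def classic_ora(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    interest: list[str],
    params: EnrichmentParams | None = None,
) -> EnrichmentResult:
    """Plain term-for-term hypergeometric ORA over the same inputs.

    Equivalent to :func:`run_enrichment` with unit weights and re-weighting
    disabled; per-node p equals :func:`hypergeom_upper_tail` on raw counts.
    """
    base = params if params is not None else EnrichmentParams()
    classic = replace(base, weight_step=0.0, min_init_weight=1.0, reweight=False)
    return run_enrichment(graph, annotations, interest, classic)
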