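"""Seeded synthetic ontologies, annotation tables, and interest sets.

Real disease ontologies are deep multi-parent DAGs (a dozen-plus levels)
with a heavy-tailed genes-per-term distribution: most terms carry a handful
of direct annotations while a few hubs carry thousands. The generators here
reproduce those structural features at arbitrary scale so the enrichment
algorithm and the benchmark protocols can be exercised without any
downloads. Everything is driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .annotation import AnnotationTable, propagate_true_path
from .ontology import OntologyGraph, Term, build_graph, write_obo


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generator.

    n_terms            total number of terms including the root.
    n_levels           target DAG depth (root = level 1); the backbone
                       construction achieves it exactly.
    n_genes            size of the gene universe.
    branching          geometric growth factor of level sizes; >1 puts the
                       bulk of terms in the middle/deep levels, as in real
                       disease DAGs.
    multi_parent_prob  probability that a non-root node draws a second,
                       strictly shallower parent (multiple inheritance).
    tail_exponent      exponent of the discrete power law for direct genes
                       per term; < 2 gives the observed 1-to-thousands
                       spread with a long right tail.
    max_genes_per_term truncation of that law (defaults to n_genes // 4).
    seed               master seed for all sampling.
    """

    n_terms: int = 150
    n_levels: int = 8
    n_genes: int = 500
    branching: float = 2.0
    multi_parent_prob: float = 0.3
    tail_exponent: float = 1.6
    max_genes_per_term: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.n_terms < self.n_levels:
            raise ValueError("n_terms must be >= n_levels")
        if self.tail_exponent <= 1.0:
            raise ValueError("tail_exponent must exceed 1")


def _term_id(i: int) -> str:
    return f"T:{i:06d}"


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _level_sizes(config: FixtureConfig) -> list[int]:
    """Distribute n_terms across n_levels: geometric growth, each level >= 1."""
    raw = [config.branching ** (l - 1) for l in range(1, config.n_levels)]
    remaining = config.n_terms - 1  # minus root
    total = sum(raw)
    sizes = [max(1, int(round(remaining * w / total))) for w in raw]
    # repair rounding drift against the deepest levels first
    drift = remaining - sum(sizes)
    idx = len(sizes) - 1
    while drift != 0:
        step = 1 if drift > 0 else -1
        if sizes[idx] + step >= 1:
            sizes[idx] += step
            drift -= step
        idx = (idx - 1) % len(sizes)
    return [1, *sizes]


def generate_ontology(config: FixtureConfig) -> tuple[list[Term], str]:
    """Generate a rooted multi-parent DAG with the target depth.

    Each non-root node takes a primary parent one level up (so the longest
    root path through it realizes the intended level exactly) and, with
    ``multi_parent_prob``, a second parent from any strictly shallower
    level. Serializing with :func:`dagenrich.ontology.write_obo` and
    re-parsing reproduces nodes and edges losslessly.
    """
    rng = np.random.default_rng([config.seed, 101])
    sizes = _level_sizes(config)
    root_id = _term_id(0)
    terms: list[Term] = [Term(id=root_id, name="synthetic root")]
    by_level: list[list[str]] = [[root_id]]
    next_idx = 1
    for level in range(2, config.n_levels + 1):
        ids = [_term_id(next_idx + j) for j in range(sizes[level - 1])]
        next_idx += len(ids)
        shallower = [tid for lvl in by_level for tid in lvl]
        prev = by_level[-1]
        for tid in ids:
            parents = [prev[rng.integers(len(prev))]]
            candidates = [x for x in shallower if x != parents[0]]
            if candidates and rng.random() < config.multi_parent_prob:
                parents.append(candidates[rng.integers(len(candidates))])
            terms.append(Term(id=tid, name=f"synthetic term {tid[2:]}", parents=parents))
        by_level.append(ids)
    return terms, root_id


def _power_law_counts(rng, n: int, exponent: float, kmax: int) -> np.ndarray:
    """Discrete power law on {1, ..., kmax} via inverse-CDF sampling."""
    u = rng.random(n)
    k = np.floor(u ** (-1.0 / (exponent - 1.0))).astype(int)
    return np.clip(k, 1, kmax)


def generate_annotations(graph: OntologyGraph, config: FixtureConfig) -> AnnotationTable:
    """Draw heavy-tailed direct gene counts per term and sample genes.

    Every term receives at least one direct gene, so pruning is a no-op
    unless a test removes annotations deliberately. Returns the direct
    table; callers expand via :func:`propagate_true_path`.
    """
    rng = np.random.default_rng([config.seed, 202])
    terms = sorted(graph.nodes)
    kmax = config.max_genes_per_term or max(1, config.n_genes // 4)
    kmax = min(kmax, config.n_genes)
    counts = _power_law_counts(rng, len(terms), config.tail_exponent, kmax)
    genes = np.array([_gene_id(i) for i in range(1, config.n_genes + 1)])
    direct: set[tuple[str, str]] = set()
    for term, count in zip(terms, counts):
        chosen = rng.choice(genes, size=int(count), replace=False)
        direct.update((str(g), term) for g in chosen)
    return AnnotationTable(direct=direct)


def implant_interest(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    signal_terms: dict[str, float],
    background_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Build an interest list around implanted signal terms.

    A direct gene of a signal term with strength s enters with probability
    s / (1 + s) (so strength -> infinity recovers the full direct gene set);
    every other gene enters at ``background_rate``. The ground truth is the
    ``signal_terms`` mapping itself.
    """
    missing = [t for t in signal_terms if t not in graph]
    if missing:
        raise ValueError(f"signal terms absent from graph: {missing}")
    rng = np.random.default_rng([seed, 303])
    direct_of: dict[str, set[str]] = {}
    for gene, term in annotations.direct:
        direct_of.setdefault(term, set()).add(gene)
    signal_genes: dict[str, float] = {}
    for term, strength in signal_terms.items():
        p = 1.0 if math.isinf(strength) else strength / (1.0 + strength)
        for gene in direct_of.get(term, ()):
            signal_genes[gene] = max(signal_genes.get(gene, 0.0), p)
    universe = sorted({g for g, _ in annotations.direct})
    interest: list[str] = []
    for gene in universe:
        p = signal_genes.get(gene, background_rate)
        if p >= 1.0 or rng.random() < p:
            interest.append(gene)
    return interest


# -- presets ---------------------------------------------------------------

PRESETS: dict[str, FixtureConfig] = {
    # quick unit-test scale
    "small": FixtureConfig(n_terms=30, n_levels=5, n_genes=100, branching=1.8, seed=0),
    # structural depth matching the deepest real disease DAGs
    "deep": FixtureConfig(n_terms=120, n_levels=13, n_genes=400, branching=1.5, seed=0),
    # exaggerated annotation skew
    "skewed": FixtureConfig(n_terms=300, n_levels=8, n_genes=800, tail_exponent=1.3, seed=0),
    # the standard recovery-study fixture; tail_exponent chosen so mean
    # genes-per-term (~50) and terms-per-gene (~13) match real disease-DAG
    # annotation density at this scale
    "benchmark": FixtureConfig(
        n_terms=500, n_levels=10, n_genes=2000, branching=2.0, tail_exponent=1.45, seed=0
    ),
    # reduced scale for the repeated perturbation study, same density
    "perturb": FixtureConfig(
        n_terms=150, n_levels=8, n_genes=600, branching=2.0, tail_exponent=1.45, seed=0
    ),
}


def make_fixture(preset: str, seed: int = 0):
    """Generate (graph, expanded annotations, config) for a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    config = replace(PRESETS[preset], seed=seed)
    terms, root = generate_ontology(config)
    graph = build_graph(terms, root)
    annotations = propagate_true_path(generate_annotations(graph, config), graph)
    return graph, annotations, config


def write_fixture(preset: str, seed: int, outdir) -> dict[str, str]:
    """Write fixture OBO + annotation TSV (+ an example interest list)."""
    from pathlib import Path

    from .annotation import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = replace(PRESETS[preset], seed=seed)
    terms, root = generate_ontology(config)
    graph = build_graph(terms, root)
    annotations = generate_annotations(graph, config)
    expanded = propagate_true_path(annotations, graph)
    deepest = max(graph.nodes, key=lambda t: (graph.level[t], t))
    interest = implant_interest(
        graph, annotations, {deepest: float("inf")}, background_rate=0.02, seed=seed
    )
    paths = {
        "obo": str(outdir / "ontology.obo"),
        "annotations": str(outdir / "annotations.tsv"),
        "interest": str(outdir / "interest.txt"),
    }
    write_obo(terms, paths["obo"])
    write_annotations(expanded, paths["annotations"])
    with open(paths["interest"], "w", encoding="utf-8") as handle:
        handle.write("\n".join(interest) + "\n")
    return paths
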