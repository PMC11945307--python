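"""Accuracy (known-term implantation) and robustness (perturbation) studies.

The accuracy protocol implants k "known" terms drawn from the middle 50% of
the direct-annotation-count ordering, builds an interest list from their
gene sets, reruns the enrichment, and counts how many known terms surface
among the top-ranked significant results. The robustness protocol removes
genes from, or adds background noise to, a fixed interest list and measures
the overlap of the perturbed top-100 with the unperturbed top-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .core import EnrichmentParams, EnrichmentResult, classic_ora, run_enrichment
from .ontology import OntologyGraph


@dataclass(frozen=True)
class SimulationDesign:
    """Configuration of one recovery study."""

    k_known: int = 20
    mode: str = "direct"  # "direct" or "expanded" interest-set construction
    max_terms_per_gene: int = 30
    top_k: tuple[int, ...] = (25, 50, 100)
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.k_known < 1:
            raise ValueError("k_known must be >= 1")
        if self.mode not in ("direct", "expanded"):
            raise ValueError("mode must be 'direct' or 'expanded'")
        if list(self.top_k) != sorted(self.top_k) or min(self.top_k) < 1:
            raise ValueError("top_k cutoffs must be positive ascending")


@dataclass
class BenchmarkReport:
    """Tidy per-rep table plus summary means."""

    records: pd.DataFrame
    summary: pd.DataFrame
    baseline_significant: int = 0


def select_known_terms(annotations: AnnotationTable, k: int, seed: int) -> list[str]:
    """Sample k terms uniformly from the middle 50% of the size ordering.

    Terms with at least one direct annotation are ordered by direct count
    (ascending, ties by id); eligibility is restricted to ranks strictly
    above the 25th percentile up to the 75th, avoiding terms whose gene
    sets are too small or too large to be informative.
    """
    counts = annotations.direct_gene_counts()
    ordered = sorted(counts, key=lambda t: (counts[t], t))
    total = len(ordered)
    lo = int(np.floor(total * 0.25))
    hi = int(np.floor(total * 0.75))
    eligible = ordered[lo:hi]
    if k > len(eligible):
        raise ValueError(
            f"too few eligible terms: need {k}, middle-50% pool has {len(eligible)}"
        )
    rng = np.random.default_rng([seed, 11])
    picked = rng.choice(len(eligible), size=k, replace=False)
    return sorted(eligible[i] for i in picked)


def build_interest_set(
    terms: list[str],
    annotations: AnnotationTable,
    mode: str = "direct",
    max_terms_per_gene: int = 30,
) -> list[str]:
    """Union of the terms' gene sets, with promiscuous genes removed.

    ``mode`` selects directly annotated genes or the true-path-expanded
    sets. A gene directly annotated to ``max_terms_per_gene`` or more terms
    carries no specificity and is dropped.
    """
    genes: set[str] = set()
    if mode == "direct":
        wanted = set(terms)
        for gene, term in annotations.direct:
            if term in wanted:
                genes.add(gene)
    elif mode == "expanded":
        for term in terms:
            genes.update(annotations.genes(term))
    else:
        raise ValueError("mode must be 'direct' or 'expanded'")
    term_counts = annotations.direct_term_counts()
    genes = {g for g in genes if term_counts.get(g, 0) < max_terms_per_gene}
    if not genes:
        raise ValueError("interest set is empty after filtering")
    return sorted(genes)


def evaluate_overlap(
    result: EnrichmentResult,
    known: list[str],
    cutoffs: tuple[int, ...] = (25, 50, 100),
    significant_only: bool = True,
) -> dict[int, int]:
    """|top-c recovered terms ∩ known| per cutoff c.

    Only terms with raw p at or below the run's threshold count as
    recovered (a rank deep in the insignificant tail is not a discovery).
    """
    known_set = set(known)
    return {
        c: len(set(result.top_terms(c, significant_only=significant_only)) & known_set)
        for c in cutoffs
    }


def run_recovery_study(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    design: SimulationDesign,
    params: EnrichmentParams | None = None,
    methods: tuple[str, ...] = ("weighted", "classic"),
) -> BenchmarkReport:
    """Repeat select-implant-rerun-count for each method; report means.

    Per-rep seeds derive deterministically from the design seed, so the
    whole report is reproducible bit-for-bit from (design, seed).
    """
    records = []
    for rep in range(design.n_reps):
        rep_seed = int(np.random.default_rng([design.seed, rep]).integers(2**31 - 1))
        known = select_known_terms(annotations, design.k_known, rep_seed)
        interest = build_interest_set(
            known, annotations, design.mode, design.max_terms_per_gene
        )
        for method in methods:
            if method == "weighted":
                result = run_enrichment(graph, annotations, interest, params)
            elif method == "classic":
                result = classic_ora(graph, annotations, interest, params)
            else:
                raise ValueError(f"unknown method {method!r}")
            overlaps = evaluate_overlap(result, known, tuple(design.top_k))
            for cutoff, overlap in overlaps.items():
                records.append(
                    {
                        "rep": rep,
                        "method": method,
                        "mode": design.mode,
                        "cutoff": cutoff,
                        "overlap": overlap,
                        "fraction": overlap / design.k_known,
                    }
                )
    frame = pd.DataFrame(records)
    summary = (
        frame.groupby(["method", "cutoff"], as_index=False)[["overlap", "fraction"]]
        .mean()
        .rename(columns={"overlap": "mean_overlap", "fraction": "mean_fraction"})
    )
    return BenchmarkReport(records=frame, summary=summary)


def perturb_gene_list(
    interest: list[str],
    background: list[str],
    remove_frac: float = 0.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Remove a fraction of genes, or add background noise genes.

    Exactly one of the fractions may be nonzero; both zero is the identity.
    Removal deletes round(frac * |interest|) genes uniformly; noise adds
    round(frac * |interest|) genes sampled uniformly from background
    outside the interest list.
    """
    if remove_frac and noise_frac:
        raise ValueError("specify only one of remove_frac / noise_frac")
    for frac in (remove_frac, noise_frac):
        if not 0.0 <= frac <= 0.3:
            raise ValueError("perturbation fractions must be in [0, 0.3]")
    interest = sorted(set(interest))
    if remove_frac == 0.0 and noise_frac == 0.0:
        return interest
    rng = np.random.default_rng([seed, 23])
    k = int(round((remove_frac or noise_frac) * len(interest)))
    if remove_frac:
        drop = set(rng.choice(len(interest), size=k, replace=False))
        return [g for i, g in enumerate(interest) if i not in drop]
    pool = sorted(set(background) - set(interest))
    if k > len(pool):
        raise ValueError(f"background too small: need {k} noise genes, have {len(pool)}")
    added = rng.choice(len(pool), size=k, replace=False)
    return sorted(interest + [pool[i] for i in added])


def run_perturbation_study(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    interest: list[str],
    levels: list[float],
    kind: str = "noise",
    n_reps: int = 100,
    seed: int = 0,
    params: EnrichmentParams | None = None,
    top: int = 100,
) -> BenchmarkReport:
    """Perturb-rerun-overlap for each level, against the unperturbed run.

    Records, per (level, rep), the size of the intersection of the
    perturbed run's top-``top`` significant terms with the unperturbed
    top-``top``, and the ratio of that overlap to the unperturbed count.
    """
    if kind not in ("remove", "noise"):
        raise ValueError("kind must be 'remove' or 'noise'")
    baseline = run_enrichment(graph, annotations, interest, params)
    base_top = set(baseline.top_terms(top, significant_only=True))
    background = sorted(annotations.background)
    records = []
    for level_idx, level in enumerate(levels):
        for rep in range(n_reps):
            rep_seed = int(
                np.random.default_rng([seed, level_idx, rep]).integers(2**31 - 1)
            )
            kwargs = {"remove_frac": level} if kind == "remove" else {"noise_frac": level}
            perturbed = perturb_gene_list(interest, background, seed=rep_seed, **kwargs)
            result = run_enrichment(graph, annotations, perturbed, params)
            overlap = len(set(result.top_terms(top, significant_only=True)) & base_top)
            records.append(
                {
                    "level": level,
                    "rep": rep,
                    "overlap": overlap,
                    "ratio": overlap / len(base_top) if base_top else 0.0,
                }
            )
    frame = pd.DataFrame(records)
    summary = (
        frame.groupby("level", as_index=False)[["overlap", "ratio"]]
        .mean()
        .rename(columns={"overlap": "mean_overlap", "ratio": "mean_ratio"})
    )
    return BenchmarkReport(records=frame, summary=summary, baseline_significant=len(base_top))
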