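"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid scipy/statsmodels and the package's own code paths:
exact rational arithmetic, literal subset enumeration, and definitional
re-implementations at tiny scale.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def exact_hypergeom_tail(N: int, m: int, n: int, r: int) -> Fraction:
    """P(X >= r) for X ~ Hypergeometric(N, m, n) as an exact rational."""
    denom = comb(N, n)
    head = sum(comb(m, k) * comb(N - m, n - k) for k in range(r))
    return Fraction(denom - head, denom)


def enumerate_hypergeom_tail(N: int, m: int, n: int, r: int) -> Fraction:
    """Same tail probability by literally enumerating all C(N, n) draws."""
    marked = set(range(m))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= r:
            hits += 1
    return Fraction(hits, total)


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up from the definition."""
    M = len(pvalues)
    order = sorted(range(M), key=lambda i: pvalues[i])
    adjusted = [0.0] * M
    running_min = 1.0
    for rank in range(M, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * M / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def brute_longest_path_levels(edges: set[tuple[str, str]], root: str) -> dict[str, int]:
    """Levels via exhaustive DFS over all root->node paths (edges child->parent)."""
    children: dict[str, list[str]] = {}
    nodes = {root}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
        nodes.update((child, parent))
    best: dict[str, int] = {}

    def walk(node: str, depth: int) -> None:
        if depth > best.get(node, 0):
            best[node] = depth
        for child in children.get(node, ()):  # revisit on purpose: all paths
            walk(child, depth + 1)

    walk(root, 1)
    return best
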