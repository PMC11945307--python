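"""Hypergeometric upper-tail test, weighted variant, and BH adjustment.

The over-representation p-value for a term with m annotated genes, of which
r fall in an interest list of size n drawn from a background of N genes, is
the upper tail P(X >= r) of Hypergeometric(N, m, n). The weighted variant
replaces m and r by floors of weight sums, so down-weighted genes count
fractionally.
"""

from __future__ import annotations

import sys

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: smallest positive normalized double; lower clamp so log(p) stays finite
XMIN = sys.float_info.min


def hypergeom_upper_tail(N: int, m: int, n: int, r: int) -> float:
    """P(X >= r) for X ~ Hypergeometric(N, m, n); r = 0 gives 1.0."""
    if N < 0:
        raise ValueError(f"N must be non-negative, got {N}")
    if not 0 <= m <= N:
        raise ValueError(f"require 0 <= m <= N, got m={m}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if r < 0:
        raise ValueError(f"r must be non-negative, got {r}")
    if r > m:
        raise ValueError(f"require r <= m, got r={r}, m={m}")
    if r > n:
        raise ValueError(f"require r <= n, got r={r}, n={n}")
    if r == 0:
        return 1.0
    p = float(hypergeom.sf(r - 1, N, m, n))
    return min(max(p, 0.0), 1.0)


def weighted_significance(N: int, n: int, m_w: int, r_w: int) -> float:
    """Upper-tail test on floored weight sums; clamped to [XMIN, 1].

    ``m_w`` and ``r_w`` are the floors of the weight sums over the term's
    annotated genes and over its interesting genes; N and n stay unweighted.
    """
    if r_w > m_w:
        raise ValueError(f"require r_w <= m_w, got r_w={r_w}, m_w={m_w}")
    if r_w == 0:
        return 1.0
    p = hypergeom_upper_tail(N, m_w, n, min(r_w, n))
    return max(p, XMIN)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if not pvalues:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])
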