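"""Gene-set enrichment: exact hypergeometric upper-tail tests and one-sided
Fisher tests.

The hypergeometric test asks whether a query gene set (for example a cluster of
differentially expressed genes) overlaps a target set (for example the targets
of one transcription factor) more than expected when drawing ``n`` genes at
random from a universe of ``N`` genes of which ``K`` belong to the target set.
The reported p-value is the exact upper tail P(X >= k), accumulated in log
space from ``k`` upward so that deep tails do not suffer catastrophic
cancellation.  Multiple target sets are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "hypergeom_enrichment",
    "fisher_one_sided",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one target set against a query within a universe.

    ``k`` genes overlap between the query (size ``n``) and the target set
    (size ``K``) inside a universe of ``N`` genes.
    """

    set_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float | None = None


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space from ``k`` up to ``min(K, n)``; never computed as
    ``1 - CDF``.
    """
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if k <= 0:
        return 1.0  # the upper tail covers the whole support
    hi = min(K, n)
    if k > hi:
        # Impossible overlap requested: the upper tail is empty.
        return 0.0
    support = np.arange(k, hi + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def hypergeom_enrichment(
    query: set[str] | list[str],
    target_sets: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> list[EnrichmentResult]:
    """Test each target set for over-representation in ``query``.

    Query and target genes outside the universe are reported and clipped.
    BH-adjusted q-values are computed across all target sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query genes outside the universe were clipped"
        )
        query &= universe
    n = len(query)
    N = len(universe)
    results: list[EnrichmentResult] = []
    for set_id, members in target_sets.items():
        members = set(members)
        stray = members - universe
        if stray:
            warnings.warn(
                f"set {set_id!r}: {len(stray)} genes outside the universe "
                "were clipped"
            )
            members &= universe
        K = len(members)
        k = len(members & query)
        p = hypergeom_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(set_id, k, K, n, N, p))
    if results:
        qvals = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.set_id, r.k, r.K, r.n, r.N, r.p, float(q))
            for r, q in zip(results, qvals)
        ]
    return results


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Identical to the hypergeometric upper tail with k=a, K=a+b, n=a+c,
    N=a+b+c+d.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    N = a + b + c + d
    if N == 0:
        raise ValueError("all-zero table")
    return hypergeom_upper_tail(a, a + b, a + c, N)


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results (one row per target set), sorted by p."""
    df = pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "overlap": r.k,
                "set_size": r.K,
                "query_size": r.n,
                "universe_size": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )
    return df.sort_values("p", kind="stable").reset_index(drop=True)
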