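"""Hypergeometric / EASE term enrichment with Bonferroni correction.

For a query of n proteins from a universe of N, a term annotating K of them
and overlapping the query in k, the one-tailed p-value is the
hypergeometric upper tail P(X >= k).  The ``ease`` variant is the
conservative DAVID-style score: the same tail with one query member removed
from the overlap (k replaced by k-1, floored at 0).  Tails are computed with
exact integer binomial coefficients — no normal approximation — because the
interesting overlaps are small.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return numer / comb(N, n)


def term_test(
    query: set[str], term_members: set[str], universe: set[str], variant: str = "fisher"
) -> float:
    """One-tailed over-representation p-value for one term.

    ``variant='fisher'`` is the plain hypergeometric upper tail; ``'ease'``
    removes one overlapping member first (more conservative, never smaller).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if not term_members <= universe:
        raise ValueError("term members must be a subset of the universe")
    N, K, n = len(universe), len(term_members), len(query)
    k = len(query & term_members)
    if variant == "fisher":
        pass
    elif variant == "ease":
        k = max(0, k - 1)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'fisher' or 'ease'")
    return hypergeom_upper_tail(N, K, n, k)


@dataclass
class EnrichedTerm:
    """One term's enrichment summary (count, ratio, raw and corrected p)."""

    term_id: str
    name: str
    count: int
    universe_count: int
    enrichment_ratio: float
    p_raw: float
    p_corrected: float

    @property
    def neglog10_p_corrected(self) -> float:
        import math

        return -math.log10(self.p_corrected) if self.p_corrected > 0 else math.inf


def enrich(
    query: set[str],
    annotation,
    alpha: float = 0.05,
    min_count: int = 2,
    variant: str = "ease",
    correction: str = "bonferroni",
    bonferroni_scope: str = "overlapping",
) -> list[EnrichedTerm]:
    """Test every term and report the significantly enriched ones.

    Bonferroni multiplies by the number of terms with at least one query
    member (``bonferroni_scope='overlapping'``, the chart-report behaviour)
    or by all annotated terms (``'all'``).  Reported terms need corrected
    p < ``alpha`` and at least ``min_count`` query members; sorted by
    corrected p ascending.
    """
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    universe = annotation.universe
    query = set(query) & universe
    tested = []
    for term_id, members in annotation.terms.items():
        k = len(query & members)
        if bonferroni_scope == "overlapping" and k == 0:
            continue
        tested.append((term_id, members, k))
    m = len(tested) if tested else 1
    n_query = len(query)
    out = []
    for term_id, members, k in tested:
        p_raw = term_test(query, members, universe, variant=variant)
        p_corr = min(1.0, p_raw * m)
        if k < min_count or p_corr >= alpha:
            continue
        ratio = (
            (k / n_query) / (len(members) / len(universe))
            if n_query and members
            else 0.0
        )
        out.append(
            EnrichedTerm(
                term_id=term_id,
                name=annotation.name(term_id),
                count=k,
                universe_count=len(members),
                enrichment_ratio=ratio,
                p_raw=p_raw,
                p_corrected=p_corr,
            )
        )
    out.sort(key=lambda t: (t.p_corrected, t.p_raw, t.term_id))
    return out
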