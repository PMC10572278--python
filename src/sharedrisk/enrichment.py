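"""Hypergeometric over-representation of gene sets and locus windows.

Drawing n items from a population of N containing K marked items, the
chance of observing at least k marked draws is the upper tail

    P(X >= k) = sum_{j=k}^{min(n,K)} C(K,j) C(N-K, n-j) / C(N, n),

computed here entirely in log space via log-gamma so that enrichments down
to p ~ 1e-300 and far below retain a finite log10 p.  Alongside the tail the
result reports the expected overlap n*K/N and the fold enrichment
k / expected, the quantities conventionally printed by over-representation
calculators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln, logsumexp

from .summary_io import GeneList


@dataclass(frozen=True)
class EnrichmentResult:
    """k observed of n drawn against K marked in a background of N."""

    k: int
    n: int
    K: int
    N: int
    expected: float
    fold: float
    p_upper: float
    log10_p: float

    def format_row(self) -> str:
        """expected to 2 decimals, p to 2 significant figures (the display
        convention of published over-representation tables)."""
        return f"{self.expected:.2f}\t{self.fold:.0f}\t{format_sig(self.p_upper, self.log10_p)}"


def format_sig(p: float, log10_p: float | None = None, digits: int = 2) -> str:
    if log10_p is not None and log10_p < -300.0:
        return "<1e-300"
    return f"{p:.{digits - 1}e}"


def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_hypergeom_sf(k: int, n: int, K: int, N: int) -> float:
    """Natural-log upper tail ln P(X >= k) for Hypergeometric(N, K, n)."""
    hi = min(n, K)
    if k <= 0:
        return 0.0
    if k > hi:
        return -math.inf
    lo_j = max(k, n + K - N)
    terms = [
        _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
        for j in range(lo_j, hi + 1)
    ]
    return float(logsumexp(terms))


def expected_overlap(n: int, K: int, N: int) -> float:
    """Mean overlap n*K/N when n draws are made at random."""
    if N <= 0:
        raise ValueError(f"background size must be positive, got {N}")
    if n > N or K > N:
        raise ValueError(f"set sizes (n={n}, K={K}) exceed background N={N}")
    return n * K / N


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment of k observed overlaps."""
    if min(k, n, K, N) < 0:
        raise ValueError("all arguments must be non-negative")
    if n > N or K > N:
        raise ValueError(f"set sizes (n={n}, K={K}) exceed background N={N}")
    if k > min(n, K):
        raise ValueError(f"observed overlap k={k} exceeds min(n, K)={min(n, K)}")
    expected = expected_overlap(n, K, N)
    fold = k / expected if expected > 0 else math.nan
    log_p = log_hypergeom_sf(k, n, K, N)
    return EnrichmentResult(
        k=k, n=n, K=K, N=N, expected=expected, fold=fold,
        p_upper=math.exp(log_p) if log_p > -745 else 0.0,
        log10_p=log_p / math.log(10.0),
    )


def enrich_gene_lists(query: GeneList, subject: GeneList,
                      background_size: int = 19_303,
                      ) -> tuple[EnrichmentResult, list[str]]:
    """Overlap enrichment of two gene lists against a gene universe.

    Symbols are case-normalized by :class:`GeneList`; the default background
    of 19,303 is the size of a whole-proteome interaction-network universe.
    Returns the enrichment plus the shared symbols in query order.
    """
    qset = set(query.symbols)
    sset = set(subject.symbols)
    union = len(qset | sset)
    if background_size < union:
        raise ValueError(
            f"background ({background_size}) smaller than the union of the "
            f"two lists ({union})"
        )
    shared = [s for s in query.symbols if s in sset]
    result = hypergeom_enrichment(len(shared), len(qset), len(sset), background_size)
    return result, shared
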