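"""Over-representation analysis of a gene list against GMT gene sets.

The test is the standard one-sided hypergeometric upper tail (equivalently a
one-sided Fisher exact test) with Benjamini-Hochberg step-up FDR control, the
same adjusted p-value a typical web enrichment service reports.  Proprietary
combined scores are deliberately not reproduced; ranking is by (FDR, p, term).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # background size
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a uniformly drawn size-``n`` query from a background
    of ``N`` genes overlaps a size-``K`` set in at least ``k`` genes.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    # survival function is P(X > k-1) = P(X >= k); scipy computes it in log
    # space internally, stable for extreme tails
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass
class EnrichmentReport:
    rows: list[EnrichmentRow]  # all sets, ranked
    significant: list[EnrichmentRow]  # top_k rows passing the FDR cut
    n_query_used: int
    n_query_dropped: int  # query genes outside the background


def enrich(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    background: Iterable[str] | None = None,
    top_k: int = 10,
    fdr_cut: float = 0.05,
) -> EnrichmentReport:
    """Hypergeometric ORA of ``query_genes`` against every set in the collection.

    ``background`` defaults to the collection's own background; query genes
    outside it are dropped (counted, never silently).  Set members outside the
    background are likewise ignored for counting.  Rows are ranked by
    (fdr, p, term); ``significant`` holds the first ``top_k`` with
    fdr < ``fdr_cut``.
    """
    bg = frozenset(background) if background is not None else gene_sets.background
    if not bg:
        raise ValueError("enrichment requires a non-empty background")
    query_all = set(query_genes)
    query = query_all & bg
    n, N = len(query), len(bg)
    terms = sorted(gene_sets.sets)
    raw: list[tuple[str, int, int, frozenset[str]]] = []
    pvals = []
    for term in terms:
        members = gene_sets.sets[term] & bg
        overlap = frozenset(query & members)
        raw.append((term, len(overlap), len(members), overlap))
        pvals.append(hypergeom_upper_tail(len(overlap), len(members), n, N))
    fdrs = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term=term, k=k, K=K, n=n, N=N, p_value=p, fdr=f, overlap_genes=overlap
        )
        for (term, k, K, overlap), p, f in zip(raw, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.fdr, r.p_value, r.term))
    significant = [r for r in rows if r.fdr < fdr_cut][:top_k]
    return EnrichmentReport(
        rows=rows,
        significant=significant,
        n_query_used=n,
        n_query_dropped=len(query_all) - n,
    )
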