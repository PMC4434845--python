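"""Size-filtered gene-set enrichment with Fisher's exact test and BH-FDR.

Each pathway is tested for over-representation of a disease's risk genes
against a declared genome background (one-sided hypergeometric tail).
Pathways and the query are both restricted to the background universe so the
2×2 table margins stay consistent. A pathway counts as significant only under
the dual rule p < 1e-3 AND BH-FDR q < 0.01, and the FDR is computed within a
single disease's scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetDB, normalize_symbol

__all__ = [
    "EnrichmentResult",
    "P_RULE",
    "Q_RULE",
    "filter_gene_sets",
    "fisher_enrichment",
    "bh_fdr",
    "enrich_all",
    "pathway_overlap",
]

#: Dual significance rule thresholds.
P_RULE = 1.0e-3
Q_RULE = 0.01


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    source: str
    set_size: int
    overlap: int
    p_value: float
    q_value: float
    significant: bool


def filter_gene_sets(
    db: GeneSetDB,
    background: Iterable[str] | None = None,
    min_size: int = 15,
    max_size: int = 1000,
) -> GeneSetDB:
    """Keep sets whose size (after background restriction) is in [min, max]."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    bg = {normalize_symbol(g) for g in background} if background is not None else None
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    for name, (source, genes) in db.sets.items():
        size = len(genes & bg) if bg is not None else len(genes)
        if min_size <= size <= max_size:
            kept[name] = (source, genes)
    return GeneSetDB(kept) if kept else GeneSetDB({})


def fisher_enrichment(
    query: Iterable[str], pathway: Iterable[str], background_n: int
) -> float:
    """One-sided enrichment p: hypergeometric P(X ≥ k) for the 2×2 table.

    ``query`` and ``pathway`` must already be restricted to the background
    universe of ``background_n`` genes.
    """
    q = set(query)
    s = set(pathway)
    k = len(q & s)
    n_q, n_s = len(q), len(s)
    if n_q > background_n or n_s > background_n or n_q + n_s - k > background_n:
        raise ValueError("query/pathway sizes inconsistent with background size")
    # P(X >= k), X ~ Hypergeom(N=background_n, K=n_s, n=n_q)
    return float(hypergeom.sf(k - 1, background_n, n_s, n_q))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich_all(
    query: Iterable[str],
    db: GeneSetDB,
    background: Iterable[str] | int = 23510,
    p_rule: float = P_RULE,
    q_rule: float = Q_RULE,
) -> list[EnrichmentResult]:
    """Test every pathway in an (already size-filtered) database.

    ``background`` is either the background universe as a gene collection
    (query and pathways are intersected with it) or a bare gene count when
    the inputs are known to be pre-restricted. FDR is computed over all
    pathways of this scan.
    """
    query_set = {normalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("empty query gene set")
    if isinstance(background, int):
        background_n = background
        universe = None
    else:
        universe = {normalize_symbol(g) for g in background}
        background_n = len(universe)
        query_set &= universe
        if not query_set:
            raise ValueError("query has no genes in the background universe")
    names = db.names()
    rows: list[tuple[str, str, int, int, float]] = []
    for name in names:
        source, genes = db.sets[name]
        genes_r = genes & universe if universe is not None else genes
        p = fisher_enrichment(query_set, genes_r, background_n)
        rows.append((name, source, len(genes_r), len(query_set & genes_r), p))
    qvals = bh_fdr([r[4] for r in rows])
    return [
        EnrichmentResult(
            pathway=name,
            source=source,
            set_size=size,
            overlap=k,
            p_value=p,
            q_value=qv,
            significant=bool(p < p_rule and qv < q_rule),
        )
        for (name, source, size, k, p), qv in zip(rows, qvals)
    ]


def pathway_overlap(
    results_a: Sequence[EnrichmentResult], results_b: Sequence[EnrichmentResult]
) -> int:
    """Number of pathway names significant in both result lists."""
    sig_a = {r.pathway for r in results_a if r.significant}
    sig_b = {r.pathway for r in results_b if r.significant}
    return len(sig_a & sig_b)
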