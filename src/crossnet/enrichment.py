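"""Overrepresentation analysis against the predictor-pool background.

For a query gene list (e.g. a Venn region of shared neighbors) and a
term collection (GMT), each term is tested with the one-sided
hypergeometric upper tail P(X ≥ k) where, out of M background genes of
which K carry the term, the query of size n overlaps k. The background
is the predictor pool Π of the run — never the whole genome — so that
the test asks whether a term is enriched among the *called* neighbors
relative to the genes that were eligible to be called. FDR across terms
is Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .preprocessing import GeneSetCollection

__all__ = ["EnrichmentRow", "overrepresentation", "enrichment_frame"]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    overlap_count: int  # k
    term_size: int  # K (after intersection with background)
    query_size: int  # n
    background_size: int  # M
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


def overrepresentation(
    query: set[str], background: set[str], terms: GeneSetCollection
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of each term in the query.

    The query must be a subset of the background; term sets are
    intersected with the background before testing, and terms with zero
    overlap are reported (they contribute to the FDR denominator).
    Rows are sorted by p-value, ties broken by term id.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError(
            f"query is not a subset of the background "
            f"({len(query - background)} genes outside)"
        )
    M, n = len(background), len(query)
    records = []
    for term_id, (desc, genes) in terms.items():
        in_bg = genes & background
        K = len(in_bg)
        overlap = in_bg & query
        k = len(overlap)
        # Upper tail P(X >= k); sf(k-1) is exact for the discrete distribution
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        records.append((term_id, desc, k, K, overlap, p))
    if not records:
        return []
    # BH step-up in a fixed order so FDRs are invariant to input row order
    records.sort(key=lambda r: (r[5], r[0]))
    _, fdrs, _, _ = multipletests([r[5] for r in records], method="fdr_bh")
    return [
        EnrichmentRow(term_id, desc, k, K, n, M, p, float(f), frozenset(overlap))
        for (term_id, desc, k, K, overlap, p), f in zip(records, fdrs)
    ]


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view (one row per term) for TSV export."""
    return pd.DataFrame(
        {
            "term": [r.term_id for r in rows],
            "description": [r.description for r in rows],
            "k": [r.overlap_count for r in rows],
            "K": [r.term_size for r in rows],
            "n": [r.query_size for r in rows],
            "M": [r.background_size for r in rows],
            "p_value": [r.p_value for r in rows],
            "fdr": [r.fdr for r in rows],
            "genes": [",".join(sorted(r.overlap_genes)) for r in rows],
        }
    )
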