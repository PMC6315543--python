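"""Gene-set over-representation analysis against GMT libraries.

For a query gene list and each set in a library, the overlap k is tested
with a one-sided hypergeometric test (probability of >= k successes when
drawing n = |query| from a background of N genes of which K = |set| are
marked), the per-library family of p-values is Benjamini-Hochberg
adjusted, and results are reported Enrichr-style (term, "k/K" overlap, raw
and adjusted p). A coverage summary reports how many query genes fall in
the union of the significant sets — the construction used to count genes
targeted by significant miRNA target sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetLibrary
from .pca import adjust_bh

__all__ = [
    "EnrichmentRecord",
    "enrich_genes",
    "summarize_mirna_coverage",
    "records_to_frame",
    "DEFAULT_BACKGROUND_N",
]

# approximate protein-coding genome; the effective background of web
# enrichment services is library-dependent, so this is configurable
DEFAULT_BACKGROUND_N = 20000


@dataclass
class EnrichmentRecord:
    """One term's over-representation result."""

    term: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    background_N: int
    raw_p: float
    adjusted_p: float
    overlapping_symbols: frozenset[str]

    @property
    def overlap(self) -> str:
        """Enrichr-style "k/K" string."""
        return f"{self.overlap_k}/{self.set_size_K}"


def enrich_genes(
    query: "set[str] | list[str]",
    library: GeneSetLibrary,
    background_N: int = DEFAULT_BACKGROUND_N,
    background: "set[str] | None" = None,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation of ``query`` per term.

    Parameters
    ----------
    query
        Gene symbols to test (case-insensitive; uppercased internally).
    library
        GMT-style gene-set library.
    background_N
        Size of the gene universe. Ignored when ``background`` is given.
    background
        Optional explicit universe of symbols. Query symbols and set
        members outside it are dropped (with a warning for the query).

    Returns records sorted by raw p ascending, ties broken by term name.
    An empty library yields an empty list. k = 0 is reported with p = 1
    (the probability of observing >= 0 overlaps).
    """
    query_set = {str(s).upper() for s in query}
    if not query_set:
        raise ValueError("query must be non-empty")
    if background is not None:
        background = {str(s).upper() for s in background}
        dropped = query_set - background
        if dropped:
            warnings.warn(
                f"{len(dropped)} query symbol(s) absent from background dropped",
                stacklevel=2,
            )
        query_set &= background
        if not query_set:
            raise ValueError("no query symbols remain inside the background")
        N = len(background)
    else:
        N = int(background_N)
    n = len(query_set)
    if N < n:
        raise ValueError(f"background N={N} smaller than query size {n}")

    terms: list[str] = []
    raws: list[float] = []
    rows: list[tuple[int, int, frozenset[str]]] = []
    for term, members in library.items():
        members_eff = members & background if background is not None else members
        K = len(members_eff)
        if N < K:
            raise ValueError(
                f"background N={N} smaller than set {term!r} of size {K}"
            )
        hits = frozenset(query_set & members_eff)
        k = len(hits)
        if N < K + n - k:
            raise ValueError(
                f"background N={N} inconsistent with overlap for {term!r} "
                f"(needs >= {K + n - k})"
            )
        raw = float(hypergeom.sf(k - 1, N, K, n))
        terms.append(term)
        raws.append(min(raw, 1.0))
        rows.append((k, K, hits))
    if not terms:
        return []
    adjusted = adjust_bh(raws)
    records = [
        EnrichmentRecord(
            term=t,
            overlap_k=k,
            set_size_K=K,
            query_size_n=n,
            background_N=N,
            raw_p=raw,
            adjusted_p=float(adj),
            overlapping_symbols=hits,
        )
        for t, raw, adj, (k, K, hits) in zip(terms, raws, adjusted, rows)
    ]
    records.sort(key=lambda r: (r.raw_p, r.term))
    return records


def summarize_mirna_coverage(
    query: "set[str] | list[str]",
    records: list[EnrichmentRecord],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentRecord], set[str], int]:
    """Coverage of the query by the significant sets.

    Returns (significant records, query symbols covered by the union of
    their overlaps, coverage count). With miRNA target-set libraries this
    answers "how many query genes are targeted by at least one significant
    miRNA".
    """
    query_set = {str(s).upper() for s in query}
    significant = [r for r in records if r.adjusted_p <= alpha]
    covered: set[str] = set()
    for r in significant:
        covered |= r.overlapping_symbols
    covered &= query_set
    return significant, covered, len(covered)


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular view matching the usual enrichment-report layout."""
    return pd.DataFrame(
        {
            "term": [r.term for r in records],
            "overlap": [r.overlap for r in records],
            "p_value": [r.raw_p for r in records],
            "adjusted_p_value": [r.adjusted_p for r in records],
            "overlapping_symbols": [
                ";".join(sorted(r.overlapping_symbols)) for r in records
            ],
        }
    )
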