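"""Term (e.g. Gene Ontology) enrichment with a permutation-based
family-wise adjusted p-value.

For a query gene set within an annotation universe, each term yields a 2x2
table (query membership x term membership) tested with the one-sided
(greater) Fisher exact test.  The effect size is the log10 odds ratio
(LOD), Haldane-corrected when a cell is zero.  The adjusted p-value uses a
Westfall-Young-style min-p resampling scheme: random query sets of the
same size are drawn, and a term's adjusted p is the (add-one smoothed)
fraction of resamples whose smallest per-term p is at most the term's
observed p.  Annotations are taken as flat gene -> term sets; no ontology
propagation is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .expression import fisher_exact

__all__ = ["TermAnnotation", "TermEnrichmentRow", "enrich_terms", "permutation_adjust"]


@dataclass(frozen=True)
class TermAnnotation:
    """Flat gene -> term annotations over a gene universe."""

    gene_terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.gene_terms) - set(self.universe)
        if stray:
            raise ValueError(f"annotated genes outside universe: {sorted(stray)[:5]}")

    def term_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for term in terms:
                members.setdefault(term, set()).add(gene)
        return members


@dataclass(frozen=True)
class TermEnrichmentRow:
    """One term's enrichment statistics.

    ``n_query`` (N) and ``n_universe`` (X) are the counts of query and
    universe genes carrying the term; ``lod`` is the log10 odds ratio.
    ``p_adj`` is None until :func:`permutation_adjust` fills it in.
    """

    term: str
    n_query: int
    n_universe: int
    lod: float
    p: float
    p_adj: Optional[float] = None


def enrich_terms(
    query: Iterable[str], ann: TermAnnotation, sided: str = "greater"
) -> list[TermEnrichmentRow]:
    """Per-term Fisher enrichment of ``query`` within the annotation universe.

    Terms annotating no gene or every gene in the universe are skipped
    (their tables are degenerate).  Rows are sorted by LOD descending,
    with p ascending and then term id as tie-breaks.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    stray = query - set(ann.universe)
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    u = len(ann.universe)
    q = len(query)
    rows = []
    for term, members in ann.term_members().items():
        x = len(members)
        if x == 0 or x == u:
            continue
        n = len(members & query)
        table = ((n, q - n), (x - n, u - q - (x - n)))
        res = fisher_exact(table, sided=sided)
        rows.append(
            TermEnrichmentRow(
                term=term,
                n_query=n,
                n_universe=x,
                lod=math.log10(res.odds_ratio),
                p=res.p(sided),
            )
        )
    rows.sort(key=lambda r: (-r.lod, r.p, r.term))
    return rows


def permutation_adjust(
    rows: Sequence[TermEnrichmentRow],
    query_size: int,
    ann: TermAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[TermEnrichmentRow]:
    """Westfall-Young-style min-p adjusted p-values.

    Draws ``n_perm`` uniform random query sets of size ``query_size`` from
    the universe; for each resample the minimum per-term one-sided p is
    recorded, and a term's adjusted p is ``(1 + #{min_p <= p_obs}) /
    (1 + n_perm)``, clipped from below at the raw p so the family-wise
    estimate never undercuts the per-term one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if not rows:
        return []
    genes = sorted(ann.universe)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    members = ann.term_members()
    terms = [r.term for r in rows]
    indicator = np.zeros((n_genes, len(terms)), dtype=bool)
    for j, term in enumerate(terms):
        for g in members[term]:
            indicator[gene_pos[g], j] = True
    x_counts = indicator.sum(axis=0)

    # Per-term lookup of the one-sided greater p for every possible overlap
    # count a = 0..min(X, q); used for both observed and resampled queries
    # so tie comparisons are internally consistent.
    lookups = []
    for x in x_counts:
        amax = int(min(x, query_size))
        avals = np.arange(amax + 1)
        lookups.append(stats.hypergeom.sf(avals - 1, n_genes, int(x), query_size))
    obs_p = np.array(
        [lookups[j][min(rows[j].n_query, len(lookups[j]) - 1)] for j in range(len(terms))]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=query_size, replace=False)
        counts = indicator[idx].sum(axis=0)
        min_p = min(
            lookups[j][int(counts[j])] for j in range(len(terms))
        )
        exceed += min_p <= obs_p
    p_adj = (1 + exceed) / (1 + n_perm)
    return [
        replace(r, p_adj=float(max(r.p, p_adj[j]))) for j, r in enumerate(rows)
    ]
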