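"""Transcript-selection procedures yielding non-redundant transcript sets.

Three strategies are supported:

``keep_all``
    Every transcript is retained.
``locus_overlap``
    Transcripts are partitioned into locus equivalence classes — connected
    components of the relation "transcription intervals on the same
    chromosome and strand overlap by more than ``min_overlap`` (default 20)
    base pairs" — and one uniformly random representative is kept per class.
``unique_5utr``
    Transcripts sharing an identical 5'UTR exon structure collapse to one
    random representative; transcripts that differ anywhere in their 5'UTR
    are all retained.

All random choices are driven by a seed over lexicographically sorted
transcript ids, so selection is reproducible and invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genemodels import GeneModel, GenomicInterval, five_prime_utr_span

__all__ = [
    "LocusPartition",
    "drop_multi_locus_ids",
    "locus_equivalence_classes",
    "select_representatives",
    "STRATEGIES",
]

STRATEGIES = ("keep_all", "locus_overlap", "unique_5utr")


@dataclass(frozen=True)
class LocusPartition:
    """A partition of transcript ids into locus equivalence classes."""

    classes: tuple[frozenset[str], ...]
    rule: str = "overlap20"


def drop_multi_locus_ids(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Remove ids that map to more than one genomic locus.

    Byte-identical duplicate rows collapse to a single model first.  An id
    whose remaining models do not all belong to one overlap-connected locus
    (same chromosome, transcription intervals sharing at least one base,
    transitively) is removed entirely.
    """
    seen: set[GeneModel] = set()
    unique: list[GeneModel] = []
    for m in models:
        if m not in seen:
            seen.add(m)
            unique.append(m)
    by_id: dict[str, list[GeneModel]] = {}
    for m in unique:
        by_id.setdefault(m.transcript_id, []).append(m)

    bad_ids = set()
    for tid, group in by_id.items():
        if len(group) == 1:
            continue
        chroms = {m.chrom for m in group}
        if len(chroms) > 1:
            bad_ids.add(tid)
            continue
        # Connected components under ">0 bp overlap" on one chromosome:
        # a sorted sweep suffices, since the member with the largest end
        # seen so far maximizes overlap with the next interval.
        ivals = sorted((m.tx_start, m.tx_end) for m in group)
        max_end = ivals[0][1]
        for s, e in ivals[1:]:
            if s >= max_end:  # no shared base -> second locus
                bad_ids.add(tid)
                break
            max_end = max(max_end, e)
    return [m for m in unique if m.transcript_id not in bad_ids]


def locus_equivalence_classes(
    models: Sequence[GeneModel], min_overlap: int = 20
) -> LocusPartition:
    """Partition transcripts into connected components of >min_overlap bp
    transcription-interval overlap on the same chromosome and strand."""
    if min_overlap < 0:
        raise ValueError("min_overlap must be non-negative")
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_key.setdefault((m.chrom, m.strand), []).append(m)
    classes: list[frozenset[str]] = []
    for group in by_key.values():
        group = sorted(group, key=lambda m: (m.tx_start, m.tx_end, m.transcript_id))
        current: list[str] = []
        max_end = None
        for m in group:
            if max_end is not None and min(max_end, m.tx_end) - m.tx_start > min_overlap:
                current.append(m.transcript_id)
                max_end = max(max_end, m.tx_end)
            else:
                if current:
                    classes.append(frozenset(current))
                current = [m.transcript_id]
                max_end = m.tx_end
        if current:
            classes.append(frozenset(current))
    classes.sort(key=lambda c: min(c))
    return LocusPartition(classes=tuple(classes), rule=f"overlap{min_overlap}")


def _pick_per_group(
    groups: list[list[str]], seed: int
) -> set[str]:
    """One seeded-uniform pick per group, iterated in canonical order."""
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for ids in sorted(groups, key=lambda g: min(g)):
        ids = sorted(ids)
        chosen.add(ids[int(rng.integers(len(ids)))])
    return chosen


def _utr5_structure_key(model: GeneModel):
    span = five_prime_utr_span(model)
    if span is None:
        return None
    pieces = tuple(
        (max(e.start, span.start), min(e.end, span.end))
        for e in model.exons
        if max(e.start, span.start) < min(e.end, span.end)
    )
    return (model.chrom, model.strand, pieces)


def select_representatives(
    models: Sequence[GeneModel],
    strategy: str,
    seed: int = 0,
    min_overlap: int = 20,
) -> list[GeneModel]:
    """Select a non-redundant transcript subset under the named strategy.

    Input order is preserved in the output.  Under ``unique_5utr``,
    transcripts with no annotated 5'UTR are always retained (an empty
    5'UTR is not treated as a shared structure).
    """
    if strategy == "keep_all":
        return list(models)
    if strategy == "locus_overlap":
        partition = locus_equivalence_classes(models, min_overlap=min_overlap)
        chosen = _pick_per_group([sorted(c) for c in partition.classes], seed)
        return [m for m in models if m.transcript_id in chosen]
    if strategy == "unique_5utr":
        groups: dict[object, list[str]] = {}
        keep_always = []
        for m in models:
            key = _utr5_structure_key(m)
            if key is None:
                keep_always.append(m.transcript_id)
            else:
                groups.setdefault(key, []).append(m.transcript_id)
        chosen = _pick_per_group(list(groups.values()), seed)
        chosen.update(keep_always)
        return [m for m in models if m.transcript_id in chosen]
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
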