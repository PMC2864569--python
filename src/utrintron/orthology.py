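"""Cross-species comparison of total 5'UTR-intron lengths in ortholog groups.

Each ortholog group carries, per species, the splice variants of one gene
symbol with their total 5'UTR-intron (5UI) lengths.  Because species differ
in how many variants are annotated, a per-species summary length is
computed by one of three methods: the mean over variants with non-zero 5UI
length, the variant with the longest 5UIs, or the variant whose length is
closest to a reference (typically the ortholog's summary).  Pairwise
length correlations across species consider only groups where both species
have a non-zero summary; presence/absence changes additionally require an
annotated 5'UTR on both sides to be comparable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .expression import pearson_correlation

__all__ = [
    "OrthologTranscript",
    "OrthologGroup",
    "PresenceChange",
    "SUMMARY_METHODS",
    "summarize_5ui_length",
    "pairwise_length_correlation",
    "classify_presence_change",
]

SUMMARY_METHODS = ("mean_nonzero", "longest", "closest")


@dataclass(frozen=True)
class OrthologTranscript:
    transcript_id: str
    total_5ui_length: int
    utr_annotated: bool = True

    def __post_init__(self) -> None:
        if self.total_5ui_length < 0:
            raise ValueError("negative 5UI length")


@dataclass(frozen=True)
class OrthologGroup:
    """One gene symbol's transcripts across species."""

    symbol: str
    species: Mapping[str, tuple[OrthologTranscript, ...]]


@dataclass(frozen=True)
class PresenceChange:
    symbol: str
    species_pair: tuple[str, str]
    status: str  # both_present / present_only_in_first / present_only_in_second / not_comparable
    delta_length: Optional[float] = None


def summarize_5ui_length(
    group: OrthologGroup,
    species: str,
    method: str = "mean_nonzero",
    ref_length: Optional[float] = None,
) -> Optional[float]:
    """Summarize one species' 5UI length over its splice variants.

    Only variants with an annotated 5'UTR and a non-zero 5UI length enter
    the summary; returns None when there is none.  ``closest`` picks the
    variant minimizing |length - ref_length|, ties breaking toward the
    smaller length.
    """
    if species not in group.species:
        raise KeyError(f"{group.symbol}: no data for species {species!r}")
    if method not in SUMMARY_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SUMMARY_METHODS}")
    lengths = sorted(
        t.total_5ui_length
        for t in group.species[species]
        if t.utr_annotated and t.total_5ui_length > 0
    )
    if not lengths:
        return None
    if method == "mean_nonzero":
        return float(np.mean(lengths))
    if method == "longest":
        return float(lengths[-1])
    if ref_length is None:
        raise ValueError("method 'closest' requires ref_length")
    return float(min(lengths, key=lambda l: (abs(l - ref_length), l)))


def _pair_summaries(
    group: OrthologGroup, species_a: str, species_b: str, method: str
) -> tuple[Optional[float], Optional[float]]:
    """Summaries for a species pair; 'closest' references the partner's
    mean-over-nonzero-variants summary."""
    if method == "closest":
        ref_b = summarize_5ui_length(group, species_b, "mean_nonzero")
        ref_a = summarize_5ui_length(group, species_a, "mean_nonzero")
        va = summarize_5ui_length(group, species_a, "closest", ref_length=ref_b) if ref_b is not None else None
        vb = summarize_5ui_length(group, species_b, "closest", ref_length=ref_a) if ref_a is not None else None
        return va, vb
    return (
        summarize_5ui_length(group, species_a, method),
        summarize_5ui_length(group, species_b, method),
    )


def pairwise_length_correlation(
    groups: Sequence[OrthologGroup],
    species_a: str,
    species_b: str,
    method: str = "mean_nonzero",
    log10: bool = False,
) -> tuple[float, int]:
    """Pearson correlation of summary 5UI lengths between two species.

    Groups where either species has no non-zero 5UI summary are excluded;
    the number of groups actually used is returned alongside r.  With
    ``log10=True`` the correlation is computed on log10 lengths.
    """
    xs, ys = [], []
    for g in groups:
        va, vb = _pair_summaries(g, species_a, species_b, method)
        if va is not None and vb is not None:
            xs.append(va)
            ys.append(vb)
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable groups; need at least 3")
    if log10:
        xs = [math.log10(v) for v in xs]
        ys = [math.log10(v) for v in ys]
    return pearson_correlation(xs, ys), len(xs)


def classify_presence_change(
    group: OrthologGroup,
    species_a: str,
    species_b: str,
    method: str = "mean_nonzero",
) -> PresenceChange:
    """Classify 5UI presence/absence between two species for one group.

    A species with no 5'UTR-annotated transcript is not comparable; a
    comparable species is "present" if any annotated variant has a
    non-zero 5UI length.  When both are present the summary-length
    difference (first minus second) is reported.
    """
    def annotated(sp: str) -> bool:
        return any(t.utr_annotated for t in group.species.get(sp, ()))

    pair = (species_a, species_b)
    if not annotated(species_a) or not annotated(species_b):
        return PresenceChange(group.symbol, pair, "not_comparable")
    va, vb = _pair_summaries(group, species_a, species_b, method)
    if va is not None and vb is not None:
        return PresenceChange(group.symbol, pair, "both_present", delta_length=va - vb)
    if va is not None:
        return PresenceChange(group.symbol, pair, "present_only_in_first")
    if vb is not None:
        return PresenceChange(group.symbol, pair, "present_only_in_second")
    return PresenceChange(group.symbol, pair, "both_absent")
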