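"""Gene models, strand-aware interval arithmetic and 5'UTR-intron extraction.

A transcript is represented by its genomic structure in UCSC refGene
coordinates (0-based, half-open).  From that structure we derive the
introns, classify each intron by the transcript region it lies in (5'UTR,
coding region, 3'UTR), filter out 5'UTR-intron candidates that overlap
coding sequence of sibling transcripts at the same locus, and compute a
per-transcript profile: number and total length of 5'UTR introns (5UIs),
total 5'UTR exonic length, total length of the remaining introns, and the
5'-proximal-coding-intron (5PCI) flag for transcripts whose first coding
intron starts within 150 spliced nucleotides of the transcription start
site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "IntronClass",
    "IntronRecord",
    "UTRProfile",
    "GeneTableError",
    "parse_gene_table",
    "write_gene_table",
    "introns_of",
    "five_prime_utr_span",
    "three_prime_utr_span",
    "classify_introns",
    "filter_coding_overlap",
    "transcript_coordinate",
    "utr_profile",
    "compute_profiles",
    "write_intron_bed",
    "PCI_MAX_TSS_DISTANCE",
]

#: Maximum spliced distance (nt) from the TSS to the 5' splice site of the
#: first coding intron for a transcript to count as 5PCI-bearing.
PCI_MAX_TSS_DISTANCE = 150


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class IntronClass(enum.Enum):
    UTR5 = "UTR5"
    CODING_REGION = "CODING_REGION"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class GeneModel:
    """One transcript's genomic structure.

    Exons are stored in ascending genomic order regardless of strand; the
    strand determines transcript (5'->3') orientation.  ``cds_start`` ==
    ``cds_end`` marks a non-coding transcript.
    """

    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"{self.transcript_id}: bad tx bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.transcript_id}: cds outside tx bounds")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exon on wrong chrom")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"{self.transcript_id}: exon outside tx bounds")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = ex.end
        if self.exons[0].start != self.tx_start or self.exons[-1].end != self.tx_end:
            raise ValueError(f"{self.transcript_id}: exons do not span tx bounds")
        if self.cds_start < self.cds_end:
            # Both CDS boundaries must fall in exonic sequence.
            if not any(e.start <= self.cds_start < e.end for e in self.exons):
                raise ValueError(f"{self.transcript_id}: cds_start not exonic")
            if not any(e.start < self.cds_end <= e.end for e in self.exons):
                raise ValueError(f"{self.transcript_id}: cds_end not exonic")

    @property
    def tx_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def total_exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a transcript, with its 5'->3' ordinal and region class."""

    transcript_id: str
    interval: GenomicInterval
    ordinal: int
    klass: IntronClass
    strand: str


@dataclass(frozen=True)
class UTRProfile:
    """Per-transcript derived 5'UTR-intron quantities."""

    transcript_id: str
    n_5ui: int
    total_5ui_len: int
    total_5utr_exon_len: int
    total_other_intron_len: int
    first_coding_intron_tss_dist: Optional[int]
    has_5ui: bool
    has_5pci: bool


class GeneTableError(ValueError):
    """Raised when a gene-annotation table row cannot be parsed."""


def _parse_int(text: str, row: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise GeneTableError(f"row {row}: malformed integer for {what}: {text!r}") from None


def _parse_int_list(text: str, row: int, what: str) -> list[int]:
    items = [t for t in text.strip().rstrip(",").split(",") if t != ""]
    return [_parse_int(t, row, what) for t in items]


def parse_gene_table(stream: Iterable[str]) -> list[GeneModel]:
    """Parse a refGene-dialect tab-separated annotation table.

    Expected field order: name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (exon lists comma-terminated).
    Lines starting with ``#`` and blank lines are skipped.  Rows violating
    the gene-model invariants raise :class:`GeneTableError` naming the row.
    """
    models: list[GeneModel] = []
    for row, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 10:
            raise GeneTableError(f"row {row}: expected 10 fields, got {len(fields)}")
        name, chrom, strand = fields[0], fields[1], fields[2]
        strand = strand.replace("−", "-")  # tolerate unicode minus
        tx_start = _parse_int(fields[3], row, "txStart")
        tx_end = _parse_int(fields[4], row, "txEnd")
        cds_start = _parse_int(fields[5], row, "cdsStart")
        cds_end = _parse_int(fields[6], row, "cdsEnd")
        exon_count = _parse_int(fields[7], row, "exonCount")
        starts = _parse_int_list(fields[8], row, "exonStarts")
        ends = _parse_int_list(fields[9], row, "exonEnds")
        if len(starts) != exon_count or len(ends) != exon_count:
            raise GeneTableError(
                f"row {row}: exonCount={exon_count} but "
                f"{len(starts)} starts / {len(ends)} ends"
            )
        try:
            exons = tuple(
                GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
            )
            models.append(
                GeneModel(
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=exons,
                )
            )
        except ValueError as exc:
            raise GeneTableError(f"row {row}: {exc}") from None
    return models


def write_gene_table(models: Iterable[GeneModel], stream: TextIO) -> None:
    """Write models in the refGene field order accepted by parse_gene_table."""
    for m in models:
        starts = "".join(f"{e.start}," for e in m.exons)
        ends = "".join(f"{e.end}," for e in m.exons)
        stream.write(
            "\t".join(
                (
                    m.transcript_id,
                    m.chrom,
                    m.strand,
                    str(m.tx_start),
                    str(m.tx_end),
                    str(m.cds_start),
                    str(m.cds_end),
                    str(len(m.exons)),
                    starts,
                    ends,
                )
            )
            + "\n"
        )


def introns_of(model: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, ascending; zero-length gaps omitted."""
    out = []
    for left, right in zip(model.exons, model.exons[1:]):
        if right.start > left.end:
            out.append(GenomicInterval(model.chrom, left.end, right.start))
    return out


def five_prime_utr_span(model: GeneModel) -> Optional[GenomicInterval]:
    """Genomic span of the 5'UTR: [txStart, cdsStart) on '+', [cdsEnd, txEnd) on '-'."""
    if model.strand == "+":
        if model.tx_start < model.cds_start:
            return GenomicInterval(model.chrom, model.tx_start, model.cds_start)
    else:
        if model.cds_end < model.tx_end:
            return GenomicInterval(model.chrom, model.cds_end, model.tx_end)
    return None


def three_prime_utr_span(model: GeneModel) -> Optional[GenomicInterval]:
    if model.strand == "+":
        if model.cds_end < model.tx_end:
            return GenomicInterval(model.chrom, model.cds_end, model.tx_end)
    else:
        if model.tx_start < model.cds_start:
            return GenomicInterval(model.chrom, model.tx_start, model.cds_start)
    return None


def classify_introns(model: GeneModel) -> list[IntronRecord]:
    """Classify each intron by region.

    An intron is UTR5 only if it lies entirely within the strand-aware
    5'UTR span (i.e. between two 5'UTR exons); UTR3 by the mirror rule.
    Introns straddling a CDS boundary are CODING_REGION.  Ordinals follow
    transcript 5'->3' order, so genomic order is reversed on '-'.
    """
    span5 = five_prime_utr_span(model)
    span3 = three_prime_utr_span(model)
    introns = introns_of(model)
    ordered = introns if model.strand == "+" else list(reversed(introns))
    records = []
    for ordinal, iv in enumerate(ordered, start=1):
        if span5 is not None and span5.contains(iv):
            klass = IntronClass.UTR5
        elif span3 is not None and span3.contains(iv):
            klass = IntronClass.UTR3
        else:
            klass = IntronClass.CODING_REGION
        records.append(
            IntronRecord(model.transcript_id, iv, ordinal, klass, model.strand)
        )
    return records


def _coding_exon_pieces(model: GeneModel) -> list[GenomicInterval]:
    if not model.is_coding:
        return []
    pieces = []
    for ex in model.exons:
        s = max(ex.start, model.cds_start)
        e = min(ex.end, model.cds_end)
        if s < e:
            pieces.append(GenomicInterval(model.chrom, s, e))
    return pieces


def filter_coding_overlap(
    candidates: Sequence[IntronRecord], siblings: Sequence[GeneModel]
) -> list[IntronRecord]:
    """Drop 5'UTR-intron candidates overlapping sibling coding sequence.

    A candidate is removed if any base of its interval is a coding exonic
    base of a same-chromosome, same-strand sibling transcript.  Antisense
    overlap does not disqualify a candidate.
    """
    if not candidates:
        return []
    kept = []
    for cand in candidates:
        hit = False
        for sib in siblings:
            if sib.chrom != cand.interval.chrom or sib.strand != cand.strand:
                continue
            if sib.tx_end <= cand.interval.start or sib.tx_start >= cand.interval.end:
                continue
            if any(p.overlaps(cand.interval) for p in _coding_exon_pieces(sib)):
                hit = True
                break
        if not hit:
            kept.append(cand)
    return kept


def transcript_coordinate(model: GeneModel, pos: int) -> int:
    """Spliced distance from the TSS to genomic position ``pos``.

    ``pos`` must be exonic.  Counts exonic bases in [txStart, pos) on '+'
    and in [pos, txEnd) on '-', i.e. the window between the TSS-side
    transcript boundary and ``pos`` walking 5'->3'.
    """
    if pos < model.tx_start or pos >= model.tx_end:
        raise ValueError(f"position {pos} outside transcript bounds")
    if not any(e.start <= pos < e.end for e in model.exons):
        raise ValueError(f"position {pos} is intronic")
    total = 0
    for e in model.exons:
        if model.strand == "+":
            total += max(0, min(e.end, pos) - e.start)
        else:
            total += max(0, e.end - max(e.start, pos))
    return total


def _first_coding_intron_tss_dist(
    model: GeneModel, records: Sequence[IntronRecord]
) -> Optional[int]:
    coding = [r for r in records if r.klass is IntronClass.CODING_REGION]
    if not coding:
        return None
    first = min(coding, key=lambda r: r.ordinal)
    # Distance = number of exonic bases 5' of the intron's 5' splice site.
    if model.strand == "+":
        return transcript_coordinate(model, first.interval.start - 1) + 1
    return transcript_coordinate(model, first.interval.end)


def utr_profile(
    model: GeneModel,
    siblings: Sequence[GeneModel] = (),
    pci_max_tss_distance: int = PCI_MAX_TSS_DISTANCE,
) -> UTRProfile:
    """Compute the per-transcript 5'UTR-intron profile.

    5UIs are the UTR5-class introns surviving the sibling coding-overlap
    filter; removed candidates and all non-UTR5 introns count toward
    ``total_other_intron_len`` so that intronic + exonic lengths always
    sum to the transcription-unit length.
    """
    records = classify_introns(model)
    utr5 = [r for r in records if r.klass is IntronClass.UTR5]
    kept = filter_coding_overlap(utr5, siblings)
    total_5ui = sum(r.interval.length for r in kept)
    total_intronic = sum(iv.length for iv in introns_of(model))
    span5 = five_prime_utr_span(model)
    utr5_exonic = 0
    if span5 is not None:
        utr5_exonic = sum(span5.overlap_length(e) for e in model.exons)
    dist = _first_coding_intron_tss_dist(model, records)
    has_5ui = len(kept) > 0
    has_5pci = (not has_5ui) and dist is not None and dist <= pci_max_tss_distance
    return UTRProfile(
        transcript_id=model.transcript_id,
        n_5ui=len(kept),
        total_5ui_len=total_5ui,
        total_5utr_exon_len=utr5_exonic,
        total_other_intron_len=total_intronic - total_5ui,
        first_coding_intron_tss_dist=dist,
        has_5ui=has_5ui,
        has_5pci=has_5pci,
    )


def compute_profiles(
    models: Sequence[GeneModel],
    pci_max_tss_distance: int = PCI_MAX_TSS_DISTANCE,
) -> list[UTRProfile]:
    """Profiles for a transcript collection, using locus neighbours as siblings.

    For each transcript the sibling set used by the coding-overlap filter
    is every other transcript whose transcription interval overlaps it on
    the same chromosome (strand filtering happens inside the filter).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for group in by_chrom.values():
        group.sort(key=lambda m: (m.tx_start, m.tx_end, m.transcript_id))
    profiles = []
    for m in models:
        group = by_chrom[m.chrom]
        sibs = [
            s
            for s in group
            if s is not m and s.tx_start < m.tx_end and m.tx_start < s.tx_end
        ]
        profiles.append(utr_profile(m, sibs, pci_max_tss_distance))
    return profiles


def write_intron_bed(records: Iterable[IntronRecord], stream: TextIO) -> None:
    """Write intron records as BED6 (0-based, half-open)."""
    for r in records:
        stream.write(
            "\t".join(
                (
                    r.interval.chrom,
                    str(r.interval.start),
                    str(r.interval.end),
                    r.transcript_id,
                    "0",
                    r.strand,
                )
            )
            + "\n"
        )
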