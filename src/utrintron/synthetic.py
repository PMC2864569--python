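"""Seeded generators for annotation tables, expression matrices, term
annotations and ortholog groups.

The generators emulate the statistical structure the analyses assume:
roughly a third of genes carry a 5'UTR intron, the number of 5UIs per gene
decays geometrically (>90% of 5UI-bearing genes have exactly one), 5UI
lengths are long-tailed (log-normal on the nucleotide scale), expression
variability decreases with mean expression, membership in the top fraction
of mean expression is planted with a configurable odds ratio relative to
the short-5UI category, designated terms are over-represented in a query
set, and ortholog log-lengths share a latent value giving a configurable
cross-species correlation.  Every generator is a pure function of the
configuration (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ProbeMap, length_categories
from .genemodels import GeneModel, GenomicInterval, UTRProfile, classify_introns, IntronClass
from .orthology import OrthologGroup, OrthologTranscript
from .term_enrichment import TermAnnotation

__all__ = [
    "SyntheticConfig",
    "gen_gene_models",
    "gen_expression",
    "gen_term_annotations",
    "gen_ortholog_groups",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    ``p_5ui`` (0.35) matches the observed fraction of transcripts with at
    least one 5'UTR intron; ``intron_count_decay`` (0.9) is the geometric
    success parameter for the per-gene 5UI count, putting >=90% of
    5UI-bearing genes at exactly one intron; ``length_log_mean`` /
    ``length_log_sd`` put the inter-quartile range of 5UI lengths at
    roughly 1.3-16 kb; ``p_5pci`` (0.24) is the fraction of 5UI-lacking
    genes given a coding intron within 150 spliced nt of the TSS;
    ``n_tissues`` (79) matches the expression atlas.  ``planted_or`` links
    the short-5UI category to top-``top_fraction`` mean-expression
    membership; ``ortholog_r`` is the planted cross-species correlation of
    log10 5UI lengths.
    """

    seed: int = 0
    n_genes: int = 10_000
    p_5ui: float = 0.35
    intron_count_decay: float = 0.9
    length_log_mean: float = 3.66
    length_log_sd: float = 0.8
    p_5pci: float = 0.24
    p_utr3_intron: float = 0.05
    alt_variant_frac: float = 0.15
    # expression
    n_tissues: int = 79
    expr_log_mean: float = 2.0
    expr_log_sd: float = 0.5
    cv_base: float = 0.4
    cv_mean_slope: float = 0.3
    cv_noise_sd: float = 0.08
    planted_or: float = 8.0
    top_fraction: float = 0.05
    probe_affinity_sd: float = 0.04
    shared_probe_frac: float = 0.05
    # term annotations
    n_terms: int = 50
    term_size_min: int = 20
    term_size_max: int = 200
    planted_term_size: int = 50
    planted_terms: tuple[tuple[str, float], ...] = (("PLANTED01", 8.0),)
    query_fraction: float = 0.25
    # orthologs
    ortholog_species: tuple[str, ...] = ("human", "mouse", "rat")
    n_ortholog_groups: int = 40
    ortholog_r: float = 0.9
    ortholog_log_mean: float = 3.2
    ortholog_log_sd: float = 0.7
    ortholog_variant_sd: float = 0.05
    ortholog_absence_rate: float = 0.15
    ortholog_unannotated_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in ("p_5ui", "intron_count_decay", "p_5pci", "top_fraction",
                     "query_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.planted_or < 1:
            raise ValueError("planted_or must be >= 1")
        if not 0 <= self.ortholog_r <= 1:
            raise ValueError("ortholog_r must be in [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _intron_len(rng: np.random.Generator, log_mean: float, log_sd: float) -> int:
    return max(60, int(round(10 ** rng.normal(log_mean, log_sd))))


def _gene_segments(
    rng: np.random.Generator, cfg: SyntheticConfig, has5: bool, five_pci: bool
) -> list[tuple[int, bool, str]]:
    """Transcript-order segments (length, exonic, region in {u5, cds, u3})."""
    segs: list[tuple[int, bool, str]] = []
    if has5:
        k = int(rng.geometric(cfg.intron_count_decay))
        for _ in range(k):
            segs.append((int(rng.integers(30, 200)), True, "u5"))
            segs.append((_intron_len(rng, cfg.length_log_mean, cfg.length_log_sd), False, "u5"))
        segs.append((int(rng.integers(30, 200)), True, "u5"))
    elif five_pci:
        segs.append((int(rng.integers(20, 100)), True, "u5"))
    else:
        segs.append((int(rng.integers(50, 300)), True, "u5"))
    utr_exonic = sum(l for l, exonic, _ in segs if exonic)

    n_cds_introns = int(rng.poisson(2.0))
    if five_pci:
        n_cds_introns = max(1, n_cds_introns)
        first_chunk = int(rng.integers(3, max(4, 151 - utr_exonic)))
    else:
        first_chunk = int(rng.integers(200, 800))
    segs.append((first_chunk, True, "cds"))
    for _ in range(n_cds_introns):
        segs.append((_intron_len(rng, 3.3, 0.6), False, "cds"))
        segs.append((int(rng.integers(80, 300)), True, "cds"))

    if rng.random() < cfg.p_utr3_intron:
        segs.append((int(rng.integers(50, 300)), True, "u3"))
        segs.append((_intron_len(rng, 3.0, 0.4), False, "u3"))
        segs.append((int(rng.integers(100, 500)), True, "u3"))
    else:
        segs.append((int(rng.integers(100, 800)), True, "u3"))
    return segs


def _layout(
    gid: str, chrom: str, strand: str, start: int, segs: Sequence[tuple[int, bool, str]]
) -> GeneModel:
    ordered = list(segs) if strand == "+" else list(reversed(segs))
    pos = start
    exons: list[list[int]] = []
    cds_lo: Optional[int] = None
    cds_hi: Optional[int] = None
    for length, exonic, region in ordered:
        if exonic:
            if exons and exons[-1][1] == pos:
                exons[-1][1] = pos + length
            else:
                exons.append([pos, pos + length])
            if region == "cds":
                cds_lo = pos if cds_lo is None else min(cds_lo, pos)
                cds_hi = pos + length if cds_hi is None else max(cds_hi, pos + length)
        pos += length
    assert cds_lo is not None and cds_hi is not None
    return GeneModel(
        transcript_id=gid,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=pos,
        cds_start=cds_lo,
        cds_end=cds_hi,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


def _coding_overlap_sibling(primary: GeneModel, rng: np.random.Generator) -> Optional[GeneModel]:
    """A same-strand sibling whose coding exon covers part of the primary's
    first 5'UTR intron, exercising the coding-overlap filter."""
    utr5 = [r for r in classify_introns(primary) if r.klass is IntronClass.UTR5]
    if not utr5:
        return None
    iv = utr5[0].interval
    span = min(400, iv.length - 20)
    if span < 70:
        return None
    s = iv.start + 5
    e = s + span
    return GeneModel(
        transcript_id=primary.transcript_id + "ov",
        chrom=primary.chrom,
        strand=primary.strand,
        tx_start=s,
        tx_end=e,
        cds_start=s + 20,
        cds_end=e - 20,
        exons=(GenomicInterval(primary.chrom, s, e),),
    )


def _downstream_variant(primary: GeneModel, rng: np.random.Generator) -> GeneModel:
    """A locus-sharing variant confined to the coding/3' side of the primary,
    so it never touches the primary's 5'UTR."""
    ext = int(rng.integers(50, 300))
    if primary.strand == "+":
        s = primary.cds_start + 5
        e = primary.tx_end + ext
        cds = (s + 30, e - 60)
    else:
        s = primary.tx_start - ext
        e = primary.cds_end - 5
        cds = (s + 60, e - 30)
    return GeneModel(
        transcript_id=primary.transcript_id + "lv",
        chrom=primary.chrom,
        strand=primary.strand,
        tx_start=s,
        tx_end=e,
        cds_start=cds[0],
        cds_end=cds[1],
        exons=(GenomicInterval(primary.chrom, s, e),),
    )


def gen_gene_models(cfg: SyntheticConfig) -> list[GeneModel]:
    """Generate a synthetic transcript collection.

    Strand is uniform; 5UI counts are geometric; 5UI lengths log-normal.
    A fraction of genes carry an extra splice variant: half share the
    primary's 5'UTR exactly (differing only in 3'UTR length), and the rest
    either overlap the locus downstream of the 5'UTR or place a coding
    exon inside the primary's first 5UI.
    """
    rng = _rng(cfg, 0)
    chroms = [f"chr{i}" for i in range(1, 6)]
    cursors = {c: 1_000 for c in chroms}
    models: list[GeneModel] = []
    for i in range(cfg.n_genes):
        gid = f"NM_{i + 1:06d}"
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        has5 = rng.random() < cfg.p_5ui
        five_pci = (not has5) and rng.random() < cfg.p_5pci
        segs = _gene_segments(rng, cfg, has5, five_pci)
        start = cursors[chrom]
        primary = _layout(gid, chrom, strand, start, segs)
        group = [primary]
        if rng.random() < cfg.alt_variant_frac:
            u = rng.random()
            if u < 0.5:
                delta = int(rng.integers(50, 400))
                vsegs = list(segs)
                last_len, _, last_region = vsegs[-1]
                vsegs[-1] = (last_len + delta, True, last_region)
                vstart = start if strand == "+" else start - delta
                group.append(_layout(gid + "alt", chrom, strand, vstart, vsegs))
            elif u < 0.7 and has5:
                sib = _coding_overlap_sibling(primary, rng)
                if sib is not None:
                    group.append(sib)
            else:
                group.append(_downstream_variant(primary, rng))
        models.extend(group)
        cursors[chrom] = max(m.tx_end for m in group) + 5_000
    return models


def gen_expression(
    cfg: SyntheticConfig, profiles: Sequence[UTRProfile]
) -> tuple[pd.DataFrame, ProbeMap]:
    """Generate a probe x tissue matrix and probe map for the given profiles.

    Per-gene mean expression is log-normal; per-tissue values are gamma
    with a coefficient of variation that decreases with the mean
    (``cv_mean_slope``) times log-normal noise.  Within the 5UI-bearing
    genes, membership in the top ``top_fraction`` of mean expression is
    drawn from Fisher's noncentral hypergeometric distribution with odds
    ``planted_or`` relative to the short-5UI length category, and the top
    mean values are dealt to the drawn members.  Each gene gets 1-3
    probes; a small fraction of probes additionally map to a second gene.
    """
    rng = _rng(cfg, 1)
    genes = [p.transcript_id for p in profiles]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate transcript ids in profiles")
    n = len(genes)
    means = 10 ** rng.normal(cfg.expr_log_mean, cfg.expr_log_sd, n)

    ui_pos = np.array([i for i, p in enumerate(profiles) if p.n_5ui > 0])
    if ui_pos.size >= 4:
        lengths = pd.Series(
            [profiles[i].total_5ui_len for i in ui_pos],
            index=[genes[i] for i in ui_pos],
        )
        cats = length_categories(lengths)
        short_mask = (cats == "short").to_numpy()
        short_pos = ui_pos[short_mask]
        other_pos = ui_pos[~short_mask]
        m_ui = ui_pos.size
        k = max(1, int(round(cfg.top_fraction * m_ui)))
        a = int(
            stats.nchypergeom_fisher.rvs(
                m_ui, short_pos.size, k, cfg.planted_or, random_state=rng
            )
        )
        top_members = np.concatenate(
            [
                rng.choice(short_pos, size=a, replace=False),
                rng.choice(other_pos, size=k - a, replace=False),
            ]
        ).astype(int)
        # Deal the top-k mean values (within the 5UI gene pool) to the
        # drawn top members, the rest to the remaining 5UI genes.
        pool = np.sort(means[ui_pos])[::-1]
        rest = np.setdiff1d(ui_pos, top_members)
        means[rng.permutation(top_members)] = pool[:k]
        means[rng.permutation(rest)] = pool[k:]

    rel = means / np.median(means)
    cv = cfg.cv_base * rel ** (-cfg.cv_mean_slope) * 10 ** rng.normal(
        0, cfg.cv_noise_sd, n
    )
    cv = np.clip(cv, 0.05, 2.0)
    shape = 1.0 / cv**2
    scale = means * cv**2
    values = rng.gamma(shape[:, None], scale[:, None], size=(n, cfg.n_tissues))

    n_probes = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])
    probe_gene = np.repeat(np.arange(n), n_probes)
    total = probe_gene.size
    affinity = 10 ** rng.normal(0, cfg.probe_affinity_sd, total)
    probe_values = values[probe_gene] * affinity[:, None]
    probe_ids = [f"P{j + 1:06d}" for j in range(total)]
    relations: dict[str, frozenset[str]] = {
        pid: frozenset([genes[g]]) for pid, g in zip(probe_ids, probe_gene)
    }
    n_shared = int(math.floor(cfg.shared_probe_frac * total))
    if n_shared:
        shared = rng.choice(total, size=n_shared, replace=False)
        extra = rng.integers(0, n, size=n_shared)
        for j, g2 in zip(shared, extra):
            pid = probe_ids[int(j)]
            relations[pid] = relations[pid] | {genes[int(g2)]}
    tissues = [f"tissue_{t + 1:02d}" for t in range(cfg.n_tissues)]
    matrix = pd.DataFrame(probe_values, index=probe_ids, columns=tissues)
    return matrix, ProbeMap(relations)


def gen_term_annotations(
    cfg: SyntheticConfig,
    genes: Sequence[str],
    query: Optional[Iterable[str]] = None,
) -> TermAnnotation:
    """Generate flat term annotations over ``genes``.

    Background terms draw members uniformly (hypergeometric null with
    respect to any query).  Each planted term's overlap with the query set
    is drawn from Fisher's noncentral hypergeometric distribution at the
    configured odds.  When ``query`` is None a seeded random subset of
    ``query_fraction`` of the genes is used.
    """
    rng = _rng(cfg, 2)
    genes = list(genes)
    n = len(genes)
    if n < cfg.term_size_max:
        raise ValueError("gene universe smaller than term_size_max")
    if query is None:
        q_n = max(1, int(round(cfg.query_fraction * n)))
        query_list = sorted(
            np.array(genes)[rng.choice(n, size=q_n, replace=False)].tolist()
        )
    else:
        query_list = sorted(set(query))
        if not set(query_list) <= set(genes):
            raise ValueError("query genes outside universe")
    gene_terms: dict[str, set[str]] = {}

    def add(term: str, members: Iterable[str]) -> None:
        for g in members:
            gene_terms.setdefault(g, set()).add(term)

    n_background = cfg.n_terms - len(cfg.planted_terms)
    if n_background < 0:
        raise ValueError("more planted terms than n_terms")
    for t in range(n_background):
        x = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        members = np.array(genes)[rng.choice(n, size=x, replace=False)]
        add(f"T{t + 1:04d}", members.tolist())

    query_arr = np.array(query_list)
    nonquery = np.array(sorted(set(genes) - set(query_list)))
    for term, effect in cfg.planted_terms:
        x = cfg.planted_term_size
        a = int(
            stats.nchypergeom_fisher.rvs(
                n, len(query_arr), x, effect, random_state=rng
            )
        )
        a = min(a, len(query_arr))
        picked = np.concatenate(
            [
                rng.choice(query_arr, size=a, replace=False),
                rng.choice(nonquery, size=x - a, replace=False),
            ]
        )
        add(term, picked.tolist())
    return TermAnnotation(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        universe=frozenset(genes),
    )


def gen_ortholog_groups(cfg: SyntheticConfig) -> list[OrthologGroup]:
    """Generate ortholog groups with planted cross-species length correlation.

    Species log10 lengths share a latent standard-normal component with
    weight sqrt(ortholog_r), giving pairwise correlation ``ortholog_r`` on
    the log scale.  Each species independently loses its 5UI entirely at
    ``ortholog_absence_rate`` or lacks 5'UTR annotation altogether at
    ``ortholog_unannotated_rate``; extra splice variants jitter the length
    by ``ortholog_variant_sd`` in log10.
    """
    rng = _rng(cfg, 3)
    r = cfg.ortholog_r
    w_shared = math.sqrt(r)
    w_own = math.sqrt(1 - r)
    variant_p = {cfg.ortholog_species[0]: [0.5, 0.3, 0.2]}
    groups = []
    for i in range(cfg.n_ortholog_groups):
        symbol = f"GENE{i + 1:03d}"
        latent = rng.normal()
        per_species: dict[str, tuple[OrthologTranscript, ...]] = {}
        for sp in cfg.ortholog_species:
            x = w_shared * latent + w_own * rng.normal()
            base = max(60, int(round(10 ** (cfg.ortholog_log_mean + cfg.ortholog_log_sd * x))))
            absent = rng.random() < cfg.ortholog_absence_rate
            unannotated = rng.random() < cfg.ortholog_unannotated_rate
            p = variant_p.get(sp, [0.8, 0.15, 0.05])
            n_t = int(rng.choice([1, 2, 3], p=p))
            transcripts = []
            for j in range(n_t):
                if absent:
                    length = 0
                elif j == 0:
                    length = base
                elif rng.random() < 0.15:
                    length = 0  # a variant without any 5UI
                else:
                    length = max(
                        60,
                        int(round(base * 10 ** rng.normal(0, cfg.ortholog_variant_sd))),
                    )
                transcripts.append(
                    OrthologTranscript(
                        transcript_id=f"{symbol}_{sp}_{j + 1}",
                        total_5ui_length=length,
                        utr_annotated=not unannotated,
                    )
                )
            per_species[sp] = tuple(transcripts)
        groups.append(OrthologGroup(symbol=symbol, species=per_species))
    return groups
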