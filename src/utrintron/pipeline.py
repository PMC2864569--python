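"""End-to-end orchestration: from input tables to report TSVs.

``run_analysis`` composes the module operations into the full study:
transcript dedup, 5'UTR-intron profiling, architecture-length
correlations, expression-level enrichment of the short-5UI category,
robust across-tissue dispersion, tissue breadth, term enrichment and the
cross-species ortholog comparison.  Each report section is an independent
DataFrame; a section whose inputs are missing is skipped with a logged
warning.  Everything is deterministic given the configured seed.

Transcript selection differs by section, mirroring how redundant splice
variants bias each statistic differently: length summaries keep one
representative per distinct 5'UTR (``unique_5utr``), while correlation and
expression sections keep one representative per transcription locus
(``locus_overlap``).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dedup, expression as xp, orthology, term_enrichment as te
from .expression import ExpressionMatrix, ProbeMap
from .genemodels import GeneModel, UTRProfile, compute_profiles
from .orthology import OrthologGroup
from .term_enrichment import TermAnnotation

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisInputs", "AnalysisReport", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    seed: int = 0
    window: int = 201
    low_expr_drop: float = 0.25
    top_fractions: tuple[float, ...] = (0.01, 0.05)
    n_perm: int = 1000
    min_overlap: int = 20
    pci_max_tss_distance: int = 150
    dedup_expression: str = "locus_overlap"
    n_breadth_classes: int = 5
    ortholog_methods: tuple[str, ...] = ("mean_nonzero", "longest", "closest")


@dataclass
class AnalysisInputs:
    models: Sequence[GeneModel]
    probe_matrix: Optional[pd.DataFrame] = None
    probemap: Optional[ProbeMap] = None
    terms: Optional[TermAnnotation] = None
    term_universe: Optional[frozenset] = None
    orthologs: Optional[Sequence[OrthologGroup]] = None


@dataclass
class AnalysisReport:
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.sections.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        with open(outdir / "run_log.txt", "w") as fh:
            for key in sorted(self.log):
                fh.write(f"{key}\t{self.log[key]}\n")


def _profiles_frame(profiles: Sequence[UTRProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [p.transcript_id for p in profiles],
            "n_5ui": [p.n_5ui for p in profiles],
            "total_5ui_len": [p.total_5ui_len for p in profiles],
            "total_5utr_exon_len": [p.total_5utr_exon_len for p in profiles],
            "total_other_intron_len": [p.total_other_intron_len for p in profiles],
            "has_5ui": [p.has_5ui for p in profiles],
            "has_5pci": [p.has_5pci for p in profiles],
        }
    ).set_index("transcript_id")


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _summary_section(prof: pd.DataFrame) -> pd.DataFrame:
    ui = prof[prof.has_5ui]
    rows = [
        ("n_transcripts", len(prof)),
        ("n_with_5ui", len(ui)),
        ("fraction_with_5ui", len(ui) / len(prof) if len(prof) else float("nan")),
        ("n_with_5pci", int(prof.has_5pci.sum())),
        (
            "fraction_5pci_among_no_5ui",
            prof.loc[~prof.has_5ui, "has_5pci"].mean() if (~prof.has_5ui).any() else float("nan"),
        ),
    ]
    if len(ui):
        counts = ui.n_5ui.value_counts().sort_index()
        rows.append(("fraction_single_5ui", counts.get(1, 0) / len(ui)))
        for q in (0.25, 0.5, 0.75):
            rows.append(
                (f"total_5ui_len_q{int(q * 100)}", xp.nearest_rank_quantile(ui.total_5ui_len, q))
            )
        for k, c in counts.items():
            rows.append((f"n_genes_with_{k}_5ui", int(c)))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def _correlation_section(prof: pd.DataFrame) -> pd.DataFrame:
    ui = prof[prof.has_5ui]
    rows = []
    strata = {
        "all": ui,
        "bottom25_by_5ui_len": ui[
            ui.total_5ui_len <= xp.nearest_rank_quantile(ui.total_5ui_len, 0.25)
        ],
        "bottom50_by_5ui_len": ui[
            ui.total_5ui_len <= xp.nearest_rank_quantile(ui.total_5ui_len, 0.50)
        ],
    }
    for other, label in (
        ("total_5utr_exon_len", "5ui_vs_5utr_exon"),
        ("total_other_intron_len", "5ui_vs_other_introns"),
    ):
        for stratum, sub in strata.items():
            if len(sub) < 3:
                continue
            r = xp.pearson_correlation(sub.total_5ui_len, sub[other])
            with np.errstate(divide="ignore"):
                rl = xp.pearson_correlation(
                    np.log10(sub.total_5ui_len.clip(lower=1)),
                    np.log10(sub[other].clip(lower=1)),
                )
            rows.append((label, stratum, len(sub), r, rl))
    return pd.DataFrame(
        rows, columns=["comparison", "stratum", "n", "pearson_r", "pearson_r_log10"]
    )


def _enrichment_rows(
    means: pd.Series, prof: pd.DataFrame, cats: pd.Series, fractions
) -> pd.DataFrame:
    """Top-fraction Fisher enrichment tables for the standard comparisons."""
    rows = []
    ui_genes = prof.index[prof.has_5ui & prof.index.isin(means.index)]
    no_ui = prof.index[~prof.has_5ui & prof.index.isin(means.index)]
    short = cats.index[cats == "short"]
    intermediate = cats.index[cats == "intermediate"]
    comparisons = []
    if len(ui_genes) >= 4:
        comparisons += [
            ("short_vs_other_5ui", means.loc[ui_genes], set(short)),
            (
                "short_vs_intermediate",
                means.loc[short.union(intermediate)],
                set(short),
            ),
        ]
    comparisons.append(("5ui_vs_no_5ui", means, set(ui_genes)))
    pci = prof.index[prof.has_5pci & prof.index.isin(no_ui)]
    if len(pci):
        comparisons.append(("5pci_vs_no_5pci", means.loc[no_ui], set(pci)))
    for fraction in fractions:
        for label, values, members in comparisons:
            if not members or fraction * len(values) < 1:
                continue
            res = xp.top_fraction_enrichment(values, members, fraction)
            (a, b), (c, d) = res.table
            rows.append(
                (
                    label,
                    fraction,
                    "fisher_exact_greater",
                    a + b + c + d,
                    f"{a},{b},{c},{d}",
                    res.odds_ratio,
                    res.relative_risk,
                    res.p_one_sided,
                    res.p_two_sided,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "top_fraction",
            "test",
            "n",
            "table_abcd",
            "odds_ratio",
            "relative_risk",
            "p_one_sided",
            "p_two_sided",
        ],
    )


def _rank_test_rows(means: pd.Series, prof: pd.DataFrame, cats: pd.Series) -> pd.DataFrame:
    rows = []
    short = means.reindex(cats.index[cats == "short"]).dropna()
    longer = means.reindex(cats.index[cats != "short"]).dropna()
    inter = means.reindex(cats.index[cats == "intermediate"]).dropna()
    long_ = means.reindex(cats.index[cats == "long"]).dropna()
    ui = means.reindex(prof.index[prof.has_5ui].intersection(means.index)).dropna()
    no_ui = means.reindex(prof.index[~prof.has_5ui].intersection(means.index)).dropna()
    pci = means.reindex(prof.index[prof.has_5pci].intersection(no_ui.index)).dropna()
    no_pci = no_ui.drop(pci.index)

    def add(label, a, b, sided):
        if len(a) and len(b):
            rows.append(
                (label, "wilcoxon_rank_sum", sided, len(a), len(b),
                 xp.wilcoxon_rank_sum(a, b, sided=sided))
            )

    add("short_expr_gt_longer_5ui", short, longer, "greater")
    add("long_expr_lt_intermediate", long_, inter, "less")
    add("5ui_vs_no_5ui_expr", ui, no_ui, "two")
    add("5pci_expr_gt_no_5pci", pci, no_pci, "greater")
    return pd.DataFrame(rows, columns=["comparison", "test", "sided", "n_a", "n_b", "p"])


def _dispersion_section(
    matrix: ExpressionMatrix, prof: pd.DataFrame, cats: pd.Series, cfg: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    means = xp.mean_expression(matrix)
    cv = xp.coefficient_of_variation(matrix)
    disp = xp.robust_dispersion(cv, means, window=cfg.window, low_expr_drop=cfg.low_expr_drop)
    retained = disp[disp.retained]
    rows = []
    groups = {
        c: retained.cv.reindex(cats.index[cats == c]).dropna() for c in xp.LENGTH_CATEGORIES
    }
    usable = [g for g in groups.values() if len(g)]
    if len(usable) == len(groups):
        h, p = xp.kruskal_wallis([g.to_numpy() for g in groups.values()])
        rows.append(
            ("cv_by_length_category", "kruskal_wallis", sum(map(len, usable)), h, p)
        )
    d = retained.dispersion.dropna()
    lengths = prof.total_5ui_len.reindex(cats.index).astype(float)
    for frac in (0.05, 0.01):
        if frac * len(d) < 1:
            continue
        thr = xp.nearest_rank_quantile(d, 1 - frac)
        top_d = set(d.index[d > thr])
        in_top = lengths.reindex(lengths.index.intersection(top_d)).dropna()
        out_top = lengths.drop(in_top.index).dropna()
        if len(in_top) and len(out_top):
            p = xp.wilcoxon_rank_sum(in_top, out_top, sided="less")
            rows.append(
                (f"5ui_len_top{int(frac * 100)}pct_dispersion_lt_rest",
                 "wilcoxon_rank_sum", len(in_top) + len(out_top), float("nan"), p)
            )
        short_set = set(cats.index[cats == "short"]) & set(d.index)
        if short_set:
            res = xp.top_fraction_enrichment(d, short_set, frac)
            rows.append(
                (f"short_in_top{int(frac * 100)}pct_dispersion", "fisher_exact_greater",
                 len(d), res.odds_ratio, res.p_one_sided)
            )
    table = pd.DataFrame(rows, columns=["comparison", "test", "n", "statistic", "p"])
    return table, disp


def _breadth_section(
    matrix: ExpressionMatrix, prof: pd.DataFrame, cfg: AnalysisConfig
) -> pd.DataFrame:
    presence = xp.presence_calls(matrix)
    classes = xp.tissue_breadth_classes(presence, n_classes=cfg.n_breadth_classes)
    lengths = prof.total_5ui_len.reindex(classes.index)
    ui_mask = prof.has_5ui.reindex(classes.index).fillna(False).astype(bool)
    rows = []
    groups = []
    for c in range(1, cfg.n_breadth_classes + 1):
        sel = lengths[(classes == c) & ui_mask & (lengths > 0)]
        rows.append(
            (f"class_{c}", "count", int((classes == c).sum()), int(((classes == c) & ui_mask).sum()), float("nan"))
        )
        if len(sel):
            groups.append(np.log10(sel.to_numpy()))
    rows.append(
        ("absent", "count", int((classes == 0).sum()), int(((classes == 0) & ui_mask).sum()), float("nan"))
    )
    if len(groups) >= 2:
        h, p = xp.kruskal_wallis(groups)
        rows.append(("log10_5ui_len_by_breadth_class", "kruskal_wallis", sum(map(len, groups)), h, p))
    return pd.DataFrame(rows, columns=["item", "kind", "n_genes", "n_with_5ui_or_stat", "p"])


def _term_section(
    terms: TermAnnotation, query: set, cfg: AnalysisConfig
) -> pd.DataFrame:
    query = set(query) & set(terms.universe)
    if not query:
        return pd.DataFrame(columns=["term", "N", "X", "LOD", "P", "P_adj"])
    rows = te.enrich_terms(query, terms)
    rows = te.permutation_adjust(rows, len(query), terms, n_perm=cfg.n_perm, seed=cfg.seed)
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "N": [r.n_query for r in rows],
            "X": [r.n_universe for r in rows],
            "LOD": [r.lod for r in rows],
            "P": [r.p for r in rows],
            "P_adj": [r.p_adj for r in rows],
        }
    )


def _ortholog_section(groups: Sequence[OrthologGroup], cfg: AnalysisConfig) -> pd.DataFrame:
    species = sorted({sp for g in groups for sp in g.species})
    rows = []
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            for method in cfg.ortholog_methods:
                try:
                    r, n = orthology.pairwise_length_correlation(groups, sa, sb, method)
                    rlog, _ = orthology.pairwise_length_correlation(
                        groups, sa, sb, method, log10=True
                    )
                except ValueError:
                    continue
                rows.append((sa, sb, method, "pearson_r", n, r, rlog))
            statuses = [
                orthology.classify_presence_change(g, sa, sb).status for g in groups
            ]
            for status in sorted(set(statuses)):
                rows.append(
                    (sa, sb, "presence", status, statuses.count(status),
                     float("nan"), float("nan"))
                )
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "method", "statistic", "n", "value", "value_log10"],
    )


def run_analysis(config: AnalysisConfig, inputs: AnalysisInputs) -> AnalysisReport:
    """Run every report section whose inputs are available."""
    report = AnalysisReport()
    report.log["seed"] = config.seed
    report.log["config"] = repr(config)
    report.log["models_digest"] = _digest(tuple(m for m in inputs.models))
    models = dedup.drop_multi_locus_ids(inputs.models)

    # Length summaries: one representative per distinct 5'UTR.
    m_utr = dedup.select_representatives(models, "unique_5utr", seed=config.seed)
    prof_utr = _profiles_frame(compute_profiles(m_utr, config.pci_max_tss_distance))
    report.sections["summary"] = _summary_section(prof_utr)

    # Feature correlations: one representative per locus.
    m_locus = dedup.select_representatives(
        models, "locus_overlap", seed=config.seed, min_overlap=config.min_overlap
    )
    prof_locus = _profiles_frame(compute_profiles(m_locus, config.pci_max_tss_distance))
    report.sections["length_correlations"] = _correlation_section(prof_locus)

    if inputs.probe_matrix is not None and inputs.probemap is not None:
        m_expr = dedup.select_representatives(
            models, config.dedup_expression, seed=config.seed, min_overlap=config.min_overlap
        )
        prof_expr = _profiles_frame(compute_profiles(m_expr, config.pci_max_tss_distance))
        matrix = xp.collapse_probes(inputs.probe_matrix, inputs.probemap, seed=config.seed)
        keep = matrix.values.index.intersection(prof_expr.index)
        matrix = ExpressionMatrix(matrix.values.loc[keep])
        prof_expr = prof_expr.loc[prof_expr.index.intersection(keep)]
        means = xp.mean_expression(matrix)
        ui = prof_expr[prof_expr.has_5ui & (prof_expr.total_5ui_len > 0)]
        cats = (
            xp.length_categories(ui.total_5ui_len.reindex(means.index).dropna())
            if len(ui) >= 4
            else pd.Series(dtype=object)
        )
        report.sections["expression_enrichment"] = _enrichment_rows(
            means, prof_expr, cats, config.top_fractions
        )
        report.sections["expression_rank_tests"] = _rank_test_rows(means, prof_expr, cats)
        disp_table, disp = _dispersion_section(matrix, prof_expr, cats, config)
        report.sections["dispersion_tests"] = disp_table
        report.sections["dispersion_table"] = disp.reset_index(names="gene")
        report.sections["tissue_breadth"] = _breadth_section(matrix, prof_expr, config)
        if inputs.terms is not None:
            query = set(prof_expr.index[prof_expr.has_5ui])
            report.sections["term_enrichment"] = _term_section(inputs.terms, query, config)
    else:
        logger.warning("expression inputs missing; skipping expression sections")
        report.log["skipped_expression"] = True
        if inputs.terms is not None:
            query = set(prof_locus.index[prof_locus.has_5ui])
            report.sections["term_enrichment"] = _term_section(inputs.terms, query, config)

    if inputs.orthologs is not None:
        report.sections["orthologs"] = _ortholog_section(inputs.orthologs, config)
    else:
        logger.warning("ortholog table missing; skipping ortholog section")
        report.log["skipped_orthologs"] = True
    return report
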