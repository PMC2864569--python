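"""Readers and writers for the plain-text table formats used throughout.

All tables are TSV.  Gene annotation tables use the refGene field order
(see :mod:`utrintron.genemodels`); expression matrices have an id column
followed by one column per tissue; probe maps and term annotations are
two-column pair lists; ortholog tables have one row per transcript.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .expression import ProbeMap
from .genemodels import GeneModel, parse_gene_table, write_gene_table
from .orthology import OrthologGroup, OrthologTranscript
from .term_enrichment import TermAnnotation

__all__ = [
    "read_gene_table",
    "write_gene_table_file",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_probe_map",
    "write_probe_map",
    "read_term_annotations",
    "write_term_annotations",
    "read_ortholog_table",
    "write_ortholog_table",
]


def read_gene_table(path) -> list[GeneModel]:
    with open(path) as fh:
        return parse_gene_table(fh)


def write_gene_table_file(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        write_gene_table(models, fh)


def read_expression_tsv(path) -> pd.DataFrame:
    """Matrix TSV: first column is the row id, remaining columns tissues."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_probe_map(path) -> ProbeMap:
    relations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            probe, gene = line.split("\t")[:2]
            relations.setdefault(probe, set()).add(gene)
    return ProbeMap({p: frozenset(g) for p, g in relations.items()})


def write_probe_map(probemap: ProbeMap, path) -> None:
    with open(path, "w") as fh:
        for probe in sorted(probemap.relations):
            for gene in sorted(probemap.relations[probe]):
                fh.write(f"{probe}\t{gene}\n")


def read_term_annotations(path, universe: Iterable[str]) -> TermAnnotation:
    """Two-column gene, term pairs restricted to the supplied universe."""
    universe = frozenset(universe)
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            if gene in universe:
                gene_terms.setdefault(gene, set()).add(term)
    return TermAnnotation(
        gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
        universe=universe,
    )


def write_term_annotations(ann: TermAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


ORTHOLOG_COLUMNS = ("symbol", "species", "transcript", "total_5ui_length", "utr_annotated")


def read_ortholog_table(path) -> list[OrthologGroup]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    groups = []
    for symbol, sub in df.groupby("symbol", sort=True):
        species: dict[str, tuple[OrthologTranscript, ...]] = {}
        for sp, sub2 in sub.groupby("species", sort=True):
            species[str(sp)] = tuple(
                OrthologTranscript(
                    transcript_id=str(row.transcript),
                    total_5ui_length=int(row.total_5ui_length),
                    utr_annotated=bool(row.utr_annotated),
                )
                for row in sub2.itertuples()
            )
        groups.append(OrthologGroup(symbol=str(symbol), species=species))
    return groups


def write_ortholog_table(groups: Sequence[OrthologGroup], path) -> None:
    rows = []
    for g in groups:
        for sp in sorted(g.species):
            for t in g.species[sp]:
                rows.append(
                    (g.symbol, sp, t.transcript_id, t.total_5ui_length, int(t.utr_annotated))
                )
    pd.DataFrame(rows, columns=list(ORTHOLOG_COLUMNS)).to_csv(path, sep="\t", index=False)
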