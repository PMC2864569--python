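# utrintron

Gene-architecture and expression analysis of human-style 5'UTR introns
(5UIs), for computational biologists studying why an appreciable fraction
of genes carry introns upstream of the coding sequence and what that
implies for their expression.

About a third of curated transcripts contain at least one intron entirely
within the 5' untranslated region. These introns are unusually long and
their functional role is contested: an energetic-cost view predicts highly
expressed genes should shed them, while a "genome design" view predicts
tissue-specific genes should grow them to house regulatory elements. This
package implements the full analysis needed to test those predictions on
gene-model tables and a tissue expression atlas:

- **5UI extraction** — strand-aware interval arithmetic over refGene-dialect
  tables (0-based, half-open): introns between two 5'UTR exons, filtered
  against splice variants whose coding exons overlap the candidate intron.
- **5PCI classification** — transcripts without a 5UI whose first
  coding-region intron starts within 150 spliced nucleotides of the
  transcription start site.
- **Transcript dedup** — three selection procedures: keep all; one random
  representative per locus (transcription intervals overlapping by more
  than 20 bp, transitively); one representative per distinct 5'UTR.
- **Expression statistics** — probe-to-gene collapsing, short/intermediate/
  long 5UI-length categories (quartiles), Fisher-exact enrichment of the
  short category in the top 1%/5% of mean expression, the coefficient of
  variation CV = s/x̄ across tissues, and the robust dispersion

  D(x) = (CV_x − μ₁/₂(y_x)) / MAD(y_x)

  where y_x is the vector of CVs of the 201 genes in a window centred on
  gene x after ordering by mean expression; presence calls and
  tissue-breadth classes; Wilcoxon rank-sum and Kruskal-Wallis tests.
- **Term enrichment** — per-term one-sided Fisher tests reported as
  N, X, LOD (log10 odds ratio), P and a Westfall-Young-style
  permutation-adjusted P.
- **Ortholog comparison** — total 5UI length per ortholog group summarized
  by mean-over-nonzero variants, longest variant, or variant closest to
  the ortholog; pairwise Pearson correlations (raw and log10) and
  presence/absence change classes across species.
- **Synthetic data** — seeded generators reproducing the statistical
  structure of the real inputs (geometric 5UI counts, log-normal lengths,
  mean-dependent CV, planted enrichment odds ratios, planted terms,
  correlated ortholog lengths), so the whole pipeline is testable without
  downloads.

## Worked example

```python
from io import StringIO
from utrintron import parse_gene_table, classify_introns, utr_profile

row = "NM_0001\tchr1\t+\t0\t700\t300\t650\t3\t0,200,500,\t100,400,700,"
model = parse_gene_table(StringIO(row))[0]
for rec in classify_introns(model):
    print(rec.ordinal, rec.klass.value, (rec.interval.start, rec.interval.end))
print(utr_profile(model))
```

prints

```
1 UTR5 (100, 200)
2 CODING_REGION (400, 500)
UTRProfile(transcript_id='NM_0001', n_5ui=1, total_5ui_len=100,
           total_5utr_exon_len=200, total_other_intron_len=100,
           first_coding_intron_tss_dist=300, has_5ui=True, has_5pci=False)
```

i.e. the intron at [100, 200) lies between two 5'UTR exons (a 100-nt 5UI),
the 5'UTR contributes 200 exonic nt, and the first coding intron starts
300 spliced nt from the TSS — too far for the transcript to count as
5PCI-bearing.

The same analysis end to end, on a generated study:

```sh
utrintron synth --seed 5 --out demo
utrintron run --genes demo/genes.tsv --expr demo/expr.tsv \
    --probemap demo/probemap.tsv --terms demo/terms.tsv \
    --orthologs demo/orthologs.tsv --out demo/report
head -8 demo/report/summary.tsv
```

```
statistic	value
n_transcripts	10711
n_with_5ui	3401
fraction_with_5ui	0.317524
n_with_5pci	1582
fraction_5pci_among_no_5ui	0.216416
fraction_single_5ui	0.901206
total_5ui_len_q25	1494
```

About 32% of transcripts carry a 5UI, 90% of those have exactly one, and
the lower quartile of total 5UI length is ~1.5 kb — the architecture the
generator is calibrated to emulate. The enrichment section shows the
planted association between short 5UIs and high expression
(`demo/report/expression_enrichment.tsv`):

```
comparison	top_fraction	odds_ratio	p_one_sided
short_vs_other_5ui	0.01	5.35843	2.75028e-06
short_vs_intermediate	0.01	4.05911	0.000813038
5ui_vs_no_5ui	0.01	0.74991	0.917922
```

Genes in the short-length category are strongly over-represented in the
top 1% of mean expression, while mere 5UI presence is not — the signature
the analysis is designed to detect. The term-enrichment table ranks the
planted term first (`N=31` of `X=50` annotated genes in the query,
`LOD=0.61`, adjusted `P=0.001`).

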