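# Methods

## Coordinate model and 5'UTR-intron extraction

All genomic coordinates are 0-based, half-open (the UCSC refGene dialect
of the input tables); conversion to 1-based happens only in report text,
never internally. A transcript is its exon list plus transcription and
CDS bounds; exons are stored in ascending genomic order and the strand
determines 5'→3' orientation. Invariants are enforced at construction:
exons sorted, pairwise disjoint, spanning exactly [txStart, txEnd); CDS
bounds ordered, inside the transcription unit, and each falling in exonic
sequence when the transcript is coding.

The 5'UTR span is [txStart, cdsStart) on '+' and [cdsEnd, txEnd) on '−';
the 3'UTR span is the mirror. An intron is classified UTR5 only when it
lies *entirely* inside the 5'UTR span — i.e. it sits between two 5'UTR
exons; anything touching coding sequence, including introns flanked by an
exon that carries both UTR and CDS bases, is CODING_REGION. Zero-length
gaps between abutting exons are annotation artifacts, not introns.

A UTR5 candidate is discarded when any of its bases is a *coding exonic*
base of a same-chromosome, same-strand splice variant at the locus. The
filter deliberately uses sibling coding exons rather than the sibling's
whole genomic CDS span (intronic bases inside a sibling's CDS interval do
not make the candidate coding), and ignores antisense transcripts, which
are a different locus biologically. Candidates removed by this filter are
counted with the "other introns" total, so for every transcript

    total_5ui_len + total_other_intron_len + total_exonic_len
        = txEnd − txStart

exactly; this identity is property-tested.

### 5'-proximal coding introns (5PCIs)

A transcript without a 5UI is 5PCI-bearing when its first coding intron's
5' splice site lies within 150 nucleotides of the TSS measured in
*spliced* (transcript) coordinates — the number of exonic bases 5' of the
splice site — with the threshold inclusive (≤ 150). Spliced rather than
genomic distance is used because the motivating statistic (the typical
first-5UI position near 130 nt) is an mRNA-coordinate quantity. The
distance helper counts exonic bases in [txStart, pos) on '+' and
[pos, txEnd) on '−', a definition that is exactly mirror-symmetric:
reflecting every coordinate and flipping strand leaves all profile fields
unchanged (property-tested on whole cohorts).

## Transcript selection

Redundant splice variants bias different statistics differently, so three
selection procedures are provided. Ids mapping to more than one genomic
locus (different chromosome, or disconnected transcription intervals) are
removed first; byte-identical duplicate rows collapse to one. Locus
equivalence is the transitive closure of "transcription intervals on the
same chromosome and strand overlap by strictly more than 20 bp" — only
the closure yields a partition, and a sorted sweep computes it exactly
because, with intervals ordered by start, the component member with the
largest end maximizes overlap with the next interval. Representatives are
drawn by a seeded RNG over lexicographically sorted ids, making selection
reproducible and invariant to input order. Under `unique_5utr`,
transcripts sharing an identical (non-empty) 5'UTR exon structure
collapse to one representative; transcripts with no annotated 5'UTR are
never collapsed, since an empty structure is not a shared 5'UTR and
collapsing on it would merge unrelated loci.

The report uses `unique_5utr` for length summaries (it retains all
distinct 5'UTRs, the most information about 5UI lengths) and
`locus_overlap` for feature correlations and expression sections (one
observation per transcriptional unit). Which selection the expression
analyses should use is genuinely open; it is configurable with
`locus_overlap` as the default.

## Expression statistics

Probe-to-gene collapsing assigns each multi-gene probe to one
seeded-uniform gene and averages probes arithmetically per gene and
tissue. Input values are assumed already normalized (gcRMA-like,
non-negative); no normalization is performed here.

Percentiles use the **nearest-rank** convention everywhere (length
categories, top-fraction thresholds, the presence threshold): the
q-quantile of n sorted values is the value at 1-based rank ⌈qn⌉. It is
exact, interpolation-free and platform-independent. Length categories
among 5UI-bearing genes are short (≤ q25), intermediate, long (> q75);
ties at the boundary go to the lower category, so a degenerate all-equal
input is all-short.

Fisher's exact test is computed in exact integer arithmetic: the
hypergeometric weights C(r1,k)·C(r2,c1−k) are integers, so tail sums and
the two-sided rule (sum of probabilities of tables no more probable than
observed) involve no floating-point tie tolerance; the single float
division happens at the end. The test suite checks exact agreement
(|Δp| < 1e-12) against an independent enumeration using multinomial
table weights, over all tables with every margin ≤ 30. Odds ratios are
(a·d)/(b·c) with a +0.5 Haldane correction applied iff some cell is zero;
relative risk is reported alongside because "x times more likely"
phrasings are ambiguous between the two.

The coefficient of variation uses the sample (n−1) standard deviation;
genes with zero mean get NaN. The robust dispersion statistic orders
genes by mean expression after dropping the lowest 25% (array
measurements of weakly expressed genes inflate apparent variability),
then standardizes each gene's CV by the median and raw MAD (no 1.4826
consistency factor — the statistic is a rank-like score, not a variance
estimate) of the 201-gene window centred on it. Edge windows are clamped
to the first/last full window so the window size is constant; D is
undefined where the window MAD is zero. On synthetic data with CV a
decreasing function of the mean, Spearman(CV, mean) is strongly negative
while |Spearman(D, mean)| < 0.05 — the de-trending contract.

Presence calls use one global threshold — the nearest-rank 25th
percentile of per-gene mean expression — with strict inequality, so a
gene whose value equals the threshold is absent. Tissue-breadth classes
bin per-tissue counts 1..T into five equal-width bins of width ⌈T/5⌉
(the class boundaries are not dictated by the data; equal width is the
simplest defensible choice), with count 0 reported as a separate
"absent" class.

The Wilcoxon rank-sum p-value is exact for pooled sizes ≤ 12 via a
subset-sum dynamic programme over doubled midranks (doubling makes tied
midranks integral); this is the permutation distribution, valid under
ties, and is verified against brute-force enumeration. Larger samples
use the tie-corrected normal approximation with continuity correction.
The two-sided exact p is twice the smaller tail, capped at 1.
Kruskal-Wallis and Pearson correlation delegate to scipy, with the
degenerate all-values-identical case defined as (H = 0, p = 1).

## Term enrichment

Each term yields a query × term 2×2 table tested one-sided (greater);
the effect size is LOD = log10 of the (possibly Haldane-corrected) odds
ratio; terms annotating no gene or every gene are skipped; rows sort by
LOD descending. Annotations are flat gene → term sets — no ontology
propagation; the ontology graph is an external resource and propagated
annotation tables can be supplied as input.

The adjusted p is a Westfall-Young-style min-p resampling estimate:
n_perm uniform random query sets of the observed size are drawn, and a
term's adjusted p is the add-one-smoothed fraction of resamples whose
minimum per-term p is ≤ the term's observed p. Observed and resampled
per-term p-values come from the same precomputed hypergeometric lookup,
so discrete ties compare consistently. The estimate is clipped from
below at the raw p: with finitely many resamples the empirical min-p
fraction can undercut a very small raw p, and a family-wise estimate
below the per-term one is not meaningful.

## Ortholog comparison

Per species, the 5UI length of a gene is summarized over splice variants
three ways: mean over variants with non-zero 5UI length; the longest
variant; or the variant closest to a reference length, with ties broken
toward the smaller length. In pairwise use, "closest" references the
partner species' mean-over-nonzero summary (the definition is otherwise
circular when both species have several variants). Correlations are
Pearson, computed on raw lengths with log10 reported alongside — which
scale the headline numbers should use is open, so both are emitted; the
synthetic generator plants its correlation on the log10 scale, where
length distributions are approximately normal. Groups where either
species lacks a non-zero summary are excluded and the count used is
reported. Presence-change classification requires an annotated 5'UTR on
both sides; two annotated species that both lack 5UIs are reported as
`both_absent` (a real outcome distinct from "not comparable").

## Synthetic data

The generators are pure functions of the configuration, seed included;
identical configurations give byte-identical outputs. Defaults encode
the study conditions: 35% of genes carry a 5UI; per-gene 5UI counts are
geometric with success 0.9, putting ≥ 90% of 5UI-bearing genes at
exactly one intron; per-intron lengths are log10-normal with mean 3.66
and SD 0.8, placing the inter-quartile range of total 5UI length near
1.3–16 kb; 24% of 5UI-lacking genes get a coding intron within 150
spliced nt of the TSS; expression has 79 tissues. A configurable
fraction of genes carries an extra splice variant — identical 5'UTR with
a different 3' end (exercises `unique_5utr`), a locus-sharing variant
confined to the coding/3' side (exercises `locus_overlap`), or a sibling
whose coding exon sits inside the primary's first 5UI (exercises the
coding-overlap filter).

Expression values are gamma-distributed per gene and tissue with the
configured mean and a CV that decays as a power of the mean times
log-normal noise — gamma keeps values non-negative at exactly the
specified mean/CV. The association between the short-5UI category and
top-fraction membership is planted by drawing the overlap count from
Fisher's noncentral hypergeometric distribution at the configured odds
ratio and dealing the top mean values to the drawn members; at odds 1
this reduces exactly to the null. Probes (1–3 per gene) multiply the
gene signal by a per-probe affinity (log10 SD 0.04); a small fraction of
probes also map to a second gene. Planted terms use the same noncentral
hypergeometric device for their query overlap. Ortholog log10 lengths
share a latent standard-normal component with weight √r, giving pairwise
correlation r on the log scale.

What the generator does **not** emulate: real probe cross-hybridization
structure, correlated tissues, chromosome-scale gene density, sequence
content, alternative promoters, or annotation error modes beyond the
three variant types above. Passing tests therefore demonstrate that the
statistics recover effects of the planted form at realistic sizes and
control their nulls — not that the biological conclusions transfer to
any particular real annotation release.

## Problem sizes and numerical choices

The acceptance checks run at 10,000 genes × 79 tissues with 25 (planted)
and 100 (null) expression replicates, 50 term replicates with 500
permutations, and 100 ortholog replicates of 40 groups — sizes at which
the planted-effect estimators are stable to a few percent while the full
suite completes in well under a minute per check. Seeds are explicit
everywhere; hypothesis-based property tests run derandomized. Degenerate
inputs are defined rather than left to chance: empty 5'UTR spans yield
no span, zero window MAD yields undefined D, all-identical rank-test
inputs yield p = 1, constant vectors yield undefined correlation.

## Known limitations

- The coding-overlap filter consults transcription-interval neighbours
  only; a sibling annotated on a different chromosome copy of a locus is
  not considered (multi-locus ids are removed upstream anyway).
- The exact Wilcoxon cut-off (pooled n ≤ 12) is conservative; between 13
  and ~30 the normal approximation is used where an exact computation
  would still be feasible.
- The permutation adjustment treats terms as exchangeable under uniform
  query resampling; gene-level annotation biases (e.g. length-dependent
  annotation density) are not modelled.
- Report tables carry raw per-test p-values by design; only the term
  section is multiplicity-adjusted.
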