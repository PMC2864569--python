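"""Expression-level statistics for gene-architecture analyses.

Covers probe-to-gene collapsing, per-gene mean expression, 5'UTR-intron
length categories, exact Fisher contingency tests, top-fraction enrichment,
the coefficient of variation, a robust windowed-median/MAD dispersion
measure that de-trends the mean-variance relationship, presence calls and
tissue-breadth classes, and the rank tests (Wilcoxon rank-sum and
Kruskal-Wallis) used to compare groups of genes.

Percentiles use the nearest-rank convention throughout: the q-quantile of n
sorted values is the value at (1-based) rank ``ceil(q*n)``.  This is exact,
interpolation-free and identical across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ProbeMap",
    "ContingencyResult",
    "nearest_rank_quantile",
    "collapse_probes",
    "mean_expression",
    "length_categories",
    "LENGTH_CATEGORIES",
    "fisher_exact",
    "top_fraction_enrichment",
    "coefficient_of_variation",
    "robust_dispersion",
    "presence_calls",
    "tissue_breadth_classes",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "pearson_correlation",
]

LENGTH_CATEGORIES = ("short", "intermediate", "long")

#: Pooled-sample-size bound below which the Wilcoxon rank-sum p-value is
#: computed by exact enumeration of the permutation distribution.
WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene x tissue matrix of non-negative expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 tissues")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ProbeMap:
    """Probe identifier -> set of gene identifiers."""

    relations: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for probe, genes in self.relations.items():
            if not genes:
                raise ValueError(f"probe {probe} maps to no gene")


@dataclass(frozen=True)
class ContingencyResult:
    """Exact test result for a 2x2 table [[a, b], [c, d]].

    ``odds_ratio`` is (a*d)/(b*c), Haldane-corrected (+0.5 to every cell)
    if and only if some cell is zero; ``relative_risk`` is
    (a/(a+b))/(c/(c+d)) on the same (possibly corrected) table.
    ``p_one_sided`` is the upper (greater) hypergeometric tail;
    ``p_two_sided`` sums the probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    relative_risk: float
    p_one_sided: float
    p_two_sided: float

    def p(self, sided: str = "two") -> float:
        if sided == "greater":
            return self.p_one_sided
        if sided == "two":
            return self.p_two_sided
        raise ValueError(f"unknown sidedness {sided!r}")


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank q-quantile: sorted value at 1-based rank ceil(q*n)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty input")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


def collapse_probes(
    probe_matrix: pd.DataFrame, probemap: ProbeMap, seed: int = 0
) -> ExpressionMatrix:
    """Collapse a probe x tissue matrix to gene x tissue.

    A probe mapping to several genes is assigned to one seeded-uniform
    representative gene and removed from the others; per gene, the value is
    the arithmetic mean over its probes in each tissue.  Genes left without
    probes are dropped.
    """
    if probe_matrix.empty:
        raise ValueError("empty probe matrix")
    missing = [p for p in probe_matrix.index if p not in probemap.relations]
    if missing:
        raise ValueError(f"probes absent from probe map: {missing[:5]}")
    rng = np.random.default_rng(seed)
    assigned: dict[str, str] = {}
    for probe in sorted(probe_matrix.index):
        genes = sorted(probemap.relations[probe])
        assigned[probe] = genes[int(rng.integers(len(genes)))] if len(genes) > 1 else genes[0]
    owner = pd.Series([assigned[p] for p in probe_matrix.index], index=probe_matrix.index)
    collapsed = probe_matrix.groupby(owner).mean().sort_index()
    return ExpressionMatrix(collapsed)


def mean_expression(m: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean over tissues, per gene."""
    return m.values.mean(axis=1)


def length_categories(total_5ui_len: pd.Series) -> pd.Series:
    """Assign short / intermediate / long categories by total 5UI length.

    Boundaries are the nearest-rank 25th and 75th percentiles among the
    supplied (5UI-bearing) genes: short iff length <= q25, long iff
    length > q75, intermediate otherwise.
    """
    lengths = total_5ui_len.astype(float)
    if len(lengths) < 4:
        raise ValueError("need at least 4 genes to form length categories")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive (5UI-bearing genes only)")
    q25 = nearest_rank_quantile(lengths, 0.25)
    q75 = nearest_rank_quantile(lengths, 0.75)
    cats = np.where(lengths <= q25, "short", np.where(lengths > q75, "long", "intermediate"))
    return pd.Series(pd.Categorical(cats, categories=LENGTH_CATEGORIES), index=lengths.index)


def _table_cells(table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    cells = (int(a), int(b), int(c), int(d))
    if any(x < 0 for x in cells):
        raise ValueError("table cells must be non-negative")
    return cells


def fisher_exact(table, sided: str = "two") -> ContingencyResult:
    """Fisher's exact test on a 2x2 table, computed in exact integer arithmetic.

    The hypergeometric weights comb(r1, k) * comb(r2, c1-k) are integers, so
    tail sums and the two-sided "no more probable than observed" rule are
    evaluated without floating-point ties; the result is converted to float
    once at the end.  ``sided`` only selects which p-value :meth:`~ContingencyResult.p`
    returns; both tails are always computed.
    """
    a, b, c, d = _table_cells(table)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all four margins must be positive")
    n = r1 + r2
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    p_greater = sum(w for k, w in weights.items() if k >= a) / denom
    p_two = sum(w for w in weights.values() if w <= w_obs) / denom
    if min(a, b, c, d) == 0:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    odds_ratio = (af * df) / (bf * cf)
    relative_risk = (af / (af + bf)) / (cf / (cf + df))
    result = ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=odds_ratio,
        relative_risk=relative_risk,
        p_one_sided=min(1.0, p_greater),
        p_two_sided=min(1.0, p_two),
    )
    result.p(sided)  # validate sidedness eagerly
    return result


def top_fraction_enrichment(
    values: pd.Series, members: Iterable[str], fraction: float
) -> ContingencyResult:
    """Enrichment of a gene set in the top ``fraction`` of ``values``.

    The top set is every gene whose value exceeds the nearest-rank
    (1 - fraction)-quantile; with distinct values this has size
    round-to-floor(fraction * n).  Builds the member x top 2x2 table and
    delegates to :func:`fisher_exact`.
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    unknown = members - set(values.index)
    if unknown:
        raise ValueError(f"members not in value index: {sorted(unknown)[:5]}")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if fraction * len(values) < 1:
        raise ValueError("fraction too small for the number of genes")
    threshold = nearest_rank_quantile(values, 1 - fraction)
    top = set(values.index[values > threshold])
    a = len(members & top)
    b = len(members - top)
    c = len(top - members)
    d = len(values.index) - a - b - c
    return fisher_exact(((a, b), (c, d)))


def coefficient_of_variation(m: ExpressionMatrix) -> pd.Series:
    """Sample (n-1) standard deviation over mean, per gene; NaN if mean is 0."""
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=1)
    cv = sds / means
    cv[means <= 0] = np.nan
    return cv


def robust_dispersion(
    cv: pd.Series,
    mean: pd.Series,
    window: int = 201,
    low_expr_drop: float = 0.25,
) -> pd.DataFrame:
    """Windowed median/MAD normalization of the coefficient of variation.

    Genes in the lowest ``low_expr_drop`` fraction of mean expression are
    dropped (microarray noise inflates their apparent variability).  The
    remaining genes are ordered by mean; for each gene the dispersion is

        D = (CV - median(window CVs)) / MAD(window CVs)

    over the ``window`` genes centred on it, clamped to the first/last full
    window at the edges.  MAD is the raw median absolute deviation (no
    normal-consistency factor); D is NaN where the window MAD is zero and
    for dropped genes.

    Returns a DataFrame indexed like the input with columns ``mean``,
    ``cv``, ``window_median``, ``window_mad``, ``dispersion``, ``retained``.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if not 0 <= low_expr_drop < 1:
        raise ValueError("low_expr_drop must be in [0, 1)")
    mean = mean.astype(float)
    cv = cv.reindex(mean.index).astype(float)
    n = len(mean)
    n_drop = int(math.floor(n * low_expr_drop))
    order = mean.sort_values(kind="mergesort").index
    retained_idx = order[n_drop:]
    m = len(retained_idx)
    if window > m:
        raise ValueError(f"window {window} exceeds retained gene count {m}")
    cvs = cv.loc[retained_idx].to_numpy()
    windows = sliding_window_view(cvs, window)
    meds = np.median(windows, axis=1)
    mads = np.median(np.abs(windows - meds[:, None]), axis=1)
    half = window // 2
    widx = np.clip(np.arange(m) - half, 0, m - window)
    med_g = meds[widx]
    mad_g = mads[widx]
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mad_g > 0, (cvs - med_g) / mad_g, np.nan)
    out = pd.DataFrame(
        {
            "mean": mean,
            "cv": cv,
            "window_median": np.nan,
            "window_mad": np.nan,
            "dispersion": np.nan,
            "retained": False,
        },
        index=mean.index,
    )
    out.loc[retained_idx, "window_median"] = med_g
    out.loc[retained_idx, "window_mad"] = mad_g
    out.loc[retained_idx, "dispersion"] = disp
    out.loc[retained_idx, "retained"] = True
    return out


def presence_calls(m: ExpressionMatrix) -> pd.DataFrame:
    """Boolean gene x tissue presence calls.

    A gene is present in a tissue iff its value there strictly exceeds a
    single global threshold: the nearest-rank 25th percentile of per-gene
    mean expression over all genes.
    """
    threshold = nearest_rank_quantile(mean_expression(m), 0.25)
    return m.values > threshold


def tissue_breadth_classes(presence: pd.DataFrame, n_classes: int = 5) -> pd.Series:
    """Bin per-gene tissue counts into equal-width breadth classes.

    Counts 1..T map to classes 1..n_classes with bin width ceil(T /
    n_classes); a count of 0 is reported as class 0 ("absent").
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    counts = presence.sum(axis=1).astype(int)
    t = presence.shape[1]
    width = math.ceil(t / n_classes)
    classes = np.where(counts > 0, np.minimum((counts - 1) // width + 1, n_classes), 0)
    return pd.Series(classes, index=presence.index, dtype=int)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact P(W <= w_obs) and P(W >= w_obs) for the rank sum of sample a.

    Uses a subset-sum dynamic programme over doubled midranks (doubling
    makes tied midranks integral), counting for every subset size the
    number of subsets at each rank total.
    """
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    na = len(a)
    w_obs = int(ranks2[:na].sum())
    max_sum = int(ranks2.sum())
    counts = np.zeros((na + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in ranks2:
        counts[1:, r:] += counts[:-1, : max_sum + 1 - r]
    total = math.comb(len(pooled), na)
    dist = counts[na]
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return float(p_le), float(p_ge)


def wilcoxon_rank_sum(a, b, sided: str = "two") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``sided``: "less" tests whether ``a`` is stochastically smaller than
    ``b``, "greater" the reverse, "two" is two-sided.  With a pooled size
    of at most 12 the p-value is exact (permutation distribution of the
    rank sum, valid under ties); larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("less", "greater", "two"):
        raise ValueError(f"unknown sidedness {sided!r}")
    if a.size + b.size <= WILCOXON_EXACT_MAX_N:
        p_le, p_ge = _exact_ranksum_p(a, b)
        if sided == "less":
            return min(1.0, p_le)
        if sided == "greater":
            return min(1.0, p_ge)
        return min(1.0, 2 * min(p_le, p_ge))
    alternative = {"less": "less", "greater": "greater", "two": "two-sided"}[sided]
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # degenerate: every rank tied
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
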