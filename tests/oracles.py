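"""Independent reference implementations used to check the package.

These deliberately use brute force (per-base labelling, exhaustive
enumeration, multinomial table probabilities) and share no code paths with
the implementations they verify.
"""

from __future__ import annotations

import itertools
import math

from utrintron.genemodels import GeneModel, GenomicInterval, introns_of


def perbase_intron_classes(model: GeneModel) -> list[tuple[tuple[int, int], str]]:
    """Label each intron by checking every one of its bases against the
    strand-aware UTR spans, in genomic order."""
    if model.strand == "+":
        utr5_lo, utr5_hi = model.tx_start, model.cds_start
        utr3_lo, utr3_hi = model.cds_end, model.tx_end
    else:
        utr5_lo, utr5_hi = model.cds_end, model.tx_end
        utr3_lo, utr3_hi = model.tx_start, model.cds_start
    out = []
    for iv in introns_of(model):
        in5 = all(utr5_lo <= p < utr5_hi for p in range(iv.start, iv.end))
        in3 = all(utr3_lo <= p < utr3_hi for p in range(iv.start, iv.end))
        klass = "UTR5" if in5 else ("UTR3" if in3 else "CODING_REGION")
        out.append(((iv.start, iv.end), klass))
    return out


def mirror_model(model: GeneModel, length: int) -> GeneModel:
    """Reflect every coordinate x -> length - x and flip the strand."""
    exons = tuple(
        GenomicInterval(model.chrom, length - e.end, length - e.start)
        for e in reversed(model.exons)
    )
    return GeneModel(
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand="-" if model.strand == "+" else "+",
        tx_start=length - model.tx_end,
        tx_end=length - model.tx_start,
        cds_start=length - model.cds_end,
        cds_end=length - model.cds_start,
        exons=exons,
    )


def fisher_tail_probs(n: int, r1: int, c1: int):
    """Hypergeometric p-values for every table with the given margins.

    Table probabilities are proportional to the multinomial coefficient
    n! / (a! b! c! d!); everything stays in exact integer arithmetic.
    Returns {a: (p_greater, p_two_sided)}.
    """
    r2, c2 = n - r1, n - c1
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    fact = math.factorial
    weights = {}
    for a in range(lo, hi + 1):
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        weights[a] = fact(n) // (fact(a) * fact(b) * fact(c) * fact(d))
    total = sum(weights.values())
    out = {}
    for a in range(lo, hi + 1):
        greater = sum(w for k, w in weights.items() if k >= a)
        two = sum(w for w in weights.values() if w <= weights[a])
        out[a] = (greater / total, two / total)
    return out


def ranksum_enumeration(a, b, sided: str) -> float:
    """Exact rank-sum p by enumerating every assignment of pooled values
    to the first sample (midranks, so ties are handled)."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    w_obs = sum(ranks[:na])
    count_le = count_ge = total = 0
    for combo in itertools.combinations(range(n), na):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    p_le, p_ge = count_le / total, count_ge / total
    if sided == "less":
        return min(1.0, p_le)
    if sided == "greater":
        return min(1.0, p_ge)
    return min(1.0, 2 * min(p_le, p_ge))
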