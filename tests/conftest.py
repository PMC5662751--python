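"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (brute force, exhaustive
enumeration) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from clipdep.intervals import GenomicInterval, PeakSet, TranscriptAnnotation


# ---------------------------------------------------------------- oracles
def brute_jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    union = len(set(range(a.start, a.end)) | set(range(b.start, b.end)))
    return inter / union


def brute_nearest(query: PeakSet, reference: PeakSet):
    """All-pairs nearest distance with smallest-start-then-name tie-break."""
    out = []
    for q in query:
        best = (math.inf, None)
        for r in reference:
            if r.chrom != q.chrom:
                continue
            if q.start >= r.end:
                d = q.start - r.end
            elif r.start >= q.end:
                d = r.start - q.end
            else:
                d = 0
            if d < best[0] or (
                d == best[0]
                and best[1] is not None
                and (r.start, r.name) < (best[1].start, best[1].name)
            ):
                best = (d, r)
        out.append((best[0], best[1].name if best[1] else None))
    return out


def fisher_exact_enum(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def pmf(k: int) -> float:
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def ranksum_exact_p(x, y, alternative="two-sided") -> float:
    """Exact Wilcoxon rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    ranks = stats.rankdata(pooled)
    obs = sum(ranks[: n_x])
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n_x):
        stats_all.append(sum(ranks[i] for i in idx))
    stats_all = np.array(stats_all)
    if alternative == "greater":
        return float(np.mean(stats_all >= obs - 1e-9))
    if alternative == "less":
        return float(np.mean(stats_all <= obs + 1e-9))
    mean = stats_all.mean()
    return float(np.mean(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-9))


def signed_rank_exact_p(diffs) -> float:
    """Exact two-sided Wilcoxon signed-rank p by enumerating sign flips."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    obs = float(ranks[d > 0].sum())
    n = len(d)
    all_w = []
    for signs in itertools.product([0, 1], repeat=n):
        all_w.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    all_w = np.array(all_w)
    mean = all_w.mean()
    return float(np.mean(np.abs(all_w - mean) >= abs(obs - mean) - 1e-9))


def max_disjoint_hits_dp(sequence: str, words) -> int:
    """DP maximum number of pairwise-disjoint exact word matches."""
    matches = []
    for w in words:
        start = sequence.find(w)
        while start != -1:
            matches.append((start, start + len(w)))
            start = sequence.find(w, start + 1)
    matches.sort(key=lambda m: m[1])
    best_at_end: list[int] = []
    ends: list[int] = []
    best = 0
    for s, e in matches:
        # best count among matches ending at or before s
        import bisect

        i = bisect.bisect_right(ends, s)
        cand = (best_at_end[i - 1] if i else 0) + 1
        best = max(best, cand)
        ends.append(e)
        best_at_end.append(max(best_at_end[-1] if best_at_end else 0, cand))
    return best


def random_peakset(
    rng: np.random.Generator,
    n: int,
    label: str,
    chroms=("chr1", "chr2"),
    span: int = 10_000,
    max_len: int = 300,
) -> PeakSet:
    ivs = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(
            GenomicInterval(
                chrom, start, start + length,
                strand=".", score=float(rng.uniform(0, 20)),
                name=f"{label}_{i}",
            )
        )
    return PeakSet(ivs, label=label)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


# --------------------------------------------------------------- fixtures
@pytest.fixture()
def toy_annotation() -> list[TranscriptAnnotation]:
    """One plus-strand and one minus-strand transcript on chr1."""
    return [
        TranscriptAnnotation(
            "txA", "chr1", "+",
            {
                "UTR5": [GenomicInterval("chr1", 1000, 1200, "+")],
                "CDS": [GenomicInterval("chr1", 1200, 2000, "+")],
                "intron": [GenomicInterval("chr1", 2000, 2500, "+")],
                "UTR3": [GenomicInterval("chr1", 2500, 5000, "+")],
                "TTS": [GenomicInterval("chr1", 5000, 5200, "+")],
            },
        ),
        TranscriptAnnotation(
            "txB", "chr1", "-",
            {
                "UTR3": [GenomicInterval("chr1", 8000, 9000, "-")],
                "ncRNA": [GenomicInterval("chr1", 9500, 9800, "-")],
            },
        ),
    ]
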