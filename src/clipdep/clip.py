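"""Sfpq control over Ago2 CLIP peaks: dual-filter dependency merge, distance
categorization, category-enrichment tests, the binned shuffle Z-score test,
recruitment spatial correlation and descriptive peak/3'UTR geometry.

The causal question: are Ago2 binding sites that shrink on Sfpq knockdown
concentrated near Sfpq binding sites inside 3'UTRs? The shuffle test keeps
the Sfpq peaks fixed, re-places each reduced Ago2 peak uniformly at random
within its host 3'UTR (length preserved) and compares the observed per-bin
counts of nearest-Sfpq distances with the permutation null via a Z score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    DistanceCategory,
    GenomicInterval,
    PeakSet,
    TranscriptAnnotation,
    assign_genomic_category,
    categorize_distance,
    jaccard_merge,
    nearest_distance,
)

__all__ = [
    "DependencyCall",
    "ShuffleTestResult",
    "ShuffleTest",
    "ShuffleTestResults",
    "dependent_peak_merge",
    "categorize_by_distance",
    "calls_to_dataframe",
    "category_enrichment_test",
    "fraction_independent_close",
    "recruitment_spatial_correlation",
    "peak_geometry_summary",
    "utr_length_comparison",
    "find_host_utrs",
]


@dataclass
class DependencyCall:
    """One Ago2 peak with its nearest-Sfpq distance and categories."""

    ago2_peak: GenomicInterval
    nearest_sfpq: str | None
    distance: float
    distance_category: DistanceCategory
    genomic_category: str
    reduced_on_knockdown: bool = False


def dependent_peak_merge(
    all_peaks: PeakSet,
    filter1: PeakSet,
    filter2: PeakSet,
    min_jaccard: float = 0.10,
    mode: str = "and",
) -> PeakSet:
    """Peaks of ``all_peaks`` supported by the two knockdown filters.

    filter1: peaks enriched in control vs knockdown (the dependency signal);
    filter2: peaks unchanged between knockdown and control baselines (the
    double check). With ``mode="and"`` (default) a peak needs Jaccard >=
    ``min_jaccard`` support against both filter sets; ``mode="or"`` accepts
    support from either.
    """
    if mode not in {"and", "or"}:
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    hit1 = {iv.name for iv in jaccard_merge(all_peaks, filter1, min_jaccard)}
    hit2 = {iv.name for iv in jaccard_merge(all_peaks, filter2, min_jaccard)}
    names = hit1 & hit2 if mode == "and" else hit1 | hit2
    return PeakSet((iv for iv in all_peaks if iv.name in names), label=all_peaks.label)


def categorize_by_distance(
    ago2: PeakSet,
    sfpq: PeakSet,
    annotation: Sequence[TranscriptAnnotation],
    close_max_nt: int = 500,
    far_max_nt: int = 7000,
    reduced_names: set[str] | None = None,
) -> list[DependencyCall]:
    """Nearest-Sfpq distance, distance class and genomic category per
    Ago2 peak. Peaks with no same-chromosome Sfpq peak are very_far
    (virtually not bound)."""
    nd = nearest_distance(ago2, sfpq)
    reduced_names = reduced_names or set()
    calls = []
    for iv, (_name, dist, near) in zip(ago2, nd.itertuples(index=False)):
        calls.append(
            DependencyCall(
                ago2_peak=iv,
                nearest_sfpq=near,
                distance=dist,
                distance_category=categorize_distance(dist, close_max_nt, far_max_nt),
                genomic_category=assign_genomic_category(iv, annotation),
                reduced_on_knockdown=iv.name in reduced_names,
            )
        )
    return calls


def calls_to_dataframe(calls: Sequence[DependencyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [c.ago2_peak.name for c in calls],
            "chrom": [c.ago2_peak.chrom for c in calls],
            "start": [c.ago2_peak.start for c in calls],
            "end": [c.ago2_peak.end for c in calls],
            "nearest_sfpq": [c.nearest_sfpq for c in calls],
            "distance": [c.distance for c in calls],
            "distance_category": [c.distance_category.value for c in calls],
            "genomic_category": [c.genomic_category for c in calls],
            "reduced_on_knockdown": [c.reduced_on_knockdown for c in calls],
        }
    )


def category_enrichment_test(
    calls: Sequence[DependencyCall], region: str = "UTR3"
) -> dict[str, float]:
    """Two-sided Fisher exact tests of in-region membership, close vs far
    and close vs very_far."""
    groups = {"close": [], "far": [], "very_far": []}
    for c in calls:
        groups[c.distance_category.value].append(c.genomic_category == region)
    out = {}
    for other in ("far", "very_far"):
        if not groups["close"]:
            raise ValueError("empty distance class: close")
        if not groups[other]:
            raise ValueError(f"empty distance class: {other}")
        a_in = sum(groups["close"])
        b_in = sum(groups[other])
        table = [
            [a_in, len(groups["close"]) - a_in],
            [b_in, len(groups[other]) - b_in],
        ]
        out[f"p_close_vs_{other}"] = float(
            stats.fisher_exact(table, alternative="two-sided").pvalue
        )
    return out


def fraction_independent_close(
    calls: Sequence[DependencyCall], region: str = "UTR3"
) -> float:
    """Percentage of calls that are in-region and close to an Sfpq peak."""
    if not calls:
        raise ValueError("empty call list")
    n = sum(
        1
        for c in calls
        if c.genomic_category == region and c.distance_category.value == "close"
    )
    return 100.0 * n / len(calls)


def find_host_utrs(
    peaks: PeakSet,
    annotation: Sequence[TranscriptAnnotation],
    category: str = "UTR3",
) -> dict[str, tuple[str, GenomicInterval]]:
    """Map each peak name to (transcript_id, host feature interval) for the
    feature fully containing it. Raises when a peak has no host or exceeds
    every candidate host's length."""
    unhosted: list[str] = []
    too_long: list[str] = []
    out: dict[str, tuple[str, GenomicInterval]] = {}
    for iv in peaks:
        found = False
        saw_overlap = False
        for tx in annotation:
            if tx.chrom != iv.chrom:
                continue
            for feat in tx.feature_list(category):
                if iv.start >= feat.start and iv.end <= feat.end:
                    out[iv.name] = (tx.transcript_id, feat)
                    found = True
                    break
                if iv.overlaps(feat):
                    saw_overlap = True
            if found:
                break
        if not found:
            (too_long if saw_overlap else unhosted).append(iv.name)
    if too_long:
        raise ValueError(
            f"peaks overlap a {category} feature but do not fit inside it: "
            + ", ".join(too_long)
        )
    if unhosted:
        raise ValueError(
            f"peaks without a host {category} feature: " + ", ".join(unhosted)
        )
    return out


def _binned_counts(distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
    finite = distances[np.isfinite(distances)]
    counts, _ = np.histogram(finite, bins=edges)
    return counts


@dataclass
class ShuffleTestResult:
    """Observed vs permutation-null count of peaks in one distance bin."""

    bin_lo: int
    bin_hi: int
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int
    seed: int


class ShuffleTest:
    """Binned shuffle Z-score test of short-range Sfpq -> Ago2 dependency.

    Distances between the reduced Ago2 peaks and their nearest Sfpq peak are
    binned (default 250-nt bins over 0-1000 nt, half-open). The null
    re-places each reduced peak uniformly at random within its host 3'UTR,
    preserving peak length and leaving Sfpq fixed, ``n_shuffles`` times.
    """

    def __init__(
        self,
        reduced_ago2: PeakSet,
        sfpq: PeakSet,
        annotation: Sequence[TranscriptAnnotation],
        bin_width: int = 250,
        max_dist: int = 1000,
        n_shuffles: int = 10000,
        seed: int = 0,
    ):
        if n_shuffles <= 0:
            raise ValueError("n_shuffles must be > 0")
        if max_dist % bin_width != 0:
            raise ValueError("max_dist must be a multiple of bin_width")
        self.reduced_ago2 = reduced_ago2
        self.sfpq = sfpq
        self.annotation = annotation
        self.bin_width = bin_width
        self.max_dist = max_dist
        self.n_shuffles = n_shuffles
        self.seed = seed

    def fit(self) -> "ShuffleTestResults":
        hosts = find_host_utrs(self.reduced_ago2, self.annotation)
        edges = np.arange(0, self.max_dist + self.bin_width, self.bin_width)
        sfpq_by_chrom = self.sfpq.by_chrom()
        rng = np.random.default_rng(self.seed)

        def nearest(starts: np.ndarray, length: int, chrom: str) -> np.ndarray:
            """Vectorized nearest-Sfpq edge gap for candidate placements."""
            if chrom not in sfpq_by_chrom:
                return np.full(starts.shape, np.inf)
            s, e, _ = sfpq_by_chrom[chrom]
            ends = starts + length
            gaps = np.maximum(
                s[None, :] - ends[:, None], starts[:, None] - e[None, :]
            )
            return np.maximum(gaps, 0).min(axis=1)

        n_bins = len(edges) - 1
        observed = np.zeros(n_bins, dtype=int)
        null = np.zeros((self.n_shuffles, n_bins), dtype=int)
        # iterate peaks in sorted-name order so the draw sequence does not
        # depend on input ordering
        for iv in sorted(self.reduced_ago2, key=lambda p: p.name):
            _tx, utr = hosts[iv.name]
            observed += _binned_counts(
                nearest(np.array([iv.start]), iv.length, iv.chrom), edges
            )
            lo, hi = utr.start, utr.end - iv.length
            starts = rng.integers(lo, hi + 1, size=self.n_shuffles)
            d = nearest(starts, iv.length, iv.chrom)
            with np.errstate(invalid="ignore"):
                idx = np.floor_divide(d, self.bin_width).astype(
                    int, casting="unsafe"
                )
            valid = np.isfinite(d) & (d < self.max_dist)
            np.add.at(null, (np.nonzero(valid)[0], idx[valid]), 1)
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
        results = [
            ShuffleTestResult(
                bin_lo=int(edges[i]),
                bin_hi=int(edges[i + 1]),
                observed=int(observed[i]),
                null_mean=float(null_mean[i]),
                null_sd=float(null_sd[i]),
                z=float(z[i]),
                n_shuffles=self.n_shuffles,
                seed=self.seed,
            )
            for i in range(len(edges) - 1)
        ]
        return ShuffleTestResults(self, results)


class ShuffleTestResults:
    def __init__(self, model: ShuffleTest, bins: list[ShuffleTestResult]):
        self.model = model
        self.bins = bins

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.bins])

    def summary(self) -> str:
        lines = [
            "Shuffle Z-score test (Sfpq fixed, reduced Ago2 re-placed in host 3'UTRs)",
            f"n_shuffles = {self.model.n_shuffles}, seed = {self.model.seed}",
            f"{'bin':>12} {'observed':>9} {'null_mean':>10} {'null_sd':>8} {'Z':>7}",
        ]
        for b in self.bins:
            lines.append(
                f"[{b.bin_lo:>4},{b.bin_hi:>5}) {b.observed:>9} "
                f"{b.null_mean:>10.2f} {b.null_sd:>8.2f} {b.z:>7.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        df = self.to_dataframe()
        centers = (df["bin_lo"] + df["bin_hi"]) / 2
        ax.bar(centers, df["z"], width=0.8 * self.model.bin_width, color="steelblue")
        ax.axhline(1.96, color="red", ls="--", lw=1)
        ax.set_xlabel("distance to nearest Sfpq peak (nt)")
        ax.set_ylabel("Z score")
        return ax


def recruitment_spatial_correlation(
    reduced: PeakSet,
    recruited: PeakSet,
    annotation: Sequence[TranscriptAnnotation],
    bin_width: int = 250,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Where do newly recruited Ago2 peaks land relative to the reduced
    (Sfpq-dependent) ones, on shared 3'UTRs?

    Per distance bin: the percentage of recruited peaks whose nearest
    same-UTR reduced peak is that far away, with a flag {above, below,
    within} against the central 1 - alpha interval of a permutation null
    (recruited peaks re-placed uniformly within their host UTR).
    Percentages across bins sum to 100.
    """
    red_hosts = find_host_utrs(reduced, annotation)
    rec_hosts = find_host_utrs(recruited, annotation)
    red_tx = {tx for tx, _ in red_hosts.values()}
    shared = [iv for iv in recruited if rec_hosts[iv.name][0] in red_tx]
    if not shared:
        raise ValueError("no 3'UTRs shared between reduced and recruited sets")
    red_by_tx: dict[str, list[GenomicInterval]] = {}
    for iv in reduced:
        red_by_tx.setdefault(red_hosts[iv.name][0], []).append(iv)

    max_len = max(utr.length for _tx, utr in rec_hosts.values())
    edges = np.arange(0, max_len + 2 * bin_width, bin_width)

    def dist_to_reduced(start: np.ndarray, length: int, refs) -> np.ndarray:
        s = np.array([r.start for r in refs])
        e = np.array([r.end for r in refs])
        ends = start + length
        gaps = np.maximum(s[None, :] - ends[:, None], start[:, None] - e[None, :])
        return np.maximum(gaps, 0).min(axis=1)

    rng = np.random.default_rng(seed)
    obs = np.zeros(len(edges) - 1)
    null = np.zeros((n_perm, len(edges) - 1))
    for iv in sorted(shared, key=lambda p: p.name):
        tx, utr = rec_hosts[iv.name]
        refs = red_by_tx[tx]
        obs += _binned_counts(dist_to_reduced(np.array([iv.start]), iv.length, refs), edges)
        starts = rng.integers(utr.start, utr.end - iv.length + 1, size=n_perm)
        d = dist_to_reduced(starts, iv.length, refs)
        idx = np.floor_divide(d, bin_width).astype(int)
        valid = idx < null.shape[1]
        np.add.at(null, (np.nonzero(valid)[0], idx[valid]), 1)
    obs_pct = 100 * obs / obs.sum()
    null_pct = 100 * null / null.sum(axis=1, keepdims=True)
    lo = np.quantile(null_pct, alpha / 2, axis=0)
    hi = np.quantile(null_pct, 1 - alpha / 2, axis=0)
    flag = np.where(obs_pct > hi, "above", np.where(obs_pct < lo, "below", "within"))
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "pct_recruited": obs_pct,
            "null_lo": lo,
            "null_hi": hi,
            "flag": flag,
        }
    )


def peak_geometry_summary(
    peaks: PeakSet, annotation: Sequence[TranscriptAnnotation]
) -> pd.DataFrame:
    """Per genomic category: median/IQR of peak lengths and of
    same-category nearest-neighbour distances (NaN when < 2 peaks)."""
    by_cat: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        by_cat.setdefault(assign_genomic_category(iv, annotation), []).append(iv)
    rows = []
    for cat, ivs in sorted(by_cat.items()):
        lengths = np.array([iv.length for iv in ivs], dtype=float)
        if len(ivs) >= 2:
            sub = PeakSet(ivs, label=cat)
            nn = []
            for i, iv in enumerate(sub):
                others = PeakSet(
                    [o for j, o in enumerate(sub) if j != i], label="others"
                )
                nn.append(nearest_distance(PeakSet([iv]), others)["distance"][0])
            nn = np.array(nn, dtype=float)
            nn = nn[np.isfinite(nn)]
        else:
            nn = np.array([])
        rows.append(
            {
                "category": cat,
                "n": len(ivs),
                "length_median": float(np.median(lengths)),
                "length_iqr": float(
                    np.percentile(lengths, 75) - np.percentile(lengths, 25)
                ),
                "neighbor_median": float(np.median(nn)) if nn.size else math.nan,
                "neighbor_iqr": (
                    float(np.percentile(nn, 75) - np.percentile(nn, 25))
                    if nn.size
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def utr_length_comparison(
    utrs_all: Sequence[float],
    utrs_with_sfpq: Sequence[float],
    utrs_with_dependency: Sequence[float],
) -> dict[str, float]:
    """One-sided Wilcoxon rank-sum tests: occupied 3'UTRs longer than the
    full set, and dependency-bearing 3'UTRs longer than the occupied set."""
    for name, grp in (
        ("all", utrs_all),
        ("with_sfpq", utrs_with_sfpq),
        ("with_dependency", utrs_with_dependency),
    ):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} too small (need >= 2 lengths)")
    p_occ = stats.mannwhitneyu(
        utrs_with_sfpq, utrs_all, alternative="greater"
    ).pvalue
    p_dep = stats.mannwhitneyu(
        utrs_with_dependency, utrs_with_sfpq, alternative="greater"
    ).pvalue
    return {
        "p_occupied_vs_all": float(p_occ),
        "p_dependency_vs_occupied": float(p_dep),
    }
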