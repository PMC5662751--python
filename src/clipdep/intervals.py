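"""Strand-aware genomic intervals and the geometry primitives shared by all stages.

Coordinates are 0-based half-open throughout (BED native). Distances between
intervals are edge-to-edge gaps: 0 when two intervals overlap or abut with no
intervening base, otherwise the number of bases strictly between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "TranscriptAnnotation",
    "DistanceCategory",
    "CATEGORY_PRECEDENCE",
    "interval_jaccard",
    "interval_distance",
    "nearest_distance",
    "jaccard_merge",
    "filter_by_score",
    "assign_genomic_category",
    "categorize_distance",
]

#: Precedence used when a peak overlaps several annotated feature classes.
CATEGORY_PRECEDENCE = ("UTR3", "UTR5", "CDS", "intron", "TTS", "promoter", "ncRNA")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome strand, with an
    optional peak-caller score (e.g. a dCLIP differential-binding score)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start (got [{self.start}, {self.end}))"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")
        if self.score is not None and not math.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Jaccard index |a n b| / |a u b| on genomic bases; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = (a.length + b.length) - inter
    return inter / union


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge gap in nt; 0 when overlapping; inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start >= b.end:
        return a.start - b.end
    if b.start >= a.end:
        return b.start - a.end
    return 0.0


class PeakSet:
    """An ordered, labelled collection of peaks, kept sorted by
    (chrom, start, end, name) with unique names within the set."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
        named = []
        seen: set[str] = set()
        for i, iv in enumerate(ivs):
            name = iv.name or f"{label or 'peak'}_{i}"
            if name in seen:
                raise ValueError(f"duplicate peak name {name!r} in set {label!r}")
            seen.add(name)
            named.append(replace(iv, name=name))
        self.intervals: tuple[GenomicInterval, ...] = tuple(named)
        self.label = label
        self._by_chrom_cache: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Mapping[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """Per-chromosome (starts, ends, indices-into-self) arrays."""
        if self._by_chrom_cache is None:
            out: dict[str, tuple[list, list, list]] = {}
            for i, iv in enumerate(self.intervals):
                out.setdefault(iv.chrom, ([], [], []))
                s, e, idx = out[iv.chrom]
                s.append(iv.start)
                e.append(iv.end)
                idx.append(i)
            self._by_chrom_cache = {
                c: (np.asarray(s), np.asarray(e), idx) for c, (s, e, idx) in out.items()
            }
        return self._by_chrom_cache

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    def subset(self, names: Iterable[str], label: str | None = None) -> "PeakSet":
        wanted = set(names)
        return PeakSet(
            (iv for iv in self.intervals if iv.name in wanted),
            label=label if label is not None else self.label,
        )

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"


@dataclass
class TranscriptAnnotation:
    """Per-transcript feature map: category -> disjoint intervals on one chrom."""

    transcript_id: str
    chrom: str
    strand: str
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        for cat, ivs in self.features.items():
            for iv in ivs:
                if iv.chrom != self.chrom:
                    raise ValueError(
                        f"{self.transcript_id}: {cat} feature on {iv.chrom}, "
                        f"transcript on {self.chrom}"
                    )
            ordered = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ordered, ordered[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"{self.transcript_id}: overlapping {cat} features"
                    )

    def feature_list(self, category: str) -> list[GenomicInterval]:
        return self.features.get(category, [])


@dataclass(frozen=True)
class DistanceCategory:
    """Three-way distance class: close (d < close_max), far
    (close_max <= d < far_max), very_far (d >= far_max, including the
    no-reference-on-chromosome sentinel)."""

    value: str
    close_max_nt: int = 500
    far_max_nt: int = 7000

    def __post_init__(self) -> None:
        if self.value not in {"close", "far", "very_far"}:
            raise ValueError(f"unknown distance category {self.value!r}")


def categorize_distance(
    distance: float, close_max_nt: int = 500, far_max_nt: int = 7000
) -> DistanceCategory:
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance < close_max_nt:
        value = "close"
    elif distance < far_max_nt:
        value = "far"
    else:
        value = "very_far"
    return DistanceCategory(value, close_max_nt, far_max_nt)


def filter_by_score(peaks: PeakSet, min_score: float = 7.0) -> PeakSet:
    """Keep peaks with score >= min_score (boundary included)."""
    for iv in peaks:
        if iv.score is None:
            raise ValueError(f"peak {iv.name!r} has no score; cannot score-filter")
    return PeakSet(
        (iv for iv in peaks if iv.score >= min_score), label=peaks.label
    )


def _strand_compatible(peak_strand: str, feature_strand: str) -> bool:
    if peak_strand == "." or feature_strand == ".":
        return True
    return peak_strand == feature_strand


def assign_genomic_category(
    peak: GenomicInterval,
    annotation: Sequence[TranscriptAnnotation],
    precedence: Sequence[str] = CATEGORY_PRECEDENCE,
) -> str:
    """Assign a single genomic category to a peak.

    A peak overlapping features of several classes resolves by the fixed
    precedence (3'UTR first); no overlap anywhere yields "intergenic".
    Strand is honoured when both the peak and the transcript are stranded.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    for category in precedence:
        for tx in annotation:
            if tx.chrom != peak.chrom:
                continue
            if not _strand_compatible(peak.strand, tx.strand):
                continue
            for feat in tx.feature_list(category):
                if peak.overlaps(feat):
                    return category
    return "intergenic"


def nearest_distance(
    query: PeakSet, reference: PeakSet
) -> pd.DataFrame:
    """Per-query-peak edge-gap distance to the nearest same-chromosome
    reference peak.

    Returns a DataFrame indexed like ``query`` with columns ``name``,
    ``distance`` (inf when no reference shares the chromosome) and
    ``nearest`` (reference name, or None). Ties resolve to the reference
    with the smallest start, then lexicographically smallest name.
    """
    ref_by_chrom = reference.by_chrom()
    names, dists, nearest = [], [], []
    for iv in query:
        names.append(iv.name)
        if iv.chrom not in ref_by_chrom:
            dists.append(math.inf)
            nearest.append(None)
            continue
        starts, ends, idx = ref_by_chrom[iv.chrom]
        gaps = np.maximum(starts - iv.end, iv.start - ends)
        gaps = np.maximum(gaps, 0)
        # reference sets are sorted by (start, end, name): argmin's first
        # occurrence realises the smallest-start-then-name tie-break
        k = int(np.argmin(gaps))
        dists.append(float(gaps[k]))
        nearest.append(reference[idx[k]].name)
    return pd.DataFrame({"name": names, "distance": dists, "nearest": nearest})


def jaccard_merge(
    set_a: PeakSet, set_b: PeakSet, min_jaccard: float = 0.10
) -> PeakSet:
    """Subset of ``set_a`` whose best per-peak Jaccard against any peak of
    ``set_b`` reaches ``min_jaccard``; each A peak reported at most once."""
    b_by_chrom = set_b.by_chrom()
    kept = []
    for iv in set_a:
        if iv.chrom not in b_by_chrom:
            continue
        starts, ends, _ = b_by_chrom[iv.chrom]
        inter = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        mask = inter > 0
        if not mask.any():
            continue
        union = (ends - starts) + iv.length - inter
        if float(np.max(inter[mask] / union[mask])) >= min_jaccard:
            kept.append(iv)
    return PeakSet(kept, label=set_a.label)
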