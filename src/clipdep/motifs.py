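"""Exact-word motif scanning and miRNA seed-site search on RNA sequences.

Two Sfpq-binding motifs are realized as explicit word lists: a 4-mer motif
{CUGU, CUGA} and a 5-mer motif {CUGUA, AUGUA, UUGUA, GUGUA}. Occurrence
counting is non-overlapping by a greedy left-to-right rule (ties at the
same start resolved toward the longer word), which for these word sets
attains the maximum-disjoint-hits optimum.

A canonical miRNA seed site is the exact reverse complement of miRNA
nucleotides 2-7 (e.g. UACCUC for let-7a).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MotifSet",
    "MotifHit",
    "SeedSite",
    "MOTIF1",
    "MOTIF2",
    "canonicalize_rna",
    "reverse_complement",
    "scan_words",
    "seed_scan",
    "seed_match",
    "motif_enrichment_test",
    "occurrence_length_correlation",
    "count_sites_in_sequence",
]

_RNA_ALPHABET = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


@dataclass(frozen=True)
class MotifSet:
    name: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"motif {self.name!r}: empty word list")
        for w in self.words:
            if not w or set(w) - {"A", "C", "G", "U"}:
                raise ValueError(f"motif {self.name!r}: invalid word {w!r}")


MOTIF1 = MotifSet("motif1", ("CUGU", "CUGA"))
MOTIF2 = MotifSet("motif2", ("CUGUA", "AUGUA", "UUGUA", "GUGUA"))


@dataclass(frozen=True)
class MotifHit:
    word: str
    position: int  # 0-based offset
    motif_name: str


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    seed_match: str
    position: int


def canonicalize_rna(sequence: str) -> str:
    """Uppercase RNA spelling (T -> U)."""
    return sequence.upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    seq = canonicalize_rna(sequence)
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(sequence: str) -> None:
    for i, c in enumerate(sequence):
        if c not in _RNA_ALPHABET:
            raise ValueError(f"invalid RNA character {c!r} at position {i}")


def _all_hits(sequence: str, motifs: Sequence[MotifSet]) -> list[MotifHit]:
    """Every exact occurrence of every word, sorted by (start, -len)."""
    hits = []
    for motif in motifs:
        for word in motif.words:
            start = sequence.find(word)
            while start != -1:
                hits.append(MotifHit(word, start, motif.name))
                start = sequence.find(word, start + 1)
    hits.sort(key=lambda h: (h.position, -len(h.word), h.word))
    return hits


def scan_words(
    sequence: str, motif: MotifSet | Sequence[MotifSet], non_overlapping: bool = True
) -> list[MotifHit]:
    """Exact-word scan of an RNA sequence.

    With ``non_overlapping`` (default), hits are selected greedily left to
    right so every retained hit is disjoint from the previously retained
    one; at equal starts the longer word wins (a CUGUA counts once, never
    also as its CUGU prefix). N matches nothing.
    """
    seq = canonicalize_rna(sequence)
    _validate(seq)
    motifs = [motif] if isinstance(motif, MotifSet) else list(motif)
    hits = _all_hits(seq, motifs)
    if not non_overlapping:
        return hits
    kept: list[MotifHit] = []
    cursor = 0
    for h in hits:
        if h.position >= cursor:
            kept.append(h)
            cursor = h.position + len(h.word)
    return kept


def count_sites_in_sequence(
    sequence: str, motifs: Sequence[MotifSet] = (MOTIF1, MOTIF2)
) -> int:
    """Total non-overlapping site count scanning all motif sets jointly,
    with the same greedy rule applied across motif boundaries."""
    return len(scan_words(sequence, motifs, non_overlapping=True))


def seed_match(mirna_sequence: str) -> str:
    """Canonical site sequence: reverse complement of miRNA nt 2-7."""
    mir = canonicalize_rna(mirna_sequence)
    _validate(mir)
    if len(mir) < 7:
        raise ValueError("miRNA sequence must be >= 7 nt to define a seed")
    return reverse_complement(mir[1:7])


def seed_scan(
    sequence: str, mirna_sequence: str, mirna_id: str = ""
) -> list[SeedSite]:
    """All (possibly overlapping) occurrences of the canonical seed site."""
    seq = canonicalize_rna(sequence)
    _validate(seq)
    site = seed_match(mirna_sequence)
    out = []
    start = seq.find(site)
    while start != -1:
        out.append(SeedSite(mirna_id, site, start))
        start = seq.find(site, start + 1)
    return out


def motif_enrichment_test(
    sequences_fg: Sequence[str],
    sequences_bg: Sequence[str],
    motif: MotifSet | Sequence[MotifSet],
) -> tuple[float, float]:
    """Two-sided Fisher exact test of motif presence (>= 1 non-overlapping
    hit) in foreground vs background sequences.

    Returns (p_value, odds_ratio); the odds ratio is +inf when a zero cell
    makes it unbounded.
    """
    if not sequences_fg or not sequences_bg:
        raise ValueError("both sequence groups must be non-empty")
    fg_hit = sum(bool(scan_words(s, motif)) for s in sequences_fg)
    bg_hit = sum(bool(scan_words(s, motif)) for s in sequences_bg)
    table = [
        [fg_hit, len(sequences_fg) - fg_hit],
        [bg_hit, len(sequences_bg) - bg_hit],
    ]
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = res.statistic
    if table[0][1] * table[1][0] == 0 and table[0][0] * table[1][1] > 0:
        odds = float("inf")
    return float(res.pvalue), float(odds)


def occurrence_length_correlation(
    sequences: Sequence[str], motif: MotifSet | Sequence[MotifSet]
) -> tuple[float, float]:
    """(Spearman rho, Pearson r) between the non-overlapping occurrence
    count and the sequence length across peaks."""
    if len(sequences) < 3:
        raise ValueError("need >= 3 sequences")
    counts = np.array([len(scan_words(s, motif)) for s in sequences], dtype=float)
    lengths = np.array([len(s) for s in sequences], dtype=float)
    if counts.std() == 0 or lengths.std() == 0:
        raise ValueError("zero variance in counts or lengths")
    rho = stats.spearmanr(counts, lengths).statistic
    r = stats.pearsonr(counts, lengths).statistic
    return float(rho), float(r)
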