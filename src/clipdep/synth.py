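"""Synthetic data with the statistical structure each pipeline stage assumes.

The generator emulates, at desk scale, the data shapes of an
Sfpq/miRISC-style study: a transcriptome in which Sfpq-occupied 3'UTRs are
longer and motif-word-enriched; CLIP peak sets with a short-range (< 500 nt)
Sfpq -> Ago2 dependency planted for a known subset of peaks; a two-population
IP-MS abundance table ((+)RNase loss for RNA-dependent interactors); RIP
count tables whose log-enrichments follow a two-component Gaussian mixture;
and expression fold-change tables with a rescue planted only for directly
controlled transcripts. Every generator draws from its own RNG stream
(master seed + fixed offset) and emits a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, TranscriptAnnotation
from .motifs import MOTIF1, MOTIF2
from .rip import RipCountRecord
from .rnadep import IpmsRecord

__all__ = [
    "IpmsParams",
    "RipParams",
    "RescueParams",
    "SynthConfig",
    "Transcriptome",
    "PeakBundle",
    "RipBundle",
    "make_transcriptome",
    "make_peaks",
    "make_ipms_table",
    "make_rip_counts",
    "make_expression",
    "derive_transcript_groups",
]

_ALL_WORDS = MOTIF1.words + MOTIF2.words
_SEED_SITE = "UACCUC"  # reverse complement of the let-7a seed (nt 2-7)

# fixed RNG stream offsets per generator, so regenerating one table does
# not perturb the others
_STREAM_TRANSCRIPTOME = 11
_STREAM_PEAKS = 12
_STREAM_IPMS = 13
_STREAM_RIP = 14
_STREAM_EXPRESSION = 15


@dataclass
class IpmsParams:
    n_proteins: int = 300
    frac_dependent: float = 0.2
    effect_log2: float = 2.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    bait_id: str = "Ago2"


@dataclass
class RipParams:
    n_mirnas: int = 5000
    frac_enriched: float = 0.3
    mu0: float = 0.0
    mu1: float = 3.0
    sigma: float = 0.5
    nested_overlap: float = 0.85


@dataclass
class RescueParams:
    effect_log2: float = 0.5
    noise_sd: float = 0.2
    base_down: float = 1.0


@dataclass
class SynthConfig:
    seed: int = 0
    n_transcripts: int = 300
    utr3_log_mean: float = 7.4  # ln scale; median ~1600 nt
    utr3_log_sd: float = 0.5
    occupied_log_shift: float = 0.7  # occupied 3'UTRs drawn longer
    frac_occupied: float = 1 / 3
    n_sfpq_peaks: int = 800  # ~8 per occupied 3'UTR: dense, aggregate-like occupancy
    sfpq_len_log_mean: float = 4.1  # median ~60 nt
    sfpq_len_log_sd: float = 0.3
    n_ago2_peaks: int = 200
    ago2_peak_length: int = 50
    frac_direct: float = 0.3
    direct_distance_max: int = 500
    direct_gap_max: int = 200  # planted direct peaks sit 0-200 nt from Sfpq
    frac_independent_close: float = 0.1
    frac_canonical: float = 0.6
    n_low_score_peaks: int = 20
    motif_density_occupied_per_kb: float = 6.0
    motif_density_unoccupied_per_kb: float = 1.0
    ipms: IpmsParams = field(default_factory=IpmsParams)
    rip: RipParams = field(default_factory=RipParams)
    rescue: RescueParams = field(default_factory=RescueParams)

    def __post_init__(self) -> None:
        for name in (
            "frac_occupied",
            "frac_direct",
            "frac_independent_close",
            "frac_canonical",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_transcripts", "n_sfpq_peaks", "n_ago2_peaks",
                     "ago2_peak_length", "direct_distance_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ipms.frac_dependent <= 1:
            raise ValueError("ipms.frac_dependent must be in [0, 1]")
        if not 0 <= self.rip.frac_enriched <= 1:
            raise ValueError("rip.frac_enriched must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Transcriptome:
    annotation: list[TranscriptAnnotation]
    sequences: dict[str, str]  # 3'UTR sequences, transcript orientation
    meta: pd.DataFrame  # transcript_id, chrom, occupied, utr_start, utr_end


@dataclass
class PeakBundle:
    sfpq: PeakSet
    ago2_all: PeakSet
    ago2_filter1: PeakSet
    ago2_filter2: PeakSet
    truth: pd.DataFrame  # name, transcript_id, planted, reduced, has_seed, gap


@dataclass
class RipBundle:
    records: list[RipCountRecord]
    records_nested: list[RipCountRecord] | None
    truth: pd.DataFrame  # mirna_id, enriched, (enriched_nested,) log_enrichment


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGU"))


def _plant_words(
    rng: np.random.Generator, seq: np.ndarray, n_words: int, max_tries: int = 200
) -> None:
    """Overwrite random non-overlapping positions with motif words."""
    taken: list[tuple[int, int]] = []
    planted = 0
    tries = 0
    while planted < n_words and tries < max_tries * max(1, n_words):
        tries += 1
        word = _ALL_WORDS[rng.integers(0, len(_ALL_WORDS))]
        if len(seq) <= len(word):
            break
        pos = int(rng.integers(0, len(seq) - len(word)))
        if any(pos < e and pos + len(word) > s for s, e in taken):
            continue
        seq[pos : pos + len(word)] = [("ACGU").index(c) for c in word]
        taken.append((pos, pos + len(word)))
        planted += 1


def make_transcriptome(cfg: SynthConfig) -> Transcriptome:
    """Annotated transcripts laid out on one chromosome, 20 kb apart, all on
    the + strand; occupied 3'UTRs are longer and denser in motif words."""
    rng = np.random.default_rng(cfg.seed + _STREAM_TRANSCRIPTOME)
    annotation: list[TranscriptAnnotation] = []
    sequences: dict[str, str] = {}
    meta_rows = []
    cursor = 1000
    chrom = "chr1"
    n_occupied = int(round(cfg.frac_occupied * cfg.n_transcripts))
    occupied_flags = np.zeros(cfg.n_transcripts, dtype=bool)
    occupied_flags[
        rng.choice(cfg.n_transcripts, size=n_occupied, replace=False)
    ] = True
    for i in range(cfg.n_transcripts):
        tx_id = f"tx_{i:04d}"
        occupied = bool(occupied_flags[i])
        mu = cfg.utr3_log_mean + (cfg.occupied_log_shift if occupied else 0.0)
        utr_len = int(rng.lognormal(mu, cfg.utr3_log_sd))
        utr_len = max(utr_len, 1500 if occupied else 400)
        promoter = GenomicInterval(chrom, cursor, cursor + 500, "+")
        utr5 = GenomicInterval(chrom, cursor + 500, cursor + 700, "+")
        cds1 = GenomicInterval(chrom, cursor + 700, cursor + 1100, "+")
        intron = GenomicInterval(chrom, cursor + 1100, cursor + 1600, "+")
        cds2 = GenomicInterval(chrom, cursor + 1600, cursor + 2100, "+")
        utr3 = GenomicInterval(chrom, cursor + 2100, cursor + 2100 + utr_len, "+")
        tts = GenomicInterval(chrom, utr3.end, utr3.end + 200, "+")
        annotation.append(
            TranscriptAnnotation(
                tx_id,
                chrom,
                "+",
                {
                    "promoter": [promoter],
                    "UTR5": [utr5],
                    "CDS": [cds1, cds2],
                    "intron": [intron],
                    "UTR3": [utr3],
                    "TTS": [tts],
                },
            )
        )
        seq = _random_seq(rng, utr_len)
        density = (
            cfg.motif_density_occupied_per_kb
            if occupied
            else cfg.motif_density_unoccupied_per_kb
        )
        _plant_words(rng, seq, int(round(density * utr_len / 1000)))
        sequences[tx_id] = "".join(_BASES[seq])
        meta_rows.append(
            {
                "transcript_id": tx_id,
                "chrom": chrom,
                "occupied": occupied,
                "utr_start": utr3.start,
                "utr_end": utr3.end,
            }
        )
        cursor = tts.end + 20000
    return Transcriptome(annotation, sequences, pd.DataFrame(meta_rows))


def _place_in_utr(
    rng: np.random.Generator, utr_start: int, utr_end: int, length: int
) -> int:
    return int(rng.integers(utr_start, utr_end - length + 1))


def make_peaks(cfg: SynthConfig, transcriptome: Transcriptome) -> PeakBundle:
    """Plant Sfpq peaks in occupied 3'UTRs and Ago2 peaks with a known
    dependency structure; the knockdown filter sets are built so the
    dual-filter merge recovers exactly the planted direct peaks.

    Canonical seed sites (reverse complement of the let-7a seed) are written
    into the 3'UTR sequence inside a ``frac_canonical`` subset of the direct
    peaks (sequences are updated in place).
    """
    rng = np.random.default_rng(cfg.seed + _STREAM_PEAKS)
    meta = transcriptome.meta
    occ = meta[meta["occupied"]].reset_index(drop=True)
    if occ.empty:
        raise ValueError("no occupied transcripts to host Sfpq peaks")

    # --- Sfpq peaks, cycled over occupied 3'UTRs -------------------------
    sfpq_ivs: list[GenomicInterval] = []
    sfpq_by_tx: dict[str, list[GenomicInterval]] = {}
    for j in range(cfg.n_sfpq_peaks):
        row = occ.iloc[j % len(occ)]
        length = int(
            np.clip(
                rng.lognormal(cfg.sfpq_len_log_mean, cfg.sfpq_len_log_sd),
                20,
                (row.utr_end - row.utr_start) // 3,
            )
        )
        start = _place_in_utr(rng, row.utr_start, row.utr_end, length)
        iv = GenomicInterval(
            row.chrom, start, start + length, "+",
            score=float(rng.uniform(8, 50)), name=f"sfpq_{j:04d}",
        )
        sfpq_ivs.append(iv)
        sfpq_by_tx.setdefault(row.transcript_id, []).append(iv)
    sfpq = PeakSet(sfpq_ivs, label="Sfpq")

    # --- Ago2 peaks ------------------------------------------------------
    n_direct = int(round(cfg.frac_direct * cfg.n_ago2_peaks))
    n_indep_close = int(round(cfg.frac_independent_close * cfg.n_ago2_peaks))
    plen = cfg.ago2_peak_length
    ago2_ivs: list[GenomicInterval] = []
    truth_rows = []
    occ_ids = list(sfpq_by_tx)

    def place_near(tx_id: str, gap: int) -> int | None:
        """Start coordinate at the given edge gap from a random Sfpq peak
        of the transcript, inside the 3'UTR; None if it cannot fit."""
        row = meta[meta["transcript_id"] == tx_id].iloc[0]
        anchors = sfpq_by_tx[tx_id]
        anchor = anchors[int(rng.integers(0, len(anchors)))]
        sides = [1, -1] if rng.random() < 0.5 else [-1, 1]
        for side in sides:
            start = anchor.end + gap if side == 1 else anchor.start - gap - plen
            if start >= row.utr_start and start + plen <= row.utr_end:
                return start
        return None

    k = 0
    guard = 0
    while k < n_direct and guard < 100 * max(1, n_direct):
        guard += 1
        tx_id = occ_ids[int(rng.integers(0, len(occ_ids)))]
        gap = int(rng.integers(1, cfg.direct_gap_max))
        start = place_near(tx_id, gap)
        if start is None:
            continue
        name = f"ago2_{len(ago2_ivs):04d}"
        ago2_ivs.append(
            GenomicInterval(
                "chr1", start, start + plen, "+",
                score=float(rng.uniform(8, 50)), name=name,
            )
        )
        truth_rows.append(
            {"name": name, "transcript_id": tx_id, "planted": "direct",
             "reduced": True, "gap": gap}
        )
        k += 1
    if k < n_direct:
        raise ValueError("3'UTRs too short to host the requested direct peaks")

    k = 0
    guard = 0
    while k < n_indep_close and guard < 100 * max(1, n_indep_close):
        guard += 1
        tx_id = occ_ids[int(rng.integers(0, len(occ_ids)))]
        gap = int(rng.integers(1, cfg.direct_distance_max))
        start = place_near(tx_id, gap)
        if start is None:
            continue
        name = f"ago2_{len(ago2_ivs):04d}"
        ago2_ivs.append(
            GenomicInterval(
                "chr1", start, start + plen, "+",
                score=float(rng.uniform(8, 50)), name=name,
            )
        )
        truth_rows.append(
            {"name": name, "transcript_id": tx_id,
             "planted": "independent_close", "reduced": False, "gap": gap}
        )
        k += 1

    # remaining peaks: placed away from Sfpq (gap > 500 + margin), half in
    # 3'UTRs and half in CDS/intron/5'UTR so distance classes and genomic
    # categories both vary
    n_rest = cfg.n_ago2_peaks - n_direct - n_indep_close
    ann_by_tx = {tx.transcript_id: tx for tx in transcriptome.annotation}
    rest_done = 0
    guard = 0
    while rest_done < n_rest and guard < 200 * max(1, n_rest):
        guard += 1
        row = meta.iloc[int(rng.integers(0, len(meta)))]
        if rng.random() < 0.5:
            start = _place_in_utr(rng, row.utr_start, row.utr_end, plen)
        else:
            tx = ann_by_tx[row.transcript_id]
            cat = ("CDS", "intron", "UTR5")[int(rng.integers(0, 3))]
            feats = tx.feature_list(cat)
            feat = feats[int(rng.integers(0, len(feats)))]
            if feat.length <= plen:
                continue
            start = _place_in_utr(rng, feat.start, feat.end, plen)
        anchors = sfpq_by_tx.get(row.transcript_id, [])
        gaps = [
            max(a.start - (start + plen), start - a.end, 0) for a in anchors
        ]
        mind = min(gaps) if gaps else np.inf
        if mind < cfg.direct_distance_max + 100:  # keep a margin past 500
            continue
        name = f"ago2_{len(ago2_ivs):04d}"
        ago2_ivs.append(
            GenomicInterval(
                "chr1", start, start + plen, "+",
                score=float(rng.uniform(8, 50)), name=name,
            )
        )
        truth_rows.append(
            {"name": name, "transcript_id": row.transcript_id,
             "planted": "far" if np.isfinite(mind) and mind < 7000 else "very_far",
             "reduced": False, "gap": mind if np.isfinite(mind) else -1}
        )
        rest_done += 1

    # low-score decoys exercise the upstream score filter
    for j in range(cfg.n_low_score_peaks):
        row = meta.iloc[int(rng.integers(0, len(meta)))]
        start = _place_in_utr(rng, row.utr_start, row.utr_end, plen)
        name = f"ago2_low_{j:03d}"
        ago2_ivs.append(
            GenomicInterval(
                "chr1", start, start + plen, "+",
                score=float(rng.uniform(1, 6.9)), name=name,
            )
        )
        truth_rows.append(
            {"name": name, "transcript_id": row.transcript_id,
             "planted": "low_score", "reduced": False, "gap": -1}
        )

    truth = pd.DataFrame(truth_rows)

    # --- canonical seed sites inside a subset of direct peaks ------------
    direct_names = truth.loc[truth["planted"] == "direct", "name"].tolist()
    n_canon = int(round(cfg.frac_canonical * len(direct_names)))
    canonical = set(
        rng.choice(direct_names, size=n_canon, replace=False)
    ) if n_canon else set()
    by_name = {iv.name: iv for iv in ago2_ivs}
    tx_of = dict(zip(truth["name"], truth["transcript_id"]))
    for name in sorted(canonical):
        iv = by_name[name]
        row = meta[meta["transcript_id"] == tx_of[name]].iloc[0]
        rel = iv.start - row.utr_start + 10
        seq = transcriptome.sequences[tx_of[name]]
        transcriptome.sequences[tx_of[name]] = (
            seq[:rel] + _SEED_SITE + seq[rel + len(_SEED_SITE):]
        )
    truth["has_seed"] = truth["name"].isin(canonical)

    # --- knockdown filter sets: jittered copies of the direct peaks ------
    def jitter_set(tag: str) -> PeakSet:
        ivs = []
        for name in direct_names:
            iv = by_name[name]
            shift = int(rng.integers(-5, 6))
            ivs.append(
                GenomicInterval(
                    iv.chrom, max(0, iv.start + shift), iv.end + shift, "+",
                    score=float(rng.uniform(8, 50)), name=f"{tag}_{name}",
                )
            )
        return PeakSet(ivs, label=tag)

    return PeakBundle(
        sfpq=sfpq,
        ago2_all=PeakSet(ago2_ivs, label="Ago2-let-7a"),
        ago2_filter1=jitter_set("f1"),
        ago2_filter2=jitter_set("f2"),
        truth=truth,
    )


def make_ipms_table(cfg: SynthConfig) -> tuple[list[IpmsRecord], pd.DataFrame]:
    """Two-population IP-MS table: dependent proteins lose
    2^effect_log2 abundance on RNase digestion; the bait is unaffected."""
    p = cfg.ipms
    rng = np.random.default_rng(cfg.seed + _STREAM_IPMS)
    n_dep = int(round(p.frac_dependent * p.n_proteins))
    records = []
    truth_rows = []
    for i in range(p.n_proteins):
        pid = f"prot_{i:04d}"
        dependent = i < n_dep
        base = rng.lognormal(np.log(1e5), 1.0)
        minus = base * 2 ** rng.normal(0, p.noise_sd, size=p.n_replicates)
        scale = 2 ** (-p.effect_log2) if dependent else 1.0
        plus = base * scale * 2 ** rng.normal(0, p.noise_sd, size=p.n_replicates)
        control = base * 0.02 * 2 ** rng.normal(0, p.noise_sd, size=p.n_replicates)
        records.append(
            IpmsRecord(
                protein_id=pid,
                unique_peptides=int(1 + rng.poisson(8)),
                abundances_minus=list(np.round(minus, 2)),
                abundances_plus=list(np.round(plus, 2)),
                control_abundances=list(np.round(control, 2)),
            )
        )
        truth_rows.append({"protein_id": pid, "dependent": dependent})
    # the bait is the most abundant, best-measured protein; its replicate
    # CV sits at the bottom of the label-free noise range, which also keeps
    # the normalization anchor stable
    bait_sd = p.noise_sd / 3
    bait_base = rng.lognormal(np.log(5e6), 0.2)
    records.append(
        IpmsRecord(
            protein_id=p.bait_id,
            unique_peptides=40,
            abundances_minus=list(
                np.round(bait_base * 2 ** rng.normal(0, bait_sd, p.n_replicates), 2)
            ),
            abundances_plus=list(
                np.round(bait_base * 2 ** rng.normal(0, bait_sd, p.n_replicates), 2)
            ),
            control_abundances=list(
                np.round(bait_base * 0.02 * 2 ** rng.normal(0, bait_sd, p.n_replicates), 2)
            ),
        )
    )
    truth_rows.append({"protein_id": p.bait_id, "dependent": False})
    return records, pd.DataFrame(truth_rows)


def make_rip_counts(cfg: SynthConfig, nested: bool = False) -> RipBundle:
    """RIP count tables whose log2 IP/input enrichments follow the
    configured two-component mixture; in nested mode a second IP sample is
    generated whose planted enriched set is a subset of the first."""
    p = cfg.rip
    rng = np.random.default_rng(cfg.seed + _STREAM_RIP)
    enriched = rng.random(p.n_mirnas) < p.frac_enriched
    e = np.where(
        enriched,
        rng.normal(p.mu1, p.sigma, p.n_mirnas),
        rng.normal(p.mu0, p.sigma, p.n_mirnas),
    )
    input_reads = np.maximum(np.round(rng.lognormal(np.log(500), 0.8, p.n_mirnas)), 30)
    ip_reads = np.maximum(np.round(input_reads * 2.0**e), 0)
    ids = [f"mir_{i:04d}" for i in range(p.n_mirnas)]
    records = [
        RipCountRecord(i, float(a), float(b))
        for i, a, b in zip(ids, input_reads, ip_reads)
    ]
    truth = pd.DataFrame(
        {"mirna_id": ids, "enriched": enriched, "log_enrichment": e}
    )
    records_b = None
    if nested:
        enr_idx = np.nonzero(enriched)[0]
        keep = rng.choice(
            enr_idx, size=int(round(p.nested_overlap * enr_idx.size)), replace=False
        )
        enriched_b = np.zeros(p.n_mirnas, dtype=bool)
        enriched_b[keep] = True
        e_b = np.where(
            enriched_b,
            rng.normal(p.mu1, p.sigma, p.n_mirnas),
            rng.normal(p.mu0, p.sigma, p.n_mirnas),
        )
        ip_b = np.maximum(np.round(input_reads * 2.0**e_b), 0)
        records_b = [
            RipCountRecord(i, float(a), float(b))
            for i, a, b in zip(ids, input_reads, ip_b)
        ]
        truth["enriched_nested"] = enriched_b
    return RipBundle(records, records_b, truth)


def derive_transcript_groups(peak_truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-peak truth to a per-transcript group label, with
    the same precedence the rescue stage uses."""
    rows = []
    for tx_id, sub in peak_truth[peak_truth["planted"] != "low_score"].groupby(
        "transcript_id"
    ):
        direct = sub[(sub["planted"] == "direct")]
        if len(direct) and direct["has_seed"].any():
            group = "canonical_direct"
        elif len(direct):
            group = "direct_close"
        elif (sub["planted"] == "far").any():
            group = "far"
        elif (sub["planted"] == "very_far").any():
            group = "very_far"
        else:
            group = "independent"
        rows.append({"transcript_id": tx_id, "group": group})
    return pd.DataFrame(rows)


def make_expression(
    cfg: SynthConfig, transcript_groups: pd.DataFrame
) -> pd.DataFrame:
    """Expression log2 fold-changes: directly controlled transcripts are
    downregulated by base + effect under the miRNA and rescued back to base
    under Sfpq knockdown; all other groups show no rescue."""
    p = cfg.rescue
    rng = np.random.default_rng(cfg.seed + _STREAM_EXPRESSION)
    rows = []
    for r in transcript_groups.itertuples(index=False):
        rescued = r.group in {"canonical_direct", "direct_close"}
        if rescued:
            lfc = -(p.base_down + p.effect_log2) + rng.normal(0, p.noise_sd)
            lfc_kd = -p.base_down + rng.normal(0, p.noise_sd)
        else:
            lfc = -p.base_down + rng.normal(0, p.noise_sd)
            lfc_kd = -p.base_down + rng.normal(0, p.noise_sd)
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "lfc_mirna": lfc,
                "lfc_mirna_kd": lfc_kd,
                "true_group": r.group,
            }
        )
    return pd.DataFrame(rows)
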