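"""File I/O: BED6 peak tables, GFF3 feature annotation, FASTA sequences.

BED is consumed as-is (0-based half-open). GFF3 coordinates (1-based closed)
are converted to half-open on read and back on write. Feature types are
mapped to the genomic categories used throughout via Sequence Ontology
terms, with an optional attribute key override.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .intervals import GenomicInterval, PeakSet, TranscriptAnnotation

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "SO_CATEGORY_MAP",
]

#: Sequence Ontology / common feature-type spellings -> internal categories.
SO_CATEGORY_MAP: Mapping[str, str] = {
    "three_prime_utr": "UTR3",
    "3utr": "UTR3",
    "utr3": "UTR3",
    "five_prime_utr": "UTR5",
    "5utr": "UTR5",
    "utr5": "UTR5",
    "cds": "CDS",
    "intron": "intron",
    "tts": "TTS",
    "promoter": "promoter",
    "ncrna": "ncRNA",
    "ncrna_gene": "ncRNA",
}


class BedParseError(ValueError):
    pass


def read_peaks(path: str | Path, label: str = "") -> PeakSet:
    """Read a BED(6) file into a sorted PeakSet.

    Requires >= 3 columns per line; columns 4-6 (name, score, strand) are
    honoured when present. Malformed lines raise a BedParseError naming the
    line number; end <= start raises a validation error likewise.
    """
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            score = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score: {exc}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, score, name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(intervals, label=label or path.stem)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 (score '.' when absent)."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in peaks:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(
    path: str | Path,
    category_attribute: str | None = None,
    transcript_attribute: str = "Parent",
) -> list[TranscriptAnnotation]:
    """Read transcript feature maps from GFF3.

    The genomic category of each feature comes from the feature-type column
    via SO_CATEGORY_MAP, unless ``category_attribute`` names an attribute key
    carrying the category directly. Features are grouped into transcripts by
    ``transcript_attribute`` (falling back to ``ID``).
    """
    path = Path(path)
    grouped: dict[str, TranscriptAnnotation] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attr_text = fields
            attrs = _parse_gff_attributes(attr_text)
            if category_attribute is not None:
                category = attrs.get(category_attribute)
            else:
                category = SO_CATEGORY_MAP.get(ftype.lower())
            if category is None:
                continue
            tx_id = attrs.get(transcript_attribute) or attrs.get("ID")
            if tx_id is None:
                raise ValueError(
                    f"{path}:{lineno}: no {transcript_attribute!r} or ID attribute"
                )
            start = int(start1) - 1  # 1-based closed -> 0-based half-open
            end = int(end1)
            if tx_id not in grouped:
                grouped[tx_id] = TranscriptAnnotation(
                    transcript_id=tx_id,
                    chrom=chrom,
                    strand=strand if strand in {"+", "-"} else "+",
                    features={},
                )
            tx = grouped[tx_id]
            tx.features.setdefault(category, []).append(
                GenomicInterval(chrom, start, end, tx.strand)
            )
    # re-validate disjointness / sorting through the constructor
    return [
        TranscriptAnnotation(tx.transcript_id, tx.chrom, tx.strand, tx.features)
        for tx in grouped.values()
    ]


_CATEGORY_SO = {
    "UTR3": "three_prime_UTR",
    "UTR5": "five_prime_UTR",
    "CDS": "CDS",
    "intron": "intron",
    "TTS": "TTS",
    "promoter": "promoter",
    "ncRNA": "ncRNA",
}


def write_gff3(annotation: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for tx in annotation:
            for category, ivs in tx.features.items():
                ftype = _CATEGORY_SO.get(category, category)
                for iv in sorted(ivs, key=lambda x: x.start):
                    fh.write(
                        f"{tx.chrom}\tclipdep\t{ftype}\t{iv.start + 1}\t{iv.end}\t."
                        f"\t{tx.strand}\t.\tParent={tx.transcript_id}\n"
                    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase RNA sequence} (T canonicalised to U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
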