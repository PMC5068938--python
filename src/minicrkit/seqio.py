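"""Sequence and annotation I/O plus the basic nucleic-acid transformations.

Coordinates are 1-based inclusive internally and in GFF3/GenBank I/O; BED output is
0-based half-open.  Ambiguity codes are rejected by default; callers who opt in
(``allow_ambiguous=True``) get sequences whose ambiguous bases are treated as
never-pairing by the pairing layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AmbiguityError,
    CoordinateError,
    DuplicateIdError,
    EmptyInputError,
    SequenceAlphabetError,
)

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")
#: IUPAC ambiguity codes accepted when ambiguity is explicitly allowed.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")


def _check_alphabet(seq: str, *, label: str = "?", allow_ambiguous: bool = False) -> str:
    """Return 'DNA' or 'RNA' for *seq*, raising on bad characters.

    A sequence with neither T nor U is called DNA unless the caller overrides.
    """
    if not seq:
        raise EmptyInputError(f"sequence {label!r} is empty")
    has_t = "T" in seq
    has_u = "U" in seq
    if has_t and has_u:
        raise SequenceAlphabetError(f"sequence {label!r} mixes T and U")
    moltype = "RNA" if has_u else "DNA"
    alphabet = RNA_BASES if moltype == "RNA" else DNA_BASES
    for pos, ch in enumerate(seq, start=1):
        if ch in alphabet:
            continue
        if ch in AMBIGUITY_CODES:
            if allow_ambiguous:
                continue
            raise AmbiguityError(
                f"ambiguity code {ch!r} at position {pos} of sequence {label!r}"
            )
        raise SequenceAlphabetError(
            f"invalid character {ch!r} at position {pos} of sequence {label!r}"
        )
    return moltype


@dataclass
class NucSeq:
    """A validated nucleotide sequence (DNA or RNA, linear or circular)."""

    id: str
    seq: str
    topology: str = "linear"
    moltype: str = field(default="")
    allow_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        inferred = _check_alphabet(self.seq, label=self.id, allow_ambiguous=self.allow_ambiguous)
        if not self.moltype:
            self.moltype = inferred
        elif self.moltype == "RNA" and "T" in self.seq:
            raise SequenceAlphabetError(f"sequence {self.id!r} declared RNA but contains T")
        elif self.moltype == "DNA" and "U" in self.seq:
            raise SequenceAlphabetError(f"sequence {self.id!r} declared DNA but contains U")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CdsFeature:
    """A CDS feature as read from an annotation: one or more genomic segments."""

    locus_tag: str
    segments: list[tuple[int, int]]  # 1-based inclusive, in transcription order
    strand: str

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)


@dataclass
class CdsRecord:
    """A CDS with its sense-strand mRNA sequence."""

    locus_tag: str
    parent_genome: str
    start: int
    end: int
    strand: str
    mrna_seq: str  # RNA, sense (mRNA) orientation


def revcomp(seq: str, moltype: str | None = None) -> str:
    """Antiparallel complement, preserving the alphabet (DNA in, DNA out; RNA in, RNA out).

    A string with neither T nor U is treated as DNA unless *moltype* says "RNA".
    """
    inferred = _check_alphabet(seq)
    if moltype is None:
        moltype = inferred
    elif inferred != moltype and ("T" in seq or "U" in seq):
        raise SequenceAlphabetError(f"sequence is {inferred}, not {moltype}")
    if moltype == "RNA":
        return str(Seq(seq).reverse_complement_rna())
    return str(Seq(seq).reverse_complement())


def transcribe(dna_sense: str) -> str:
    """Transcribe a sense-strand DNA string to RNA (T→U)."""
    if _check_alphabet(dna_sense) == "RNA":
        raise SequenceAlphabetError("input is already RNA")
    return dna_sense.replace("T", "U")


def back_transcribe(rna: str) -> str:
    """Inverse of :func:`transcribe` (U→T); rejects input that is already DNA."""
    if "T" in rna:
        raise SequenceAlphabetError("input is already DNA")
    _check_alphabet(rna)
    return rna.replace("U", "T")


def as_dna(seq: str) -> str:
    """Coerce a validated sequence into the DNA alphabet (U→T, idempotent)."""
    _check_alphabet(seq)
    return seq.replace("U", "T")


def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[NucSeq]:
    """Read a FASTA file into a list of :class:`NucSeq`, preserving record order."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[NucSeq] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(NucSeq(id=rec.id, seq=str(rec.seq), allow_ambiguous=allow_ambiguous))
    return out


def write_fasta(records: Iterable[NucSeq], path: str | Path, *, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff3_cds(path: str | Path) -> list[CdsFeature]:
    """Read CDS features from a GFF3 file; multi-segment CDS share an ID/locus_tag."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    grouped: dict[str, CdsFeature] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        tag = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or f"CDS_{feat.start}_{feat.end}"
        )
        # strip gffutils uniquifier suffix so segments regroup
        base = tag.split("_gffutils_")[0]
        if base not in grouped:
            grouped[base] = CdsFeature(locus_tag=base, segments=[], strand=feat.strand)
            order.append(base)
        grouped[base].segments.append((feat.start, feat.end))
    for f in grouped.values():
        f.segments.sort(reverse=(f.strand == "-"))
    return [grouped[t] for t in order]


def read_genbank_cds(path: str | Path) -> tuple[NucSeq, list[CdsFeature]]:
    """Read a GenBank record: returns (genome sequence, CDS features)."""
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None:
        raise EmptyInputError(f"no GenBank records in {path}")
    feats: list[CdsFeature] = []
    for i, feat in enumerate(rec.features):
        if feat.type != "CDS":
            continue
        tag = feat.qualifiers.get("locus_tag", [f"CDS_{i}"])[0]
        strand = "+" if feat.location.strand in (1, None) else "-"
        segments = [(int(p.start) + 1, int(p.end)) for p in feat.location.parts]
        if strand == "-":
            segments = segments[::-1]
        feats.append(CdsFeature(locus_tag=tag, segments=segments, strand=strand))
    genome = NucSeq(id=rec.id, seq=str(rec.seq), topology="linear")
    return genome, feats


def extract_cds(genome: NucSeq, features: Sequence[CdsFeature]) -> list[CdsRecord]:
    """Extract sense-orientation mRNA sequences for CDS features on *genome*.

    Minus-strand segments are reverse-complemented before transcription; multi-segment
    CDS are concatenated in transcription order (flagged with a warning — rare in archaea).
    """
    out: list[CdsRecord] = []
    for feat in features:
        if feat.strand not in ("+", "-"):
            raise CoordinateError(
                f"feature {feat.locus_tag!r}: unknown strand symbol {feat.strand!r}"
            )
        if len(feat.segments) > 1:
            warnings.warn(
                f"feature {feat.locus_tag!r} has {len(feat.segments)} segments (multi-segment CDS)",
                stacklevel=2,
            )
        parts: list[str] = []
        for start, end in feat.segments:
            if start < 1 or end > len(genome) or start > end:
                raise CoordinateError(
                    f"feature {feat.locus_tag!r}: segment {start}..{end} outside genome "
                    f"{genome.id!r} (length {len(genome)})"
                )
            segment = genome.seq[start - 1 : end]
            if feat.strand == "-":
                segment = revcomp(segment)
            parts.append(segment)
        mrna = transcribe("".join(parts))
        out.append(
            CdsRecord(
                locus_tag=feat.locus_tag,
                parent_genome=genome.id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                mrna_seq=mrna,
            )
        )
    return out


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write BED6 lines from (chrom, start_1based, end_1based, name, score, strand)."""
    with Path(path).open("w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_gff3_cds(genome: NucSeq, features: Sequence[CdsFeature], path: str | Path) -> None:
    """Emit a minimal GFF3 with one CDS line per feature segment."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for feat in features:
            for start, end in sorted(feat.segments):
                fh.write(
                    f"{genome.id}\tminicrkit\tCDS\t{start}\t{end}\t.\t{feat.strand}\t0\t"
                    f"ID={feat.locus_tag};locus_tag={feat.locus_tag}\n"
                )
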