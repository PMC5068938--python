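"""miniCRISPR locus assembly and crRNA maturation simulation.

A miniCR locus is a leader (carrying the promoter) followed by a repeat-spacer
array: n spacers interleaved with n+1 identical repeats.  The default assembly
mode mirrors the construction used for multiplexed silencing: a six-spacer
backbone (roles D1..D6) has spacers D2-D4 replaced by the artificial spacers,
giving the array D1, <new...>, D5, D6.  Transcription of the array followed by
processing at each repeat yields one crRNA per spacer, each carrying the 8-nt
repeat-derived 5' handle; 3' trimming is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import AssemblyError, EmptyInputError
from .pairing import HandleSpec
from .seqio import NucSeq, transcribe


@dataclass(frozen=True)
class NamedSpacer:
    name: str
    seq: str  # DNA, array top strand


@dataclass
class Backbone:
    """A CRISPR locus backbone: leader, repeat, and named backbone spacers."""

    leader_seq: str
    repeat_seq: str
    spacers: list[NamedSpacer]

    def __post_init__(self) -> None:
        if len(self.spacers) < 2:
            raise AssemblyError("backbone needs at least 2 spacers")
        if not self.leader_seq or not self.repeat_seq:
            raise AssemblyError("backbone leader and repeat must be non-empty")

    @classmethod
    def from_sequences(
        cls, leader: str, repeat: str, spacer_seqs: Sequence[str], prefix: str = "D"
    ) -> "Backbone":
        return cls(
            leader_seq=leader,
            repeat_seq=repeat,
            spacers=[NamedSpacer(f"{prefix}{i+1}", s) for i, s in enumerate(spacer_seqs)],
        )

    def handle(self) -> HandleSpec:
        return HandleSpec.from_repeat(self.repeat_seq)


@dataclass(frozen=True)
class ArraySpacer:
    name: str
    seq: str
    provenance: str  # "backbone" | "artificial"


@dataclass
class MiniCRConstruct:
    """An assembled miniCR locus: leader + (repeat, spacer)*n + terminal repeat."""

    name: str
    leader_seq: str
    repeat_seq: str
    spacers: list[ArraySpacer]

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1

    @property
    def array_seq(self) -> str:
        """The repeat-spacer array: starts and ends with a repeat."""
        parts = []
        for sp in self.spacers:
            parts.append(self.repeat_seq)
            parts.append(sp.seq)
        parts.append(self.repeat_seq)
        return "".join(parts)

    @property
    def full_seq(self) -> str:
        return self.leader_seq + self.array_seq


@dataclass(frozen=True)
class CrRNA:
    """A mature crRNA: 8-nt repeat handle + full spacer transcript."""

    handle_rna: str
    spacer_rna: str
    array_index: int  # 0-based position of the source spacer in the array
    spacer_name: str = ""

    @property
    def seq(self) -> str:
        return self.handle_rna + self.spacer_rna


def assemble_minicr(
    backbone: Backbone,
    new_spacers: Sequence[NamedSpacer | str],
    mode: str = "replace_D2_D4",
    *,
    insert_after: int | None = None,
    name: str = "miniCR",
) -> MiniCRConstruct:
    """Assemble a miniCR construct from a backbone plus artificial spacers.

    Default mode replaces backbone spacers 2-4 with the new spacers (array order
    D1, new..., D5, D6 for a six-spacer backbone).  mode="custom" inserts the new
    spacers after backbone spacer index *insert_after* (1-based; 0 = before all)
    without removing any.  Identical new spacers (dosage designs) are accepted.
    """
    if not new_spacers:
        raise AssemblyError("new_spacers must be non-empty")
    named: list[NamedSpacer] = []
    for i, sp in enumerate(new_spacers):
        if isinstance(sp, str):
            sp = NamedSpacer(f"S{i+1}", sp)
        if not sp.seq:
            raise AssemblyError(f"spacer {sp.name!r} is empty")
        if backbone.repeat_seq in sp.seq:
            raise AssemblyError(
                f"spacer {sp.name!r} contains the repeat sequence; the array would "
                "be mis-processed"
            )
        named.append(sp)

    if mode == "replace_D2_D4":
        if len(backbone.spacers) < 5:
            raise AssemblyError("replace_D2_D4 mode needs a backbone with >= 5 spacers")
        kept_head = backbone.spacers[:1]
        kept_tail = backbone.spacers[4:]
    elif mode == "custom":
        if insert_after is None or not 0 <= insert_after <= len(backbone.spacers):
            raise AssemblyError("custom mode needs insert_after in 0..len(backbone spacers)")
        kept_head = backbone.spacers[:insert_after]
        kept_tail = backbone.spacers[insert_after:]
    else:
        raise AssemblyError(f"unknown assembly mode {mode!r}")

    array = (
        [ArraySpacer(s.name, s.seq, "backbone") for s in kept_head]
        + [ArraySpacer(s.name, s.seq, "artificial") for s in named]
        + [ArraySpacer(s.name, s.seq, "backbone") for s in kept_tail]
    )
    return MiniCRConstruct(
        name=name,
        leader_seq=backbone.leader_seq,
        repeat_seq=backbone.repeat_seq,
        spacers=array,
    )


def locus_transcript(construct: MiniCRConstruct) -> NucSeq:
    """Primary transcript of the array (transcription starts at the first repeat;
    the leader holds the promoter and is not part of the transcript body)."""
    return NucSeq(
        id=f"{construct.name}_transcript",
        seq=transcribe(construct.array_seq),
        moltype="RNA",
    )


def mature_crrnas(construct: MiniCRConstruct) -> list[CrRNA]:
    """Simulated processing products: one crRNA per spacer, in array order.

    Each crRNA carries the transcript of the final 8 nt of the repeat as its 5'
    handle plus the full spacer transcript (3' end untrimmed).
    """
    if len(construct.repeat_seq) < 8:
        raise AssemblyError("repeat shorter than 8 nt cannot yield a crRNA handle")
    handle = transcribe(construct.repeat_seq[-8:])
    return [
        CrRNA(
            handle_rna=handle,
            spacer_rna=transcribe(sp.seq),
            array_index=i,
            spacer_name=sp.name,
        )
        for i, sp in enumerate(construct.spacers)
    ]


@dataclass
class ValidationReport:
    violations: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_construct(
    construct: MiniCRConstruct, expected_spacer_lengths: range = range(37, 41)
) -> ValidationReport:
    """Structural checks on an assembled construct.

    Checks spacer length range (default 37-40 nt, the range spanned by targeting
    and nonsense spacers), absence of the repeat inside any spacer, full-sequence
    self-consistency, and flags duplicate spacers — duplicates make inner
    overlap-extension joins ambiguous, so dosage constructs need the inverse-PCR
    route instead.
    """
    violations: list[str] = []
    warns: list[str] = []
    for sp in construct.spacers:
        if len(sp.seq) not in expected_spacer_lengths:
            violations.append(
                f"spacer {sp.name!r} length {len(sp.seq)} outside "
                f"{expected_spacer_lengths.start}..{expected_spacer_lengths.stop - 1}"
            )
        if construct.repeat_seq in sp.seq:
            violations.append(f"spacer {sp.name!r} contains the repeat sequence")
    seqs = [sp.seq for sp in construct.spacers]
    if len(set(seqs)) < len(seqs):
        warns.append(
            "duplicate spacers present: overlap-extension fusion would be ambiguous; "
            "build this as a dosage construct via the inverse-PCR + long-overlap route"
        )
    reconstructed = construct.leader_seq + construct.array_seq
    if reconstructed != construct.full_seq:
        violations.append("full_seq does not reconstruct from leader + array")
    return ValidationReport(violations=violations, warnings=warns)


def write_construct_genbank(construct: MiniCRConstruct, path: str | Path) -> None:
    """Write the construct as GenBank with leader/repeat/spacer features."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(construct.full_seq),
        id=construct.name[:16] or "miniCR",
        name=construct.name[:16] or "miniCR",
        description="miniCR construct",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    pos = 0
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, len(construct.leader_seq)),
            type="regulatory",
            qualifiers={"note": ["leader"]},
        )
    )
    pos = len(construct.leader_seq)
    rlen = len(construct.repeat_seq)
    for sp in construct.spacers:
        rec.features.append(
            SeqFeature(FeatureLocation(pos, pos + rlen), type="repeat_region")
        )
        pos += rlen
        rec.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(sp.seq)),
                type="misc_feature",
                qualifiers={"label": [sp.name], "note": [f"spacer;provenance={sp.provenance}"]},
            )
        )
        pos += len(sp.seq)
    rec.features.append(SeqFeature(FeatureLocation(pos, pos + rlen), type="repeat_region"))
    from Bio import SeqIO

    SeqIO.write(rec, str(path), "genbank")
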