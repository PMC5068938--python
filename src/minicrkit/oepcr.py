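"""Modular overlap-extension PCR (OE-PCR) design and in-silico verification.

The construction route being modelled builds a new repeat-spacer array in three
sequential PCRs:

1. *Flank synthesis* — for each repeat of the new array, two primers anneal to
   the repeat and are extended from its middle; each primer also carries one
   adjacent spacer, so the product ("flank") is left_spacer + repeat +
   right_spacer, and the spacers are the unique parts that direct fusion.
2. *Fusion + amplification* — flanks sharing a spacer prime each other and fuse
   into one OE fragment, amplified by the M primer pair, which binds the
   spacer-side arms of the outermost (MOE) primers; amplification succeeds only
   if the flanks fused in the intended order.
3. *Megaprimer insertion* — the OE fragment primes whole-plasmid amplification
   of a circular template, replacing the span between its two arm-annealing
   sites with the fragment interior.

Dosage constructs (the same spacer repeated in series) cannot use inner flanks —
duplicate spacers make fusion ambiguous — so a separate route linearises a
single-copy plasmid in the middle of the spacer by inverse PCR and extends it
with long primers spanning half-spacer + repeat + full spacer.

Annealing is simulated as exact string matching of a primer's 3'-terminal region
(default 12 nt); there is no melting-temperature model, which keeps verification
deterministic.  Template-removal (DpnI) and ligation steps carry no sequence
information and are recorded only as protocol notes in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .assembly import ArraySpacer, Backbone, MiniCRConstruct, NamedSpacer
from .errors import (
    AssemblyError,
    FusionAmbiguityError,
    NoAmpliconError,
    PrimerDesignError,
)
from .seqio import NucSeq, revcomp

#: Protocol metadata recorded in primer reports (not used computationally).
PROTOCOL_NOTES = {
    "megaprimer_ratio": "OE fragment : template = 200:1 (20-30 ng fragment, 80-100 ng template)",
    "template_elimination": "DpnI digestion of the dam-methylated template after step 3",
    "dosage_route_cycles": "long-overlap extension limited to 4 cycles before clean-up",
}

MIN_PRIMER_LEN = 15
DEFAULT_ANNEAL_LEN = 12


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str  # DNA, 5'->3'
    role: str  # flank_fw|flank_rv|moe_fw|moe_rv|m_fw|m_rv|lin_fw|lin_rv|over
    arm_len: int | None = None  # spacer-side arm length, where meaningful

    def __post_init__(self) -> None:
        if len(self.seq) < MIN_PRIMER_LEN:
            raise PrimerDesignError(
                f"primer {self.name!r} is {len(self.seq)} nt (< {MIN_PRIMER_LEN})"
            )
        if set(self.seq) - set("ACGT"):
            raise PrimerDesignError(f"primer {self.name!r} contains non-ACGT characters")


@dataclass
class FlankUnit:
    """One flank: fw/rv primers over a shared repeat, yielding left+repeat+right."""

    left_spacer: str
    right_spacer: str
    fw_primer: Primer
    rv_primer: Primer
    product: str
    name: str = ""


@dataclass
class OEFragment:
    """A fused OE fragment with the trace of its source units."""

    seq: str
    unit_trace: list[str]
    left_arm_len: int = 0
    right_arm_len: int = 0


def simulate_primer_extension(fw: str, rv: str, *, min_overlap: int = 6) -> str:
    """Mutual extension of two primers whose 3' ends anneal (exact-match model).

    The fw 3' terminus must equal a prefix region of revcomp(rv); returns the
    filled-in double-stranded product top strand.
    """
    rc = revcomp(rv)
    best = 0
    for k in range(min_overlap, min(len(fw), len(rc)) + 1):
        if fw[-k:] == rc[:k]:
            best = k
    if best == 0:
        raise NoAmpliconError("primer 3' ends do not anneal (no overlap found)")
    return fw + rc[best:]


def _check_anneal(primer: Primer, template: str, *, anneal_len: int = DEFAULT_ANNEAL_LEN) -> bool:
    """Does the primer's 3'-terminal region match the template top strand exactly?"""
    return primer.seq[-anneal_len:] in template


def design_flank_unit(
    left_spacer: str,
    repeat: str,
    right_spacer: str,
    overlap: int = DEFAULT_ANNEAL_LEN,
    *,
    name: str = "",
) -> FlankUnit:
    """Design the two flank primers for one left_spacer+repeat+right_spacer unit.

    The primers' 3' ends overlap by *overlap* nt centred on the repeat midpoint,
    so polymerase extension from the middle of the repeat yields the full unit.
    """
    if overlap > len(repeat):
        raise PrimerDesignError(
            f"overlap {overlap} exceeds repeat length {len(repeat)}"
        )
    if repeat in left_spacer or repeat in right_spacer:
        raise PrimerDesignError("spacers must not contain the repeat sequence")
    h_fw = len(repeat) // 2 + overlap // 2
    h_rv = len(repeat) - (len(repeat) // 2 - (overlap - overlap // 2))
    fw = Primer(
        name=f"{name}_fw" if name else "flank_fw",
        seq=left_spacer + repeat[:h_fw],
        role="flank_fw",
        arm_len=len(left_spacer),
    )
    rv = Primer(
        name=f"{name}_rv" if name else "flank_rv",
        seq=revcomp(repeat[len(repeat) - h_rv :] + right_spacer),
        role="flank_rv",
        arm_len=len(right_spacer),
    )
    product = left_spacer + repeat + right_spacer
    extended = simulate_primer_extension(fw.seq, rv.seq, min_overlap=overlap)
    if extended != product:
        raise PrimerDesignError(
            f"flank {name!r}: simulated extension does not reproduce the declared product"
        )
    return FlankUnit(
        left_spacer=left_spacer,
        right_spacer=right_spacer,
        fw_primer=fw,
        rv_primer=rv,
        product=product,
        name=name or "flank",
    )


@dataclass
class MoeDesign:
    moe_fw: Primer
    moe_rv: Primer
    left_unit: FlankUnit  # D1-arm | repeat | first new spacer
    right_unit: FlankUnit  # last new spacer | repeat | D5-arm
    d1_arm: str
    d5_arm: str


def design_moe_primers(
    backbone: Backbone,
    first_new_spacer: str,
    last_new_spacer: str,
    total_length: int = 50,
    *,
    overlap: int = DEFAULT_ANNEAL_LEN,
) -> MoeDesign:
    """Design the outermost (MOE) primers and the two terminal flank units.

    moe_fw = 3' arm of backbone spacer D1 + the repeat; moe_rv = revcomp(repeat +
    5' arm of D5); each totals *total_length* nt.  The terminal units pair a MOE
    primer with the flank primer of the first/last new spacer, anchoring the OE
    fragment in backbone sequence.
    """
    repeat = backbone.repeat_seq
    arm = total_length - len(repeat)
    if arm < MIN_PRIMER_LEN:
        raise PrimerDesignError(
            f"total_length {total_length} leaves a {arm}-nt arm beside a "
            f"{len(repeat)}-nt repeat; need >= {MIN_PRIMER_LEN}"
        )
    d1, d5 = backbone.spacers[0].seq, backbone.spacers[4].seq
    if len(d1) < arm or len(d5) < arm:
        raise PrimerDesignError(
            f"backbone spacers D1/D5 shorter than the required {arm}-nt arm"
        )
    d1_arm = d1[-arm:]
    d5_arm = d5[:arm]
    moe_fw = Primer(name="MOE-Fw", seq=d1_arm + repeat, role="moe_fw", arm_len=arm)
    moe_rv = Primer(name="MOE-Rv", seq=revcomp(repeat + d5_arm), role="moe_rv", arm_len=arm)

    h_rv = len(repeat) - (len(repeat) // 2 - (overlap - overlap // 2))
    h_fw = len(repeat) // 2 + overlap // 2
    left_unit = FlankUnit(
        left_spacer=d1_arm,
        right_spacer=first_new_spacer,
        fw_primer=moe_fw,
        rv_primer=Primer(
            name="flank_first_rv",
            seq=revcomp(repeat[len(repeat) - h_rv :] + first_new_spacer),
            role="flank_rv",
            arm_len=len(first_new_spacer),
        ),
        product=d1_arm + repeat + first_new_spacer,
        name="terminal_left",
    )
    right_unit = FlankUnit(
        left_spacer=last_new_spacer,
        right_spacer=d5_arm,
        fw_primer=Primer(
            name="flank_last_fw",
            seq=last_new_spacer + repeat[:h_fw],
            role="flank_fw",
            arm_len=len(last_new_spacer),
        ),
        rv_primer=moe_rv,
        product=last_new_spacer + repeat + d5_arm,
        name="terminal_right",
    )
    for unit in (left_unit, right_unit):
        if simulate_primer_extension(unit.fw_primer.seq, unit.rv_primer.seq,
                                     min_overlap=overlap) != unit.product:
            raise PrimerDesignError(f"terminal unit {unit.name!r} fails extension check")
    return MoeDesign(
        moe_fw=moe_fw, moe_rv=moe_rv, left_unit=left_unit, right_unit=right_unit,
        d1_arm=d1_arm, d5_arm=d5_arm,
    )


def design_m_primers(moe_fw: Primer, moe_rv: Primer) -> tuple[Primer, Primer]:
    """The M amplification primers: the spacer-side arm segment of each MOE primer."""
    if moe_fw.arm_len is None or moe_rv.arm_len is None:
        raise PrimerDesignError("MOE primers must carry their arm length")
    m_fw = Primer(name="M-Fw", seq=moe_fw.seq[: moe_fw.arm_len], role="m_fw",
                  arm_len=moe_fw.arm_len)
    m_rv = Primer(name="M-Rv", seq=moe_rv.seq[: moe_rv.arm_len], role="m_rv",
                  arm_len=moe_rv.arm_len)
    return m_fw, m_rv


def design_oe_units(
    backbone: Backbone,
    new_spacers: Sequence[NamedSpacer | str],
    *,
    total_length: int = 50,
    overlap: int = DEFAULT_ANNEAL_LEN,
) -> tuple[list[FlankUnit], tuple[Primer, Primer], MoeDesign]:
    """Design the complete flank-unit set plus M primers for a replace-D2-D4 build."""
    named = [
        sp if isinstance(sp, NamedSpacer) else NamedSpacer(f"S{i+1}", sp)
        for i, sp in enumerate(new_spacers)
    ]
    moe = design_moe_primers(
        backbone, named[0].seq, named[-1].seq, total_length, overlap=overlap
    )
    units = [moe.left_unit]
    for a, b in zip(named, named[1:]):
        units.append(
            design_flank_unit(a.seq, backbone.repeat_seq, b.seq, overlap,
                              name=f"{a.name}-{b.name}")
        )
    units.append(moe.right_unit)
    m_primers = design_m_primers(moe.moe_fw, moe.moe_rv)
    return units, m_primers, moe


def simulate_oe_fusion(
    flank_units: Sequence[FlankUnit], m_primers: tuple[Primer, Primer]
) -> OEFragment:
    """Fuse flank units on shared spacers and amplify with the M primers.

    Units join wherever one product's terminal spacer equals another's initial
    spacer (exact full-spacer match).  Returns the unique maximal assembly whose
    ends are the M-primer arms; duplicate spacers raise a fusion-ambiguity error,
    and a set that cannot be chained end-to-end raises a no-amplicon error.
    """
    if not flank_units:
        raise NoAmpliconError("no flank units supplied")
    m_fw, m_rv = m_primers
    left_anchor = m_fw.seq
    right_anchor = revcomp(m_rv.seq)

    lefts = [u.left_spacer for u in flank_units]
    rights = [u.right_spacer for u in flank_units]
    for values, side in ((lefts, "left"), (rights, "right")):
        dupes = {v for v in values if values.count(v) > 1}
        if dupes:
            raise FusionAmbiguityError(
                f"duplicate {side} spacer(s) across flank units: fusion order is "
                "ambiguous (use the repeated-spacer route for dosage constructs)"
            )
    by_left = {u.left_spacer: u for u in flank_units}

    start = by_left.get(left_anchor)
    if start is None:
        raise NoAmpliconError("no flank unit begins with the M-Fw arm; nothing amplifies")
    chain = [start]
    seen = {id(start)}
    while chain[-1].right_spacer != right_anchor:
        nxt = by_left.get(chain[-1].right_spacer)
        if nxt is None:
            raise NoAmpliconError(
                f"fusion chain breaks after unit {chain[-1].name!r}: no unit continues "
                f"it and the M-Rv arm is not reached"
            )
        if id(nxt) in seen:
            raise NoAmpliconError("fusion chain cycles without reaching the M-Rv arm")
        chain.append(nxt)
        seen.add(id(nxt))
    if len(seen) != len(flank_units):
        unused = [u.name for u in flank_units if id(u) not in seen]
        raise NoAmpliconError(
            f"flank set is disconnected: unit(s) {unused} cannot join the amplified chain"
        )

    seq = chain[0].product
    for unit in chain[1:]:
        seq += unit.product[len(unit.left_spacer):]
    return OEFragment(
        seq=seq,
        unit_trace=[u.name for u in chain],
        left_arm_len=len(left_anchor),
        right_arm_len=len(right_anchor),
    )


def _circular_occurrences(template: str, query: str) -> list[int]:
    """Start offsets (0-based) of *query* in the circular sequence *template*."""
    doubled = template + template[: len(query) - 1]
    hits = []
    pos = doubled.find(query)
    while pos != -1:
        if pos < len(template):
            hits.append(pos)
        pos = doubled.find(query, pos + 1)
    return hits


def simulate_megaprimer_insertion(fragment: OEFragment, template: NucSeq) -> NucSeq:
    """Whole-plasmid amplification primed by the OE fragment.

    The fragment's two arm regions must each occur exactly once on the circular
    template; the template span between them is replaced by the fragment
    interior, preserving circular topology.
    """
    if template.topology != "circular":
        raise AssemblyError("megaprimer insertion requires a circular template")
    arm_l = fragment.seq[: fragment.left_arm_len]
    arm_r = fragment.seq[len(fragment.seq) - fragment.right_arm_len :]
    t = template.seq
    for arm, label in ((arm_l, "left (D1-side)"), (arm_r, "right (D5-side)")):
        n = len(_circular_occurrences(t, arm))
        if n == 0:
            raise AssemblyError(f"{label} arm absent from the template")
        if n > 1:
            raise AssemblyError(f"{label} arm occurs {n} times on the template (must be unique)")
    i1 = _circular_occurrences(t, arm_l)[0]
    rotated = t[i1:] + t[:i1]  # left arm now at position 0
    i2 = _circular_occurrences(rotated, arm_r)[0]
    if i2 < len(arm_l):
        raise AssemblyError("arm annealing sites overlap; incompatible orientation")
    product = fragment.seq + rotated[i2 + len(arm_r) :]
    return NucSeq(id=f"{template.id}_inserted", seq=product, topology="circular")


@dataclass
class DosageDesign:
    lin_fw: Primer
    lin_rv: Primer
    over_fw: Primer
    over_rv: Primer
    product: MiniCRConstruct


def design_dosage_route(
    single_copy_construct: MiniCRConstruct, spacer_name: str, copies: int
) -> DosageDesign:
    """Design the repeated-spacer (dosage) route and simulate its product.

    Inverse-PCR primers linearise the plasmid at the midpoint of the named spacer
    (outward-facing); long-overlap primers of composition half-spacer + repeat +
    full spacer then extend the linear template so the final, re-circularised
    construct carries the spacer *copies* times in series, interspaced by repeats.
    copies=1 returns the input construct unchanged.
    """
    if copies < 1:
        raise AssemblyError("copies must be >= 1")
    matches = [i for i, sp in enumerate(single_copy_construct.spacers)
               if sp.name == spacer_name]
    if not matches:
        raise AssemblyError(f"spacer {spacer_name!r} not found in construct")
    if len(matches) > 1:
        raise AssemblyError(f"spacer {spacer_name!r} occurs {len(matches)} times; need exactly 1")
    idx = matches[0]
    spacer = single_copy_construct.spacers[idx].seq
    if single_copy_construct.full_seq.count(spacer) != 1:
        raise AssemblyError(
            f"spacer {spacer_name!r} sequence is not unique in the construct"
        )
    repeat = single_copy_construct.repeat_seq
    mid = len(spacer) // 2
    lin_fw = Primer(name=f"{spacer_name}_lin_fw", seq=spacer[mid:], role="lin_fw")
    lin_rv = Primer(name=f"{spacer_name}_lin_rv", seq=revcomp(spacer[:mid]), role="lin_rv")
    over_fw = Primer(name=f"{spacer_name}_over_fw", seq=spacer[mid:] + repeat + spacer,
                     role="over")
    over_rv = Primer(name=f"{spacer_name}_over_rv",
                     seq=revcomp(spacer + repeat + spacer[: len(spacer) - mid]),
                     role="over")

    if copies == 1:
        product = single_copy_construct
    else:
        src = single_copy_construct.spacers[idx]
        new_spacers = (
            single_copy_construct.spacers[:idx]
            + [ArraySpacer(src.name, src.seq, "artificial") for _ in range(copies)]
            + single_copy_construct.spacers[idx + 1 :]
        )
        product = MiniCRConstruct(
            name=f"{single_copy_construct.name}_x{copies}",
            leader_seq=single_copy_construct.leader_seq,
            repeat_seq=repeat,
            spacers=new_spacers,
        )
    return DosageDesign(lin_fw=lin_fw, lin_rv=lin_rv, over_fw=over_fw, over_rv=over_rv,
                        product=product)


def primers_to_order_sheet(primers: Sequence[Primer], path: str | Path) -> None:
    """TSV order sheet: name, sequence, role, length (+ protocol notes as comments)."""
    with Path(path).open("w") as fh:
        for key, note in PROTOCOL_NOTES.items():
            fh.write(f"# {key}: {note}\n")
        fh.write("name\tsequence\trole\tlength\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.seq}\t{p.role}\t{len(p.seq)}\n")


def write_verification_report(
    path: str | Path,
    *,
    round_trip_ok: bool,
    fragment: OEFragment | None = None,
    detail: dict | None = None,
) -> None:
    payload = {
        "round_trip_ok": round_trip_ok,
        "unit_trace": fragment.unit_trace if fragment else None,
        "fragment_length": len(fragment.seq) if fragment else None,
        "protocol_notes": PROTOCOL_NOTES,
    }
    if detail:
        payload.update(detail)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
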