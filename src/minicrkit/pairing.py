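"""crRNA 5'-handle vs. target-RNA PAS base-pairing rules.

The mature crRNA of a type III system begins with an 8-nt repeat-derived handle.
When the 8 nt immediately 3' of a protospacer on the target mRNA (the
protospacer-adjacent sequence, PAS) can base-pair this handle, the complex reads
the target as "self" at the DNA level: DNA interference is suppressed while RNA
cleavage proceeds.  Handle positions are numbered -8..-1 with -1 adjacent to the
spacer; the register is antiparallel, target position +i pairs handle position -i.

A 3-nt match restricted to handle positions -3/-4/-5 (the "minimal PAS motif")
is already sufficient to suppress DNA cleavage, which is what makes genome-wide
protospacer selection practical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import SequenceAlphabetError
from .seqio import RNA_BASES, transcribe

#: Watson-Crick partner of each RNA base (target base -> handle base and vice versa).
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: G:U wobble partners: handle G pairs target U, handle U pairs target G.
WOBBLE_PARTNER = {"G": "U", "U": "G"}


class PairClass(enum.Enum):
    WATSON_CRICK = "WC"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


def classify_pair(
    target_base: str, handle_base: str, *, ambiguous_ok: bool = False
) -> PairClass:
    """Classify one target:handle RNA base pair (symmetric in its arguments)."""
    for base in (target_base, handle_base):
        if base not in RNA_BASES:
            if ambiguous_ok and base not in "T":
                return PairClass.MISMATCH  # ambiguity codes never pair
            raise SequenceAlphabetError(
                f"expected an RNA base, got {base!r} (transcribe DNA first)"
            )
    if WC_PARTNER[target_base] == handle_base:
        return PairClass.WATSON_CRICK
    if WOBBLE_PARTNER.get(target_base) == handle_base:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


@dataclass(frozen=True)
class HandleSpec:
    """The 8-nt crRNA 5' handle, written 5'->3' (first char = position -8, last = -1)."""

    handle_rna: str
    source_repeat: str | None = None

    def __post_init__(self) -> None:
        if len(self.handle_rna) != 8:
            raise ValueError(f"handle must be 8 nt, got {len(self.handle_rna)}")
        if set(self.handle_rna) - RNA_BASES:
            raise SequenceAlphabetError(f"handle {self.handle_rna!r} is not RNA")
        if self.source_repeat is not None:
            expected = transcribe(self.source_repeat[-8:])
            if expected != self.handle_rna:
                raise ValueError(
                    f"handle {self.handle_rna!r} does not match the last 8 nt of the "
                    f"repeat ({expected!r})"
                )

    @classmethod
    def from_repeat(cls, repeat_dna: str) -> "HandleSpec":
        """Derive the handle from a DNA repeat: the transcript of its final 8 nt."""
        if len(repeat_dna) < 8:
            raise ValueError("repeat shorter than 8 nt cannot yield a handle")
        return cls(handle_rna=transcribe(repeat_dna[-8:]), source_repeat=repeat_dna)

    def base_at(self, position: int) -> str:
        """Handle base at position -8..-1."""
        if not -8 <= position <= -1:
            raise ValueError(f"handle position must be -8..-1, got {position}")
        return self.handle_rna[8 + position]


@dataclass(frozen=True)
class PasConfig:
    """Configuration of the PAS acceptance rules."""

    min_paired: int = 6
    wobble_counts_as_paired: bool = True
    minimal_positions: frozenset[int] = frozenset({-3, -4, -5})

    def __post_init__(self) -> None:
        if not 0 <= self.min_paired <= 8:
            raise ValueError("min_paired must be within 0..8")
        if not set(self.minimal_positions) <= set(range(-8, 0)):
            raise ValueError("minimal_positions must be a subset of -8..-1")


@dataclass(frozen=True)
class PasMatch:
    """Per-position classification of an 8-nt PAS against the handle."""

    per_position: dict[int, PairClass]  # keys -8..-1
    paired_count: int
    wc_count: int
    minimal_ok: bool

    def pairing_string(self) -> str:
        """Compact glyph string for positions -8..-1: '|' WC, ':' wobble, '.' mismatch."""
        glyph = {PairClass.WATSON_CRICK: "|", PairClass.WOBBLE: ":", PairClass.MISMATCH: "."}
        return "".join(glyph[self.per_position[p]] for p in range(-8, 0))


def match_pas(pas: str, handle: HandleSpec, config: PasConfig = PasConfig(),
              *, ambiguous_ok: bool = False) -> PasMatch:
    """Classify an 8-nt PAS (read 5'->3' at target positions +1..+8) against the handle.

    Antiparallel register: target position +i is paired with handle position -i,
    i.e. pas[i-1] against handle.base_at(-i).
    """
    if len(pas) != 8:
        raise ValueError(f"PAS must be 8 nt, got {len(pas)}")
    per_position: dict[int, PairClass] = {}
    for i in range(1, 9):
        per_position[-i] = classify_pair(pas[i - 1], handle.base_at(-i),
                                         ambiguous_ok=ambiguous_ok)
    wc = sum(1 for c in per_position.values() if c is PairClass.WATSON_CRICK)
    paired = wc
    if config.wobble_counts_as_paired:
        paired += sum(1 for c in per_position.values() if c is PairClass.WOBBLE)

    def _is_paired(cls: PairClass) -> bool:
        if cls is PairClass.WATSON_CRICK:
            return True
        return cls is PairClass.WOBBLE and config.wobble_counts_as_paired

    minimal_ok = all(_is_paired(per_position[p]) for p in config.minimal_positions)
    return PasMatch(per_position=per_position, paired_count=paired, wc_count=wc,
                    minimal_ok=minimal_ok)


def allowed_target_bases(handle_base: str, *, wobble: bool) -> set[str]:
    """Target bases that count as paired against one handle base."""
    bases = {WC_PARTNER[handle_base]}
    if wobble and handle_base in WOBBLE_PARTNER:
        bases.add(WOBBLE_PARTNER[handle_base])
    return bases


def minimal_motif_patterns(handle: HandleSpec, config: PasConfig = PasConfig()) -> set[str]:
    """Target-side 3-mers (read 5'->3') that satisfy the minimal PAS motif.

    Requires the configured minimal positions to be three contiguous handle
    positions; the returned trinucleotides are the fast path used by the
    genome survey.
    """
    positions = sorted(abs(p) for p in config.minimal_positions)
    if len(positions) != 3 or positions[2] - positions[0] != 2:
        raise ValueError(
            f"minimal motif requires 3 contiguous handle positions, got "
            f"{sorted(config.minimal_positions)}"
        )
    # target positions +a,+a+1,+a+2 read 5'->3' pair handle -a,-a-1,-a-2
    choices = [
        allowed_target_bases(handle.base_at(-i), wobble=config.wobble_counts_as_paired)
        for i in positions
    ]
    patterns: set[str] = set()
    for b1 in choices[0]:
        for b2 in choices[1]:
            for b3 in choices[2]:
                patterns.add(b1 + b2 + b3)
    return patterns
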