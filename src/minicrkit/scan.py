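"""Protospacer enumeration, filtering, ranking and off-target screening.

A protospacer is a window on the target mRNA (default 37 nt, matching typical
type III spacer lengths); it is acceptable when the 8 nt immediately 3' of the
window (the PAS) base-pair the crRNA 5' handle — either at >= min_paired of the
8 positions ("full" mode, the design criterion used for real constructs) or only
at the minimal -3/-4/-5 motif ("minimal" mode).  The spacer is the reverse
complement of the protospacer, so the mature crRNA base-pairs the mRNA.

Off-target screening is ungapped Hamming search at every offset, mirroring the
mismatch-count criterion used to validate nonsense control spacers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SequenceAlphabetError
from .pairing import HandleSpec, PasConfig, PasMatch, match_pas
from .seqio import NucSeq, back_transcribe, revcomp, transcribe, write_fasta


@dataclass(frozen=True)
class Protospacer:
    """A candidate target window on an mRNA (1-based start, sense orientation)."""

    transcript_id: str
    start: int
    length: int
    seq: str  # RNA, mRNA sense

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("protospacer start must be >= 1")
        if len(self.seq) != self.length:
            raise ValueError("protospacer seq length disagrees with declared length")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SpacerCandidate:
    """A protospacer plus its derived spacer and PAS match profile."""

    protospacer: Protospacer
    spacer_rna: str
    pas: str
    pas_match: PasMatch
    energy_kcal_per_mol: float | None = None


EnergyScorer = Callable[[SpacerCandidate], float]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a protospacer scan."""

    protospacer_length: int = 37
    criterion_mode: str = "full"  # full: paired_count >= min_paired; minimal: minimal_ok
    pas_config: PasConfig = field(default_factory=PasConfig)
    energy_threshold: float | None = None  # kcal/mol, applied only when a scorer is plugged in

    def __post_init__(self) -> None:
        if self.protospacer_length < 1:
            raise ValueError("protospacer_length must be >= 1")
        if self.criterion_mode not in ("full", "minimal"):
            raise ValueError(f"unknown criterion_mode {self.criterion_mode!r}")

    def passes(self, match: PasMatch) -> bool:
        if self.criterion_mode == "full":
            return match.paired_count >= self.pas_config.min_paired
        return match.minimal_ok


def _as_rna(transcript: NucSeq) -> str:
    if transcript.moltype == "DNA":
        return transcribe(transcript.seq)
    return transcript.seq


def scan_transcript(
    transcript: NucSeq,
    handle: HandleSpec,
    config: ScanConfig = ScanConfig(),
    *,
    scorer: EnergyScorer | None = None,
) -> list[SpacerCandidate]:
    """Enumerate all criterion-passing protospacer windows on a transcript.

    Returns candidates sorted by (paired_count desc, Watson-Crick-only count desc,
    start asc).  A transcript too short for one window plus its PAS yields an
    empty list with a warning.
    """
    rna = _as_rna(transcript)
    L = config.protospacer_length
    if len(rna) < L + 8:
        warnings.warn(
            f"transcript {transcript.id!r} ({len(rna)} nt) shorter than "
            f"protospacer+PAS ({L + 8} nt); no candidates", stacklevel=2
        )
        return []
    candidates: list[SpacerCandidate] = []
    for start in range(1, len(rna) - L - 8 + 2):  # 1-based; PAS needs 8 nt downstream
        window = rna[start - 1 : start - 1 + L]
        pas = rna[start - 1 + L : start + L + 7]
        m = match_pas(pas, handle, config.pas_config)
        if not config.passes(m):
            continue
        proto = Protospacer(transcript_id=transcript.id, start=start, length=L, seq=window)
        cand = SpacerCandidate(
            protospacer=proto, spacer_rna=revcomp(window), pas=pas, pas_match=m
        )
        if scorer is not None:
            cand.energy_kcal_per_mol = scorer(cand)
        candidates.append(cand)
    if scorer is not None and config.energy_threshold is not None:
        candidates = [
            c for c in candidates
            if c.energy_kcal_per_mol is not None
            and c.energy_kcal_per_mol < config.energy_threshold
        ]
    candidates.sort(
        key=lambda c: (-c.pas_match.paired_count, -c.pas_match.wc_count, c.protospacer.start)
    )
    return candidates


def make_spacer(protospacer: Protospacer) -> tuple[str, str]:
    """Return (spacer_rna, spacer_dna) for a protospacer.

    spacer_rna is the reverse complement of the protospacer (the targeting part of
    the crRNA); spacer_dna is the same sequence in the DNA alphabet, as inserted
    into the array top strand so the locus transcript regenerates spacer_rna.
    """
    spacer_rna = revcomp(protospacer.seq)
    return spacer_rna, back_transcribe(spacer_rna)


def select_multiplex(
    candidates: Sequence[SpacerCandidate], k: int, min_separation: int | None = None
) -> list[SpacerCandidate]:
    """Pick k candidates greedily in rank order, subject to pairwise start separation.

    *candidates* must already be rank-sorted (as returned by :func:`scan_transcript`).
    Returned picks are in transcript order.  Defaults min_separation to twice the
    protospacer length so multiplexed spacers hit well-separated positions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        raise DesignError("no candidates to select from (maximum feasible k = 0)")
    if min_separation is None:
        min_separation = 2 * candidates[0].protospacer.length
    chosen: list[SpacerCandidate] = []
    for cand in candidates:
        if all(
            abs(cand.protospacer.start - c.protospacer.start) >= min_separation
            for c in chosen
        ):
            chosen.append(cand)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        # maximum feasible k under the separation constraint: greedy sweep by position
        starts = sorted(c.protospacer.start for c in candidates)
        feasible, last = 0, None
        for s in starts:
            if last is None or s - last >= min_separation:
                feasible += 1
                last = s
        raise DesignError(
            f"cannot select {k} candidates with separation >= {min_separation} nt; "
            f"maximum feasible k = {feasible}"
        )
    return sorted(chosen, key=lambda c: c.protospacer.start)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def min_mismatches(spacer_rna: str, transcript: NucSeq) -> int:
    """Minimum Hamming distance between the spacer's target (revcomp) and any
    equal-length window of the transcript, over all ungapped offsets."""
    rna = _as_rna(transcript)
    target_like = revcomp(spacer_rna)
    n, m = len(rna), len(target_like)
    if m > n:
        raise DesignError(
            f"spacer ({m} nt) longer than transcript {transcript.id!r} ({n} nt)"
        )
    windows = np.lib.stride_tricks.sliding_window_view(_seq_array(rna), m)
    mism = (windows != _seq_array(target_like)).sum(axis=1)
    return int(mism.min())


def offtarget_scan(
    spacer_rna: str, transcriptome: Sequence[NucSeq], max_mismatches: int
) -> list[tuple[str, int, int]]:
    """All ungapped hits of the spacer's target sequence with <= max_mismatches.

    Returns (transcript_id, start_1based, mismatches), sorted by mismatches then
    by transcript order and position.
    """
    target_like = revcomp(spacer_rna)
    tl = _seq_array(target_like)
    hits: list[tuple[str, int, int]] = []
    for order, tx in enumerate(transcriptome):
        rna = _as_rna(tx)
        if len(tl) > len(rna):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(_seq_array(rna), len(tl))
        mism = (windows != tl).sum(axis=1)
        for off in np.nonzero(mism <= max_mismatches)[0]:
            hits.append((tx.id, int(off) + 1, int(mism[off])))
    order_index = {tx.id: i for i, tx in enumerate(transcriptome)}
    hits.sort(key=lambda h: (h[2], order_index[h[0]], h[1]))
    return hits


def generate_nonsense_spacer(
    length: int,
    excluded_targets: Sequence[NucSeq],
    threshold: int = 20,
    rng_seed: int = 0,
    *,
    max_attempts: int = 10_000,
) -> str:
    """Generate a control spacer with > threshold mismatches to every excluded target.

    Rejection-samples uniform random RNA of the given length (seeded, hence
    deterministic) until the brute-force minimum-mismatch check passes for every
    target; used for nonsense controls that must not silence anything.
    """
    if threshold >= length:
        raise DesignError("threshold must be smaller than the spacer length")
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGU"))
    for _ in range(max_attempts):
        spacer = "".join(rng.choice(bases, size=length))
        if all(min_mismatches(spacer, t) > threshold for t in excluded_targets):
            return spacer
    raise DesignError(
        f"no spacer with > {threshold} mismatches found in {max_attempts} attempts; "
        "lower the threshold"
    )


def candidates_to_frame(candidates: Iterable[SpacerCandidate]) -> pd.DataFrame:
    """Tabulate candidates for TSV export."""
    rows = []
    for c in candidates:
        p = c.protospacer
        rows.append(
            {
                "transcript_id": p.transcript_id,
                "start_1based": p.start,
                "end_1based": p.end,
                "protospacer": p.seq,
                "spacer": c.spacer_rna,
                "pas": c.pas,
                "paired_count": c.pas_match.paired_count,
                "wc_count": c.pas_match.wc_count,
                "minimal_ok": c.pas_match.minimal_ok,
                "pairing": c.pas_match.pairing_string(),
                "energy_kcal_per_mol": c.energy_kcal_per_mol,
            }
        )
    return pd.DataFrame(rows)


def write_candidates_tsv(candidates: Iterable[SpacerCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def write_spacers_fasta(candidates: Sequence[SpacerCandidate], path: str | Path) -> None:
    records = [
        NucSeq(
            id=f"{c.protospacer.transcript_id}_spacer_{c.protospacer.start}",
            seq=c.spacer_rna,
        )
        for c in candidates
    ]
    write_fasta(records, path)


def candidates_to_bed(candidates: Iterable[SpacerCandidate]):
    """BED6 tuples (chrom, start_1based, end_1based, name, score, strand) for export."""
    for c in candidates:
        p = c.protospacer
        yield (
            p.transcript_id, p.start, p.end,
            f"protospacer_{p.start}", float(c.pas_match.paired_count), "+",
        )
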