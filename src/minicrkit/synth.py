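"""Seeded synthetic genomes, CDS sets and target transcripts with planted truth.

Every generator returns both the sequences and a :class:`FixtureTruth` describing
exactly what was planted, so tests can assert against the known ground truth
rather than re-derived expectations.  Backgrounds are scrubbed of accidental
criterion-passing sites by resampling the minimal disrupting base, which keeps
length and composition statistics intact.

The default transcript length (2709 nt) mirrors the size of the α-amylase gene
used as the silencing target in the study conditions this toolkit emulates, so
worked examples run at realistic scale.

Scrubbing scope: transcripts are guaranteed free of accidental *full-mode*
windows (paired_count >= min_paired outside planted sites).  Minimal-motif
(3-mer) background occurrences are not scrubbed from transcripts — in random
sequence the motif recurs every ~16 nt, and removing it would destroy the
background — so planted-truth scans of transcripts use full mode.  CDS sets are
the converse: they are scrubbed of (and planted with) minimal-motif 3-mers for
survey testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import PackingError
from .pairing import (
    WC_PARTNER,
    WOBBLE_PARTNER,
    HandleSpec,
    PasConfig,
    match_pas,
    minimal_motif_patterns,
)
from .seqio import CdsFeature, NucSeq, back_transcribe, revcomp, write_fasta, write_gff3_cds

RNA = "ACGU"


@dataclass
class FixtureTruth:
    """Authoritative record of what a fixture generator planted."""

    planted_protospacers: list[tuple[str, int, int]] = field(default_factory=list)
    planted_motifs_per_cds: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0
    generation_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_protospacers": self.planted_protospacers,
                "planted_motifs_per_cds": self.planted_motifs_per_cds,
                "rng_seed": self.rng_seed,
                "generation_params": self.generation_params,
            },
            indent=2,
        )


def _spaced_starts(
    rng: np.random.Generator, k: int, low: int, high: int, footprint: int
) -> list[int]:
    """k sorted starts in [low, high] with pairwise distance >= footprint."""
    if k == 0:
        return []
    span = high - low + 1 - (k - 1) * footprint
    if span < k:
        raise PackingError(
            f"cannot place {k} sites of footprint {footprint} in [{low}, {high}]"
        )
    picks = np.sort(rng.choice(span, size=k, replace=False))
    return [int(low + p + i * footprint) for i, p in enumerate(picks)]


def _perfect_pas(handle: HandleSpec) -> str:
    """The 8-nt target PAS fully Watson-Crick paired to the handle (positions +1..+8)."""
    return "".join(WC_PARTNER[handle.base_at(-i)] for i in range(1, 9))


def _nonpairing_bases(handle_base: str) -> list[str]:
    """Target bases that neither WC- nor wobble-pair a handle base."""
    banned = {WC_PARTNER[handle_base], WOBBLE_PARTNER.get(handle_base)}
    return [b for b in RNA if b not in banned]


def _counts_as_paired(cls, config: PasConfig) -> bool:
    from .pairing import PairClass

    if cls is PairClass.WATSON_CRICK:
        return True
    return cls is PairClass.WOBBLE and config.wobble_counts_as_paired


def synth_target_transcript(
    length: int = 2709,
    k_sites: int = 5,
    handle: HandleSpec | None = None,
    protospacer_length: int = 37,
    seed: int = 0,
    *,
    pas_config: PasConfig = PasConfig(),
    transcript_id: str = "synthetic_target",
    site_separation: int | None = None,
    max_retries: int = 50,
) -> tuple[NucSeq, FixtureTruth]:
    """A random transcript with k fully PAS-compliant protospacer windows planted.

    Each planted window's PAS pairs all 8 handle positions; the background is
    scrubbed so no other window reaches pas_config.min_paired (full mode).
    Planted starts are pairwise >= site_separation apart (default twice the
    protospacer length, so default multiplex selection stays feasible).
    """
    if handle is None:
        raise ValueError("a HandleSpec is required")
    L = protospacer_length
    footprint = L + 8
    sep = site_separation if site_separation is not None else max(footprint, 2 * L)
    if length < k_sites * sep:
        raise PackingError(
            f"length {length} cannot hold {k_sites} sites separated by {sep} nt"
        )
    rng = np.random.default_rng(seed)
    perfect = _perfect_pas(handle)

    for _attempt in range(max_retries):
        starts = _spaced_starts(rng, k_sites, 1, length - footprint + 1, sep)
        seq = list(rng.choice(list(RNA), size=length))
        # only the planted PAS octamers are immutable; protospacer bodies may be
        # resampled by the scrubber without affecting the planted truth
        protected: set[int] = set()
        for s in starts:
            for j, base in enumerate(perfect):
                seq[s - 1 + L + j] = base
            protected.update(range(s - 1 + L, s - 1 + L + 8))
        if _scrub_transcript(seq, starts, protected, handle, pas_config, L, rng):
            truth = FixtureTruth(
                planted_protospacers=[(transcript_id, s, L) for s in starts],
                rng_seed=seed,
                generation_params={
                    "length": length,
                    "k_sites": k_sites,
                    "protospacer_length": L,
                    "handle_rna": handle.handle_rna,
                    "min_paired": pas_config.min_paired,
                    "wobble_counts_as_paired": pas_config.wobble_counts_as_paired,
                },
            )
            return NucSeq(id=transcript_id, seq="".join(seq), moltype="RNA"), truth
    raise PackingError(
        f"could not scrub transcript background after {max_retries} attempts"
    )


def _scrub_transcript(
    seq: list[str],
    planted_starts: Sequence[int],
    protected: set[int],
    handle: HandleSpec,
    config: PasConfig,
    L: int,
    rng: np.random.Generator,
    *,
    max_passes: int = 30,
) -> bool:
    """Mutate PAS bases until no non-planted window passes the full-mode criterion."""
    planted = set(planted_starts)
    n_windows = len(seq) - L - 8 + 1
    for _ in range(max_passes):
        dirty = False
        for s in range(1, n_windows + 1):
            if s in planted:
                continue
            pas = "".join(seq[s - 1 + L : s - 1 + L + 8])
            m = match_pas(pas, handle, config)
            if m.paired_count < config.min_paired:
                continue
            dirty = True
            # break one currently-paired PAS position outside planted PAS octamers
            order = list(rng.permutation(8))
            fixed = False
            for t in order:
                idx = s - 1 + L + t
                if idx in protected:
                    continue
                if not _counts_as_paired(m.per_position[-(t + 1)], config):
                    continue  # already a mismatch; mutating cannot reduce the count
                choices = _nonpairing_bases(handle.base_at(-(t + 1)))
                seq[idx] = choices[int(rng.integers(len(choices)))]
                fixed = True
                break
            if not fixed:
                return False  # window unscrubbable; caller retries the whole layout
        if not dirty:
            return True
    return False


def synth_cds_set(
    n_cds: int,
    length_range: tuple[int, int],
    gc_fraction: float,
    planted_counts: Sequence[int],
    seed: int = 0,
    *,
    handle: HandleSpec | None = None,
    pas_config: PasConfig = PasConfig(),
    protospacer_length: int = 37,
    intergenic_length: int = 50,
    genome_id: str = "synthetic_genome",
    max_retries: int = 50,
) -> tuple[NucSeq, list[CdsFeature], FixtureTruth]:
    """A synthetic genome of n CDS with exact planted minimal-PAS-motif counts.

    Planted 3-mers are drawn from the wobble-off motif set and the background is
    scrubbed against the wobble-on superset, so per-CDS counts are invariant
    under either wobble setting.  All planted sites leave a full protospacer of
    upstream room, so counts also hold under both upstream-room settings.
    Strands alternate +/− across consecutive CDS.
    """
    if handle is None:
        raise ValueError("a HandleSpec is required")
    if len(planted_counts) != n_cds:
        raise PackingError("planted_counts must have one entry per CDS")
    from dataclasses import replace

    plant_patterns = sorted(
        minimal_motif_patterns(handle, replace(pas_config, wobble_counts_as_paired=False))
    )
    scrub_patterns = minimal_motif_patterns(
        handle, replace(pas_config, wobble_counts_as_paired=True)
    )
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    L = protospacer_length
    low = L + 3  # 1-based motif start leaving protospacer_length + 2 nt upstream

    mrnas: list[str] = []
    truth_counts: dict[str, int] = {}
    for i in range(n_cds):
        count = int(planted_counts[i])
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if count and length < low + 2 + (count - 1) * 3:
            raise PackingError(
                f"CDS length {length} cannot hold {count} motif sites with upstream room"
            )
        for _attempt in range(max_retries):
            seq = list(rng.choice(list(RNA), size=length, p=p))
            starts = _spaced_starts(rng, count, low, length - 2, 3) if count else []
            planted_idx: set[int] = set()
            for s in starts:
                pattern = plant_patterns[int(rng.integers(len(plant_patterns)))]
                for j, base in enumerate(pattern):
                    seq[s - 1 + j] = base
                planted_idx.update(range(s - 1, s + 2))
            if _scrub_motifs(seq, set(starts), planted_idx, scrub_patterns, rng):
                break
        else:
            raise PackingError(f"could not scrub CDS {i} after {max_retries} attempts")
        mrnas.append("".join(seq))
        truth_counts[f"CDS{i+1:04d}"] = count

    # lay CDS on the genome with intergenic pads, alternating strands
    genome_parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for i, mrna in enumerate(mrnas):
        pad = "".join(rng.choice(list("ACGT"), size=intergenic_length))
        genome_parts.append(pad)
        pos += intergenic_length
        strand = "+" if i % 2 == 0 else "-"
        dna_sense = back_transcribe(mrna)
        segment = dna_sense if strand == "+" else revcomp(dna_sense)
        genome_parts.append(segment)
        features.append(
            CdsFeature(
                locus_tag=f"CDS{i+1:04d}",
                segments=[(pos + 1, pos + len(segment))],
                strand=strand,
            )
        )
        pos += len(segment)
    genome_parts.append("".join(rng.choice(list("ACGT"), size=intergenic_length)))
    genome = NucSeq(id=genome_id, seq="".join(genome_parts), moltype="DNA")

    truth = FixtureTruth(
        planted_motifs_per_cds=truth_counts,
        rng_seed=seed,
        generation_params={
            "n_cds": n_cds,
            "length_range": list(length_range),
            "gc_fraction": gc_fraction,
            "protospacer_length": L,
            "handle_rna": handle.handle_rna,
        },
    )
    return genome, features, truth


def _scrub_motifs(
    seq: list[str],
    planted_starts: set[int],
    planted_idx: set[int],
    patterns: set[str],
    rng: np.random.Generator,
    *,
    max_passes: int = 30,
) -> bool:
    """Remove accidental motif trinucleotides, leaving planted triples untouched."""
    n = len(seq)
    for _ in range(max_passes):
        dirty = False
        for s in range(1, n - 1):  # 1-based trinucleotide start
            if s in planted_starts:
                continue
            if "".join(seq[s - 1 : s + 2]) not in patterns:
                continue
            dirty = True
            fixed = False
            for t in rng.permutation(3):
                idx = s - 1 + int(t)
                if idx in planted_idx:
                    continue
                for base in rng.permutation(list(RNA)):
                    if base == seq[idx]:
                        continue
                    old = seq[idx]
                    seq[idx] = base
                    # the mutation must clear this window and create no new motif
                    affected = range(max(1, s - 2), min(n - 1, s + 2) + 1)
                    if any(
                        w not in planted_starts
                        and "".join(seq[w - 1 : w + 2]) in patterns
                        for w in affected
                    ):
                        seq[idx] = old
                        continue
                    fixed = True
                    break
                if fixed:
                    break
            if not fixed:
                return False
        if not dirty:
            return True
    return False


def write_fixture(
    genome: NucSeq,
    features: Sequence[CdsFeature],
    truth: FixtureTruth,
    out_dir: str | Path,
    *,
    stem: str = "fixture",
) -> dict[str, Path]:
    """Write a synthetic fixture as FASTA + GFF3 + a JSON truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{stem}.fasta",
        "gff3": out / f"{stem}.gff3",
        "truth": out / f"{stem}.truth.json",
    }
    write_fasta([genome], paths["fasta"])
    write_gff3_cds(genome, features, paths["gff3"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
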