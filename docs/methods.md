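# Methods

## Pairing model

A mature type III crRNA carries an 8-nt 5′ handle, the transcript of the final
8 nt of the repeat. The handle is indexed −8…−1 with −1 adjacent to the spacer;
the PAS is the 8 nt immediately 3′ of the protospacer on the target mRNA,
indexed +1…+8, and pairing is antiparallel (+*i* ↔ −*i*). Base pairs are
classified Watson–Crick (A:U, U:A, G:C, C:G), wobble (G:U, U:G) or mismatch.

Two acceptance criteria are implemented:

- **full** (`paired_count ≥ min_paired`, default 6 of 8) — the criterion for
  selecting silencing protospacers;
- **minimal** (`minimal_ok`) — pairing at all of the configured minimal
  positions, default the contiguous set {−3, −4, −5}. For contiguous minimal
  sets the target-side trinucleotides are pre-enumerated
  (`minimal_motif_patterns`) as a fast path for the genome survey; equivalence
  with the positional definition is enforced by an exhaustive 64-trinucleotide
  test.

Whether wobble pairs count toward either criterion is configurable
(`wobble_counts_as_paired`, default on). The ≥ 6 selection rule is documented
for accepted designs that display G:U pairs, but whether the count included
wobble is not stated anywhere we know of; the default includes it and the
survey reports both settings. Ambiguity codes (N, R, …) are rejected by default
and treated as never-pairing when explicitly allowed, since no pairing
semantics for them is defined.

The handle, repeat, leader and backbone spacers are configuration inputs,
never hard-coded: they belong to the user's CRISPR locus. `RunConfig.example()`
generates a seeded synthetic demonstration backbone (24-nt repeat, 100-nt
leader, six 37-nt spacers) that is explicitly not a natural locus.

## Protospacer scanning and selection

Windows of `protospacer_length` (default 37 nt, the length used for targeting
spacers in the silencing experiments this toolkit models) are enumerated at
every start with 8 nt of downstream room. Candidates are ranked by
`paired_count` desc, then Watson–Crick-only count desc, then start asc — no
efficacy signal beyond PAS pairing is available (silencing strength is not
predictable from sequence; positions with favourable interaction energies have
still silenced poorly in practice), so the ranking orders by the only stated
quality signal and stays deterministic. Thermodynamic scoring is a pluggable
hook (`scorer` + `energy_threshold`, e.g. an RNAup-style ΔG per candidate);
without a scorer no energy filtering occurs.

Multiplex selection is greedy in rank order under a pairwise start-separation
constraint (default 2× protospacer length), returning picks in transcript
order; infeasible requests report the maximum feasible k (computed by a
position-sweep, which is optimal for pairwise-separation constraints on a
line). Off-target search is ungapped Hamming distance at every offset —
matching the mismatch-count criterion used to validate control spacers — not a
gapped aligner. Nonsense (control) spacers are rejection-sampled uniform RNA
(seeded) until the brute-force minimum mismatch count against every excluded
target exceeds the threshold (default > 20 mismatches for a 39-nt spacer; for a
random 39-mer against a 2.7-kb transcript the expected minimum over all offsets
sits near 20, so rejection genuinely filters).

## Genome survey

For each CDS the sense-strand mRNA is scanned for minimal-motif trinucleotides;
every position is tested independently (occurrences may overlap — the maximal
count is the conservative choice for "at least k occurrences"). With
`require_upstream_room` (default on) a motif at 1-based position p counts only
if a full protospacer fits 5′ of it (p − 1 ≥ protospacer_length + a − 1, where
−a is the minimal position closest to the spacer). Only the sense strand is
scanned: the PAS is a property of the targeted transcript. Because neither the
wobble nor the upstream-room convention of the original chromosome survey is
recorded, `survey_all_settings` reports all four combinations, and the report
echoes the annotation source. Percentages are kept unrounded internally.

## Locus assembly and crRNA maturation

A miniCR construct is leader + n spacers interleaved with n+1 identical repeats
(canonical array structure; the terminal repeat is retained). The default
assembly mode replaces backbone spacers 2–4 with the artificial spacers —
array D1, new…, D5, D6 for a six-spacer backbone; D6 is retained because
nothing indicates its removal. Transcription is modelled from the first repeat
(the leader carries the promoter and is not part of the transcript body; the
exact TSS is not modelled). Maturation yields one crRNA per spacer: the 8-nt
repeat-tail handle plus the full spacer transcript, 3′ untrimmed (3′ maturation
detail is heterogeneous in vivo and carries no design information). Spacers
containing the repeat as a substring are rejected — they would corrupt
processing.

## OE-PCR design and simulation

The modular construction route is modelled in three steps:

1. **Flank synthesis.** For each repeat of the new array, a forward primer
   (left spacer + 5′ repeat portion) and reverse primer (revcomp of 3′ repeat
   portion + right spacer) overlap by `overlap` nt (default 12) centred on the
   repeat midpoint; extension yields left + repeat + right. Each design is
   verified by an extension simulation (longest 3′ suffix/prefix match).
2. **Fusion and amplification.** Flanks join wherever one product's terminal
   spacer equals another's initial spacer (exact full-spacer match). The MOE
   primers (3′ arm of backbone spacer D1 + repeat, and revcomp(repeat + 5′ arm
   of D5); total 50 nt by default, giving 26-nt arms beside a 24-nt repeat)
   anchor the fragment in backbone sequence; the M primers are the spacer-side
   arms of the MOE primers, so only a correctly fused, end-to-end fragment
   amplifies. Duplicate spacers across units raise a fusion-ambiguity error;
   un-chainable unit sets raise a no-amplicon error.
3. **Megaprimer insertion.** The fragment's two arms must each occur exactly
   once on the circular template; the span between them is replaced by the
   fragment interior. An end-to-end test asserts the product reproduces direct
   assembly byte-for-byte over ≥ 50 random backbone/spacer sets.

Annealing is exact string matching of a primer's 3′-terminal region (default
12 nt); there is no melting-temperature model, which keeps verification
deterministic. DpnI template elimination, ligation and PCR stoichiometry
(200:1 fragment:template, 20–30 ng) carry no sequence information and are
recorded as protocol notes in primer reports only.

**Dosage route.** Repeated identical spacers defeat flank fusion, so dosage
constructs are built from a verified single-copy construct: inverse-PCR primers
linearise the plasmid at the spacer midpoint (outward-facing halves), and
long-overlap primers of composition half-spacer + repeat + full spacer
(80 nt for a 37-nt spacer and 24-nt repeat) extend it; the stated "one-and-a-
half spacer" length of such primers is reconciled with their ~80-nt total by
including the intervening repeat, which is the only composition that both
matches the length and regenerates the repeat between copies. The simulated
product is asserted equal to directly assembling the spacer list — route
independence.

## Quantification helpers

Standard curves are ordinary least squares of Ct on log10(copies) (≥ 3 points
spanning ≥ 2 log10 units); efficiency = 10^(−1/slope) − 1. ΔΔCt relative
expression uses result = 100 × (1 + E)^(−ΔΔCt) with E defaulting to 1.0
(base 2); a fitted efficiency (e.g. 0.94–1.00, the range typical of good runs)
can be supplied instead — both conventions are provided because reported
normalisations rarely state which was used. Replicate Cts are averaged
(arithmetic mean) before ΔΔCt; replicate SDs propagate in quadrature onto ΔΔCt
and map onto the percentage by the log-scale delta method. Copies-per-
chromosome is the ratio of back-calculated copies from two curves on one
sample. Relative consumption is (Δabsorbance)/chromosomes as percent of a
control; the medium blank cancels algebraically but is accepted for interface
fidelity. Significance testing is out of scope.

## Synthetic fixtures

Generators are fully seeded; identical seeds give byte-identical output.

- `synth_target_transcript` (default 2709 nt — the size of the α-amylase-scale
  target the defaults mirror) plants k windows whose PAS is the perfect
  Watson–Crick complement of the handle, pairwise ≥ 2× protospacer length
  apart (so default multiplex selection stays feasible), then scrubs the
  background: any other window reaching `min_paired` has one paired PAS base
  outside the planted PAS octamers resampled to a never-pairing base, iterated
  to a fixpoint (whole-layout retry on the rare unscrubbable configuration).
  Only the planted PAS octamers are immutable; protospacer bodies may be
  resampled, which does not affect the planted truth. Minimal-motif (3-mer)
  background occurrences are *not* scrubbed — the motif recurs every ~16 nt in
  random sequence — so planted-truth scans use full mode.
- `synth_cds_set` builds a genome of CDS with exact planted minimal-motif
  counts: planted 3-mers are drawn from the wobble-off pattern set while the
  background is scrubbed against the wobble-on superset, so per-CDS counts are
  invariant under either wobble setting; all planted sites leave full
  protospacer upstream room, so counts also hold under both upstream-room
  settings. Strands alternate +/− to exercise orientation handling; background
  GC is sampled at the requested fraction (held to ±3 points on ≥ 10 kb).

What the fixtures do not emulate: codon structure, real base composition
beyond GC, operons, repeats/low-complexity tracts, or any transcript secondary
structure. Passing tests therefore demonstrate correctness of the sequence
logic, not silencing efficacy on real genes — efficacy is explicitly not
predicted by this toolkit.

## Problem sizes and numerical choices

Tests run on transcripts of 0.6–2.7 kb, genomes of up to 100 CDS of 0.4–0.7 kb,
and 50 randomized OE-PCR round trips — sizes chosen so the full suite completes
in seconds while still exercising every code path at the realistic target scale
(2709 nt). Coordinates are 1-based inclusive internally and in GFF3/GenBank;
BED output is 0-based half-open. Ties in ranking are broken by transcript
position for determinism. Degenerate inputs (short transcripts) warn and return
empty rather than erroring, since an empty candidate set is a legitimate survey
outcome.

## Known limitations

- Off-target search is ungapped; bulged or gapped near-matches are unscored.
- No thermodynamics anywhere: crRNA:target ΔG is a plug-in hook, primer design
  has no Tm model.
- crRNA 3′ trimming and the exact transcription start are not modelled.
- The genome survey counts sense-strand CDS motifs only; intergenic and
  antisense sites are out of scope.
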