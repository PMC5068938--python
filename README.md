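# minicrkit

Design and in-silico verification of **miniCRISPR (miniCR) loci** for
post-transcriptional gene silencing with **type III CRISPR systems** in archaea.

## The problem

Type III CRISPR effector complexes (CSM/CMR) cleave RNA complementary to their
crRNA. In hyperthermophiles such as *Sulfolobus*, this can be turned into a gene
silencing tool: an engineered minimal CRISPR locus (leader + repeat–spacer
array) expressed from a vector supplies artificial crRNAs against a target
mRNA. The catch is that the same crRNA could also direct DNA interference
against the host chromosome. The escape hatch is the **protospacer-adjacent
sequence (PAS)**: when the 8 nt immediately 3′ of the protospacer on the target
RNA base-pair the crRNA's 8-nt repeat-derived **5′ handle**, the complex reads
the target as "self" at the DNA level — DNA interference is suppressed while RNA
cleavage proceeds. Handle positions are numbered −8…−1 (−1 adjacent to the
spacer) and pair antiparallel: target position +*i* pairs handle position −*i*.
G:U wobble pairs count as pairing by default.

Two acceptance criteria are supported:

- **full** — the PAS pairs ≥ 6 of the 8 handle positions (the criterion used to
  pick real silencing protospacers);
- **minimal** — pairing only at handle positions −3/−4/−5, a 3-nt motif that is
  already sufficient to suppress DNA cleavage and occurs in essentially every
  coding sequence, which is what the genome survey quantifies.

## What the toolkit does

- `minicrkit.pairing` — handle/PAS pairing rules, wobble handling, minimal-motif
  enumeration.
- `minicrkit.scan` — protospacer enumeration, ranking, multiplex selection,
  ungapped off-target search, nonsense (control) spacer generation with
  brute-force > 20-mismatch verification.
- `minicrkit.survey` — per-CDS minimal-PAS-motif counts and genome-level
  fractions, under both wobble and upstream-room conventions.
- `minicrkit.assembly` — miniCR locus assembly (single, multiplex, dosage),
  transcription and crRNA maturation simulation, structural validation.
- `minicrkit.oepcr` — modular overlap-extension PCR design (flank, MOE and M
  primers; the inverse-PCR dosage route) and full in-silico verification:
  flank fusion, M-primer amplification, megaprimer whole-plasmid insertion.
- `minicrkit.quant` — qPCR standard curves, ΔΔCt relative expression,
  copies-per-chromosome, relative substrate consumption.
- `minicrkit.synth` — seeded synthetic genomes/transcripts with planted,
  truth-tracked PAS sites, so everything is testable without downloads.
- `minicrkit.cli` — `minicrkit scan|design|survey|assemble|primers|simulate|quant|fixtures|config-init`.

## Worked example

```python
import minicrkit as mk

cfg = mk.RunConfig.example(7)        # synthetic demo backbone (not a natural locus)
handle = cfg.handle()                # AUACUCCC, from repeat TGGTGTTAACCTTACTATACTCCC

tx, truth = mk.synth_target_transcript(2709, 5, handle, seed=7)
cands = mk.scan_transcript(tx, handle, cfg.scan_config())
picks = mk.select_multiplex(cands, 5)
```

The five selected 37-nt protospacers (fully handle-paired PAS, `|` = Watson-Crick):

```
 start_1based  end_1based  paired_count  pairing      pas
         1370        1406             8 |||||||| GGGAGUAU
         1553        1589             8 |||||||| GGGAGUAU
         1768        1804             8 |||||||| GGGAGUAU
         2347        2383             8 |||||||| GGGAGUAU
         2531        2567             8 |||||||| GGGAGUAU
```

Each PAS (`GGGAGUAU`, read +1…+8) is the antiparallel complement of the handle
(`AUACUCCC`, −8…−1). Assembling the quintuple construct and simulating crRNA
maturation:

```python
spacers = [mk.NamedSpacer(f"AA{i+1}", mk.seqio.as_dna(c.spacer_rna))
           for i, c in enumerate(picks)]
construct = mk.assemble_minicr(cfg.backbone(), spacers, name="miniCR-AA12345")
crrnas = mk.mature_crrnas(construct)
```

prints an array `D1, AA1..AA5, D5, D6` with 9 repeats (n spacers ⇒ n+1 repeats)
and 8 mature crRNAs, each starting with the 8-nt handle `AUACUCCC`. A nonsense
control spacer is generated and verified against the target:

```python
z = mk.generate_nonsense_spacer(39, [tx], threshold=20, rng_seed=8)
mk.min_mismatches(z, tx)             # -> 21  (> 20 at every ungapped offset)
```

`minicrkit simulate` additionally verifies the whole OE-PCR construction route:
the designed flank units are fused in silico, amplified with the M primers, and
inserted into a circular template as a megaprimer; the product must reproduce
the directly assembled locus byte-for-byte.

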