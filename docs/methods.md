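# Methods

## Model and procedure

`spliceff` estimates, for every annotated intron, the ratio of spliced to
unspliced molecules at each of the two splice junctions of the intron:

* **Spliced evidence** — the transread count: reads whose alignment skips
  the intron with an N CIGAR gap that exactly matches a known intron's
  coordinates.  A transread necessarily covers the last base of the
  upstream exon and the first base of the downstream exon, so it testifies
  that this particular intron was removed.
* **Unspliced evidence** — the number of sense-strand reads whose aligned
  blocks cover the single terminal intron base (the first base for the 5′
  site, the last base for the 3′ site).  Using one base rather than a
  window keeps the two signals at the same junction-level resolution, makes
  the estimate robust to introns that host stable nested ncRNAs or are
  retained after splicing along their interior, and mirrors the RT-qPCR
  design of junction-spanning amplicons.

The ratio at the 5′ site tracks the first catalytic step, at the 3′ site
the second.  Both counts come from the same library, so sequencing depth
cancels and no between-sample normalisation is needed; relative
efficiencies (test/reference) are plain ratios of the per-sample values.

Assumptions worth stating: the annotation's introns are the introns
(novel junctions are reported but not folded into efficiencies); the
library is strand-specific and single-end (mate information is ignored);
read placement within a transcript is approximately uniform near the
junction, so the per-base counts are comparable between the two templates;
and MAPQ ≥ 10 primary alignments represent unambiguous unique mappings.

## Pipeline stages

1. **annotation** — introns are inferred as gaps between consecutive exons
   of each GTF transcript and deduplicated across transcripts by
   `(chrom, start, end, strand)`.  Explicit intron features, if present,
   are ignored; exon features are the universal denominator across GTF
   dialects.  Coordinates are 0-based half-open internally (GTF converted
   on read, BED written natively) so there is exactly one convention to
   reason about.
2. **alignments** — unmapped, secondary and supplementary records are
   dropped, then MAPQ < 10 records; duplicates are deliberately kept (the
   method operates on raw unique-mapper counts).  Each survivor is
   decomposed into reference blocks split on N gaps; deletions stay inside
   a block because the read still spans those positions on the reference.
3. **junctions** — every gap with length in [20, 10000] nt and at least 8
   aligned bases on each flanking block counts one transread for its
   junction; a read with several qualifying gaps supports each
   independently.  Junctions are classified against the annotation: exact
   match → `known`; one boundary matching an annotated splice site → the
   class names the unannotated side (strand-aware: on `-` the donor is the
   high-coordinate boundary); both boundaries from different introns →
   `novel_pair`; otherwise `novel`.  Identical intron coordinates annotated
   on both strands are flagged `ambiguous` and kept out of the known set.
4. **coverage** — sense-strand reads with a block over each terminal base,
   per sample.  `forward` strandedness counts reads on the transcript
   strand, `reverse` (dUTP-style protocols) the opposite; there is no
   default because a silently wrong setting would count antisense signal.
5. **efficiency** — ratios, the confidence rule, pooling, pairs, tables,
   scatterplots.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_mapq` | 10 | unique-mapper threshold (inclusive) |
| `min_intron`, `max_intron` | 20, 10000 nt | plausible yeast intron length bounds for junction gaps |
| `min_anchor` | 8 | aligned bases required on each side of a gap; the default of the junction-extraction tools commonly used for this task, kept for comparability — transread counts are anchor-sensitive, so report the value used |
| `min_transreads`, `min_coverage` | 5, 5 | confidence rule: a record is confident only when **both** counts reach their threshold (inclusive); this conjunctive reading is the operational one and matches how low-coverage junctions destabilise the ratio in either direction |
| `strandedness` | *(required)* | `forward` or `reverse`, must match the library protocol |

Undefined efficiencies (zero terminal coverage) are written as `NA`, never
as infinity; they also fail the coverage threshold, so they can never be
confident.  Pooling replicates sums raw counts *before* the ratio — this is
the ratio of pooled molecules, is well defined at low counts, and lets
replicates that are individually below threshold jointly clear it
(averaging per-replicate ratios would do neither).

## The simulator

`spliceff.simulate` emulates the measurement, not the sequencer: an
error-free, strand-specific, single-end experiment over two-exon (by
default) genes with known spliced fraction `p`.  Reads start at each
template position with Poisson rate `(depth/L)·p` on the spliced mRNA and
`(depth/L)·(1 − p)` on the pre-mRNA, where `depth` is the expected per-base
coverage of a single-template gene.  Spliced reads crossing the junction
receive an N gap of exactly the intron length; a configurable fraction of
decoy reads carries MAPQ 3 to exercise the filter.  Canonical GT..AG intron
ends are written into the genome FASTA for realism but no computation reads
base identities.

Under this model the expected efficiency has the closed form

```
E[efficiency] → p·(L − 2a + 1) / ((1 − p)·L)
```

because a junction collects transreads from the `L − 2a + 1` start
positions leaving ≥ `a` bases on each side, while a terminal base is
covered from exactly `L` pre-mRNA start positions (guaranteed when flanking
exons are at least `L` long, which the default layout — 300 nt exons,
150 nt introns, 100 nt reads — satisfies).  The factor `(L − 2a + 1)/L`
shows the estimator's anchor-induced downward bias relative to the
molecular ratio `p/(1 − p)`; it cancels exactly in relative efficiencies.
The test suite verifies the closed form against brute-force enumeration of
every read start position, and the parameter-recovery tests require the
full pipeline to land within 3 binomial standard errors
(`eff·sqrt(1/T + 1/C)` at the realized counts) of it for every gene at
500× depth.

What the simulator does **not** model: sequencing errors, indels, mappability
variation, positional coverage bias (e.g. 3′ bias from degraded RNA),
overlapping antisense transcription, multi-mapping ambiguity beyond flat
low-MAPQ decoys, and alternative or recursive splicing.  Passing tests
therefore demonstrate that the counting and ratio machinery is exact and
that the estimator converges as designed — not that real libraries are free
of the coverage pathologies that, as with any junction-based method, can
make particular genes' efficiencies uninformative.

## Numerical and design choices

* Internal coordinates are 0-based half-open throughout; a block ending at
  position `x` does not cover `x`.
* The junction key is `(chrom, start, end)`; strand is taken from the
  annotation, since single-end reads may carry no splice-strand signal.
* Per-gene reporting uses the lexicographically smallest gene id among a
  deduplicated intron's contributing transcripts.
* Length-1 introns are legal; both terminal bases then coincide.
* Scatterplots are log10–log10 with zero/undefined points excluded and
  counted in the margin rather than pseudocounted, so plotted values equal
  table values exactly; confident points are filled, low-confidence open.
* Filtering, junction counting and coverage counting are all invariant to
  the ordering of the input stream (asserted by tests).
* Problem sizes in tests and the acceptance script — 50 fixtures of ≤ 200
  reads for exactness checks, 20 genes at 500× depth for recovery — were
  chosen as the smallest sizes at which the 3-SE tolerance is meaningfully
  tight while the suite stays quick to run.

## Known limitations

* Single-end semantics only; paired-end data should be reduced to read 1.
* GTF only (attribute layout `gene_id "X"; transcript_id "Y";`); no GFF3.
* No differential-splicing significance testing; the outputs are ratios
  and scatterplots, and replicate agreement is assessed visually.
* Efficiencies can exceed 1 by construction (they estimate a spliced:
  unspliced molecule ratio scaled by `(L − 2a + 1)/L`, not a fraction
  spliced).
* Genes whose intron terminal bases fall in repetitive sequence lose
  coverage to the MAPQ filter, deflating the denominator; inspect the
  `_all` tables' raw counts when a value looks surprising.
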