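# Methods

This note documents the models and procedures `asmcurate` implements,
the conventions and numerical choices behind them, and what the
synthetic fixtures do and do not emulate.

## Coordinate and strand conventions

All intervals are 1-based and inclusive at both ends (the GFF
convention); an exon `[start, end]` has length `end − start + 1`.
Any half-open arithmetic is confined to the format converters in
`asmcurate.io`. Strands are `+`/`−`; wherever a rule is phrased "in
transcript orientation" (splice consensus, 3′ ends), minus-strand
genomic dinucleotides are reverse-complemented before comparison and the
3′ terminus of a minus-strand transcript is its smallest coordinate.

## Contamination screening

The screen models a two-stage decontamination. Stage one is an external
k-mer classifier whose output arrives as a contig → label manifest; the
screen consumes it as ground truth (labels `target_species` and
`unclassified` retain, `bacteria` drops — re-running the classifier is
out of scope). Stage two adjudicates `flagged` contigs from their
nucleotide BLAST hits (standard 12-column tabular output plus a
subject-taxid column):

1. bitscores are summed per subject taxid over all hits with
   e-value strictly below `evalue_max` (default 1 × 10⁻²⁵; "below" is a
   strict inequality, so a hit exactly at the threshold is excluded);
2. the contig is assigned the taxid with the highest summed score
   (ties break to the smallest taxid, for determinism);
3. the contig is retained when the assigned taxon's lineage contains
   the retain clade — `(rank, name)` defaults to `(order, Rodentia)` —
   or when no hit passed the threshold; otherwise it is dropped.

The summed-bitscore statistic rewards consistent, high-quality coverage
of a contig by one taxon over a single spurious strong hit. The rule
"retain on hits to the retain clade" is read as *the assigned (top
summed-score) taxon lies in the clade*; the looser reading — any single
passing hit in the clade rescues the contig — is available as
`ScreenPolicy(any_hit_mode=True)`. Multi-taxid BLAST cells
(semicolon-joined `staxids`) take the first taxid and log a warning.
Taxonomy arrives as a flat taxid → ranked-lineage TSV; parsing NCBI
taxonomy dumps is deliberately out of scope, the TSV is the interchange
point.

Every contig receives exactly one audit record (prior label, per-taxid
sums, assigned taxon, verdict, reason), so |retained| + |dropped| =
|input| by construction and the verdict can be reproduced from the
record alone.

## Annotation cleanup

Homology-based gene prediction transfers models from reference species
and infers UTRs from mapped RNA-seq; both steps leave systematic
defects. The pipeline applies five rules in a fixed order (the order in
which the defects are naturally described; permuting rules can change
the output, so the order is part of the contract):

1. **Name resolution per locus.** The locus's highest-scoring transcript
   (prediction score from the GFF score column, falling back to a
   configurable attribute) defines the locus's gene name; transcripts
   carrying a different name are removed. Score ties keep the earlier
   transcript in input order; the top transcript always survives, so a
   locus is never emptied by this rule.
2. **Locus deduplication per name.** When several loci share a gene
   name, only the one whose top transcript scores highest survives.
   Ties break to the smaller leftmost coordinate, then the smaller
   locus id. Unnamed loci are exempt.
3. **Shared-exon trimming.** An exon with identical
   (seqid, start, end, strand) owned by transcripts of two different
   genes is a fusion artifact of UTR inference; it is trimmed from
   every owner. Identity is exact equality, not overlap — overlap-based
   merging would exceed the rule. CDS intervals contained in a trimmed
   exon are removed with it and logged separately; transcripts left
   with no exons, and loci left with no transcripts, are dropped.
   Exons shared between isoforms of the *same* gene are untouched.
4. **Structural filter.** Transcripts with any exon strictly shorter
   than `min_exon_len` (default 15 bp — a 15 bp exon passes) or any
   intron whose donor/acceptor dinucleotides, read in transcript
   orientation, fall outside the canonical set are eliminated. The
   default canonical set is GT–AG only; GC–AG and AT–AC (rare
   minor-spliceosome forms) can be admitted via configuration. Introns
   shorter than 4 bp cannot carry both dinucleotides and are treated as
   noncanonical.
5. **Isoform deduplication.** Within a locus, isoforms with identical
   ordered exon-boundary lists collapse to the one with the longest
   total (spliced) CDS; ties keep the lexicographically smallest
   transcript id.

The pipeline is idempotent: each rule's postcondition is preserved by
all later rules, so `curate(curate(x)) = curate(x)` (checked per seed in
the tests). The report conserves counts:
`transcripts_in = transcripts_out + Σ transcripts_removed`, with a
locus removal also logging one removal per member transcript.

## 3′ UTR extension

Droplet scRNA-seq reads concentrate near transcript 3′ ends; when the
annotated 3′ UTR ends too early, downstream reads go unassigned. The
remedy: extend each transcript's 3′-terminal exon outward by
`extension_bp` (default 1,000) whenever its *downstream gap* is at
least `min_gap_bp` (default 3,000; "at least" is inclusive, so a
3,000 bp gap extends).

The downstream gap is the number of bases between the transcript's 3′
end and the start of the nearest *gene-locus span* lying strictly 3′ of
it on the same contig, either strand, excluding the transcript's own
gene (using locus spans rather than individual exons avoids
self-collisions and matches the intent "next annotated feature"). With
no such feature the gap is the distance to the contig end, flagged
`bounded_by_contig`; such transcripts extend as far as the contig
allows (there is nothing to collide with), and the clamp is logged
distinctly.

All gaps are computed against the pre-extension annotation and applied
in one pass. Because `extension_bp < min_gap_bp` is enforced as a
parameter invariant, every extended transcript retains a gap of at
least `min_gap_bp − extension_bp` (2,000 bp at defaults) to its
original downstream neighbor — extensions can never create overlaps,
and the result is independent of iteration order. Extension moves only
the one terminal exon boundary: exon count, CDS coordinates and strand
are untouched. Gene spans are defined as the union of member
transcripts and follow automatically.

`quantify_extension_effect` summarises before/after per-gene count
tables (missing genes count as zero): percent total increase
`100·(Σafter − Σbefore)/Σbefore`; newly detected genes (zero before,
any reads after — "any read" is the detection criterion); and genes
detected before whose count grew by at least the gain threshold
(default 20%, inclusive). A zero total before the extension makes the
percentage undefined and raises.

## Contiguity and completeness summaries

N50/L50 follow the cumulative convention of standard assembly QC tools:
sort lengths descending; the first contig at which the running sum
reaches **at least** half the total is the N50 contig (its length is
N50, its 1-based rank is L50). Equal lengths are interchangeable, so
tie order cannot affect the outputs. Thresholded panels report
`|{ℓ ≥ t}|` and `Σ{ℓ : ℓ ≥ t}` for thresholds (0, 25,000, 50,000) by
default.

BUSCO short-summary files are parsed by their labelled count lines; the
validator checks the two category identities, complete = single +
duplicated and total = complete + fragmented + missing, and reports the
recomputed sums rather than raising, since an inconsistent summary is a
data finding.

## Synthetic fixtures

The generators emit every input the toolkit consumes — contig FASTA,
prior-label manifest, BLAST tabular hits, lineage TSV, GFF3 annotation,
BUSCO summary — with a JSON ledger of the planted truth. One integer
seed drives a `random.Random` stream for structural choices and a numpy
generator (seeded from it) for nucleotide content; the same seed and
parameters yield byte-identical files.

**Screening fixtures** default to the category counts of the motivating
study: 2,028 target-species, 3 unclassified, 3 bacterial and 74 flagged
contigs, of which 47 adjudicate to retain — so the default screen
retains 2,078 contigs. Retainable flagged contigs alternate between the
two retention modes (rodent top summed score vs. no hit passing the
threshold, including some with no hits at all); droppable ones get a
human top score, some with a weaker rodent hit so the assigned-vs-any-hit
distinction stays observable. Contig lengths are uniform in 1–50 kb:
large enough for realistic length statistics, small enough that the
full-scale fixture generates in seconds. The paper-scale contiguity
values (multi-megabase N50) are *not* emulated — they require the real
sequencing data — so contiguity statistics are validated against an
independent oracle on random lengths instead.

**Annotation fixtures** lay 2–3-exon genes left to right on one contig
with inter-gene gaps drawn from {1,500, 2,500, 2,999, 3,000, 3,500,
6,000} bp; the first two gaps are always 2,999 and 3,000 and the first
three genes sit on the forward strand, so the UTR gate boundary is
exercised in transcript orientation for every seed. Introns of
non-defective transcripts carry planted GT–AG (genomic CT–AC on the
minus strand); defects are planted one entity each — a name-conflict
transcript, a duplicate-named locus, an exact shared exon between two
adjacent forward-strand genes (with canonical splice sites into it from
both owners), a 14 bp exon, an AA–CC intron, an identical-boundary
isoform with a shorter CDS — and recorded in the ledger, so tests can
require 100% planted-defect recovery with zero spurious actions. What
the fixtures do *not* emulate: realistic gene content or codon
structure, overlapping or nested genes, alternative splicing beyond the
planted isoforms, sequencing error, or reads (the assignment-delta
metrics take count tables as input). Passing tests therefore
demonstrate the correctness of the decision logic and bookkeeping, not
performance on real genomes.

## Problem sizes

The test suite and the acceptance script run the screening pipeline at
the full published category counts (2,108 contigs, ~50 Mbp of sequence,
a few seconds), the curation and extension pipelines on 10–20-gene
fixtures across ≥ 20 seeds, and the statistics against a quadratic
oracle at 1,000 lengths; the whole suite completes in well under a
minute.
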