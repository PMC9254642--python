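# asmcurate

A post-assembly curation toolkit for de novo genome projects. After the
heavy lifting — long-read assembly, polishing, k-mer contamination
classification, homology-based gene prediction — a set of small but
consequential bespoke steps decides what ends up in the released
assembly and annotation. `asmcurate` implements those steps as a tested,
reusable library and command-line tool:

* **Contig decontamination by BLAST bitscore adjudication.** An upstream
  k-mer classifier labels each contig (target species, unclassified,
  bacteria, or flagged as a possible contaminant, e.g. human). Bacterial
  contigs are dropped and target/unclassified contigs kept outright. For
  each flagged contig the nucleotide BLAST bitscores are summed per
  subject taxon over all hits with e-value < 10⁻²⁵; the contig is
  assigned the taxon with the highest summed score and retained iff that
  taxon's lineage lies in a retain clade (default: order Rodentia) or no
  hit passed the threshold at all.
* **Rule-based cleanup of homology-predicted gene models** (GeMoMa-style
  GFF3/GTF with per-transcript prediction scores and transferred gene
  symbols), applied in a fixed order: (1) within a locus keep only
  transcripts sharing the top-scoring transcript's gene name; (2) when
  one name claims several loci keep the locus with the higher top score;
  (3) trim exons shared between different genes (UTR-inference fusion
  artifacts); (4) eliminate transcripts with exons < 15 bp or
  noncanonical (non-GT–AG) splice consensus; (5) collapse
  identical-boundary isoforms to the longest CDS.
* **Distance-gated 3′ UTR extension** for 3′-biased read assignment:
  every transcript's 3′-terminal exon is extended by a constant 1,000 bp
  whenever the distance to the next annotated feature (either strand) is
  ≥ 3,000 bp, plus delta metrics (% assigned-read increase, newly
  detected genes, genes gaining ≥ 20%) over per-gene count tables.
* **Assembly summary statistics**: thresholded contig counts/lengths,
  N50/L50 (cumulative ≥ ½-total convention), and a BUSCO short-summary
  parser with category-arithmetic validation (C = S + D,
  C + F + M = n).
* **Seeded synthetic-fixture generators** emitting every input format
  with a planted-truth ledger, so all pipelines are testable end to end
  without any downloads.

## Worked example

Generate a small screening fixture (46 contigs: 30 target-species, 3
unclassified, 3 bacteria, 10 flagged of which 6 carry retention
evidence) and screen it:

```bash
asmcurate simulate assembly --seed 2 --out asm \
    --n-target 30 --n-flagged 10 --n-flagged-retain 6
asmcurate screen --fasta asm/assembly.fa --manifest asm/labels.tsv \
    --blast asm/hits.tsv --lineage asm/lineage.tsv \
    --out cleaned.fa --report decisions.tsv
asmcurate stats --fasta cleaned.fa --out stats.tsv
```

prints

```
retained 39 of 46 contigs (7 dropped)
N50 34,250  L50 15  contigs 39
```

39 = 30 target + 3 unclassified + 6 flagged contigs that adjudicate to
retain (rodent top score or no hit passing the threshold); the 7
dropped are the 3 bacterial contigs and the 4 flagged contigs whose top
summed bitscore belongs to a non-rodent taxon.
`decisions.tsv` is a per-contig audit trail
(prior label, assigned taxon, top score, verdict, reason).

Annotation cleanup and UTR extension work the same way:

```bash
asmcurate simulate annotation --seed 3 --out ann --n-genes 12 --defects 1
asmcurate curate --gff ann/annotation.gff3 --genome ann/genome.fa \
    --out curated.gff3 --report curation.tsv
asmcurate extend-utrs --gff curated.gff3 --genome ann/genome.fa \
    --out extended.gff3 --log extension.tsv
```

```
loci 12 -> 9; transcripts 14 -> 9
extended 7 of 9 transcripts
```

One defect of each kind was planted: the name-conflict transcript, the
duplicate-named locus, the shared exon, the sub-15 bp exon, the
noncanonical intron and the redundant isoform are each acted on by
exactly one rule (see `curation.tsv`), and the extension log records
each transcript's downstream gap and the bases applied.

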