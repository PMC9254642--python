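"""Rule-based cleanup of homology-predicted gene models.

Homology-based predictors transfer gene models from reference species;
the transfer leaves characteristic defects: loci whose isoforms carry
conflicting source gene symbols, the same symbol claimed by several
loci, UTR-inference fusions that make two genes share an exon, models
with implausibly short exons or noncanonical introns, and redundant
isoforms with identical exon boundaries. The pipeline removes each class
of defect in a fixed order:

1. within each locus, keep only transcripts sharing the gene name of the
   locus's top-scoring transcript;
2. when one gene name is claimed by several loci, keep only the locus
   with the higher top score;
3. trim exons shared (identical coordinates) between different genes
   from every owning transcript;
4. eliminate transcripts with an exon shorter than a minimum length
   (default 15 bp) or an intron whose splice consensus is noncanonical;
5. within each locus, collapse isoforms with identical exon boundaries
   to the one with the longest coding sequence.

Running the pipeline twice equals running it once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .model import (
    AsmcurateError,
    Contig,
    ExonInterval,
    GeneLocus,
    TranscriptModel,
)

#: donor/acceptor dinucleotide pairs accepted as canonical, read in
#: transcript orientation. GT-AG covers the overwhelming majority of
#: introns; GC-AG and AT-AC are rare minor-spliceosome variants that can
#: be admitted via CurationParams.splice_canon.
GT_AG = ("GT", "AG")
GC_AG = ("GC", "AG")
AT_AC = ("AT", "AC")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CurationParams:
    min_exon_len: int = 15
    splice_canon: tuple[tuple[str, str], ...] = (GT_AG,)


@dataclass
class CurationAction:
    rule: str
    entity_id: str
    action: str


@dataclass
class CurationReport:
    """Audit trail of the pipeline: per-rule counters plus an ordered log."""

    transcripts_removed: dict[str, int] = field(
        default_factory=lambda: defaultdict(int)
    )
    loci_removed: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    exons_trimmed: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    log: list[CurationAction] = field(default_factory=list)
    transcripts_in: int = 0
    transcripts_out: int = 0
    loci_in: int = 0
    loci_out: int = 0

    def record(self, rule: str, entity_id: str, action: str) -> None:
        self.log.append(CurationAction(rule, entity_id, action))
        if action == "transcript_removed":
            self.transcripts_removed[rule] += 1
        elif action == "locus_removed":
            self.loci_removed[rule] += 1
        elif action == "exon_trimmed":
            self.exons_trimmed[rule] += 1

    def total_transcripts_removed(self) -> int:
        return sum(self.transcripts_removed.values())

    def actions_for(self, rule: str) -> list[CurationAction]:
        return [a for a in self.log if a.rule == rule]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tentity_id\taction\n")
            for a in self.log:
                fh.write(f"{a.rule}\t{a.entity_id}\t{a.action}\n")


class CurationError(AsmcurateError):
    pass


# ---------------------------------------------------------------------------
# Rule 1: one gene name per locus


def resolve_locus_gene_names(
    locus: GeneLocus, report: CurationReport | None = None
) -> GeneLocus:
    """Keep only transcripts whose gene name matches the top scorer's.

    The top scorer is the highest-scoring transcript, ties keeping input
    order, so the locus is never emptied.
    """
    top = locus.top_transcript()
    keep = [t for t in locus.transcripts if t.gene_name == top.gene_name]
    if report is not None:
        for t in locus.transcripts:
            if t.gene_name != top.gene_name:
                report.record("resolve_gene_names", t.id, "transcript_removed")
    if len(keep) == len(locus.transcripts):
        return locus
    return GeneLocus(
        id=locus.id, seqid=locus.seqid, strand=locus.strand, transcripts=keep
    )


# ---------------------------------------------------------------------------
# Rule 2: one locus per gene name


def dedupe_named_loci(
    annotation: list[GeneLocus], report: CurationReport | None = None
) -> list[GeneLocus]:
    """When a gene name is claimed by several loci keep only the locus
    whose top transcript scores highest.

    Ties break to the locus with the smaller leftmost coordinate, then
    to the lexicographically smaller locus id. Unnamed loci are exempt.
    """
    by_name: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in annotation:
        name = locus.top_transcript().gene_name
        if name is not None:
            by_name[name].append(locus)

    losers: set[str] = set()
    for name, group in by_name.items():
        if len(group) < 2:
            continue
        winner = min(
            group,
            key=lambda loc: (-loc.top_transcript().score, loc.span[0], loc.id),
        )
        for loc in group:
            if loc is not winner:
                losers.add(loc.id)
                if report is not None:
                    report.record("dedupe_named_loci", loc.id, "locus_removed")
                    for t in loc.transcripts:
                        report.record("dedupe_named_loci", t.id, "transcript_removed")
    return [loc for loc in annotation if loc.id not in losers]


# ---------------------------------------------------------------------------
# Rule 3: exons shared between genes are fusion artifacts


def strip_shared_exons(
    annotation: list[GeneLocus], report: CurationReport | None = None
) -> list[GeneLocus]:
    """Trim any exon with identical (seqid, start, end, strand) present
    in transcripts of two or more different gene loci.

    The exon is removed from every owning transcript; CDS intervals
    contained in a trimmed exon are removed with it (logged when that
    happens); a transcript left without exons is dropped, and a locus
    left without transcripts is dropped.
    """
    owners: dict[tuple[str, int, int, str], set[str]] = defaultdict(set)
    for locus in annotation:
        for tx in locus.transcripts:
            for ex in tx.exons:
                owners[(locus.seqid, ex.start, ex.end, locus.strand)].add(locus.id)
    shared = {key for key, genes in owners.items() if len(genes) > 1}
    if not shared:
        return annotation

    out: list[GeneLocus] = []
    for locus in annotation:
        new_txs: list[TranscriptModel] = []
        locus_touched = False
        for tx in locus.transcripts:
            doomed = [
                ex
                for ex in tx.exons
                if (locus.seqid, ex.start, ex.end, locus.strand) in shared
            ]
            if not doomed:
                new_txs.append(tx)
                continue
            locus_touched = True
            doomed_set = {(ex.start, ex.end) for ex in doomed}
            kept_exons = [
                ex for ex in tx.exons if (ex.start, ex.end) not in doomed_set
            ]
            kept_cds = []
            for c in tx.cds:
                in_doomed = any(s <= c.start and c.end <= e for s, e in doomed_set)
                if in_doomed:
                    if report is not None:
                        report.record(
                            "strip_shared_exons", tx.id, "cds_trimmed_with_exon"
                        )
                else:
                    kept_cds.append(c)
            if report is not None:
                for _ in doomed:
                    report.record("strip_shared_exons", tx.id, "exon_trimmed")
            if not kept_exons:
                if report is not None:
                    report.record("strip_shared_exons", tx.id, "transcript_removed")
                continue
            new_txs.append(
                TranscriptModel(
                    id=tx.id,
                    gene_id=tx.gene_id,
                    seqid=tx.seqid,
                    strand=tx.strand,
                    score=tx.score,
                    exons=kept_exons,
                    cds=kept_cds,
                    gene_name=tx.gene_name,
                )
            )
        if not new_txs:
            if report is not None:
                report.record("strip_shared_exons", locus.id, "locus_removed")
            continue
        if locus_touched:
            out.append(
                GeneLocus(
                    id=locus.id,
                    seqid=locus.seqid,
                    strand=locus.strand,
                    transcripts=new_txs,
                )
            )
        else:
            out.append(locus)
    return out


# ---------------------------------------------------------------------------
# Rule 4: structural plausibility (exon length, splice consensus)


def intron_dinucleotides(
    tx: TranscriptModel, sequence: str
) -> list[tuple[str, str]]:
    """Donor/acceptor dinucleotides of every intron, in transcript
    orientation (reverse-complemented on the minus strand), 5' to 3'.
    """
    pairs = []
    for lo, hi in tx.introns():
        if hi > len(sequence):
            raise CurationError(
                f"{tx.id}: intron end {hi} exceeds contig length {len(sequence)}"
            )
        if hi - lo + 1 < 4:
            # too short to carry both consensus dinucleotides
            pairs.append(("NN", "NN"))
            continue
        left = sequence[lo - 1 : lo + 1].upper()
        right = sequence[hi - 2 : hi].upper()
        if tx.strand == "+":
            pairs.append((left, right))
        else:
            pairs.append((revcomp(right), revcomp(left)))
    if tx.strand == "-":
        pairs.reverse()
    return pairs


def filter_structural(
    annotation: list[GeneLocus],
    genome: dict[str, Contig] | list[Contig],
    params: CurationParams = CurationParams(),
    report: CurationReport | None = None,
) -> list[GeneLocus]:
    """Eliminate transcripts with an exon shorter than ``min_exon_len``
    (strictly shorter: a 15 bp exon passes at the default) or any intron
    whose donor/acceptor consensus is not in ``splice_canon``.

    A locus whose transcripts are all eliminated is removed.
    """
    if isinstance(genome, list):
        genome = {c.id: c for c in genome}
    canon = set(params.splice_canon)
    out: list[GeneLocus] = []
    for locus in annotation:
        contig = genome.get(locus.seqid)
        if contig is None or contig.sequence is None:
            raise CurationError(f"no sequence for contig {locus.seqid}")
        if locus.span[1] > contig.length:
            raise CurationError(
                f"locus {locus.id} exceeds contig {locus.seqid} length"
            )
        keep: list[TranscriptModel] = []
        for tx in locus.transcripts:
            if any(ex.length < params.min_exon_len for ex in tx.exons):
                if report is not None:
                    report.record("filter_structural", tx.id, "transcript_removed")
                continue
            dinucs = intron_dinucleotides(tx, contig.sequence)
            if any(pair not in canon for pair in dinucs):
                if report is not None:
                    report.record("filter_structural", tx.id, "transcript_removed")
                continue
            keep.append(tx)
        if not keep:
            if report is not None:
                report.record("filter_structural", locus.id, "locus_removed")
            continue
        if len(keep) == len(locus.transcripts):
            out.append(locus)
        else:
            out.append(
                GeneLocus(
                    id=locus.id,
                    seqid=locus.seqid,
                    strand=locus.strand,
                    transcripts=keep,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Rule 5: identical-boundary isoforms


def dedupe_identical_isoforms(
    locus: GeneLocus, report: CurationReport | None = None
) -> GeneLocus:
    """Among isoforms with identical ordered exon boundaries keep the one
    with the longest total (spliced) CDS; ties keep the lexicographically
    smallest transcript id."""
    groups: dict[tuple[tuple[int, int], ...], list[TranscriptModel]] = defaultdict(
        list
    )
    for tx in locus.transcripts:
        groups[tx.exon_boundaries()].append(tx)
    doomed: set[str] = set()
    for txs in groups.values():
        if len(txs) < 2:
            continue
        winner = min(txs, key=lambda t: (-t.cds_length(), t.id))
        for t in txs:
            if t is not winner:
                doomed.add(t.id)
                if report is not None:
                    report.record(
                        "dedupe_identical_isoforms", t.id, "transcript_removed"
                    )
    if not doomed:
        return locus
    return GeneLocus(
        id=locus.id,
        seqid=locus.seqid,
        strand=locus.strand,
        transcripts=[t for t in locus.transcripts if t.id not in doomed],
    )


# ---------------------------------------------------------------------------
# The pipeline


def curate(
    annotation: list[GeneLocus],
    genome: dict[str, Contig] | list[Contig],
    params: CurationParams = CurationParams(),
) -> tuple[list[GeneLocus], CurationReport]:
    """Run the five cleanup rules in their fixed order and tally every
    action. The input annotation is not modified."""
    report = CurationReport()
    report.loci_in = len(annotation)
    report.transcripts_in = sum(len(l.transcripts) for l in annotation)

    current = [resolve_locus_gene_names(l, report) for l in annotation]
    current = dedupe_named_loci(current, report)
    current = strip_shared_exons(current, report)
    current = filter_structural(current, genome, params, report)
    current = [dedupe_identical_isoforms(l, report) for l in current]

    report.loci_out = len(current)
    report.transcripts_out = sum(len(l.transcripts) for l in current)
    return current, report
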