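"""Seeded generators for every input the toolkit consumes.

Each generator emits plain-text files (FASTA, TSV, GFF3, summary text)
plus a :class:`FixtureLedger` recording the planted truth — which
contigs are contaminants, which annotation defects were introduced and
where, how genes are laid out — so that every pipeline stage can be
tested end to end against known expectations, without any downloads.

Determinism contract: the same seed and parameters produce byte-identical
files. A single integer seed drives one ``random.Random`` stream for
structural choices and one numpy generator (seeded from that stream) for
nucleotide content.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as aio
from .model import (
    BuscoSummary,
    Contig,
    ExonInterval,
    GeneLocus,
    PriorLabel,
    TaxonLineage,
    TranscriptModel,
)

_NT = np.frombuffer(b"ACGT", dtype="S1")

# Taxa used throughout the screening fixtures. Two rodents (house mouse
# and golden hamster), one primate, one fish, one bacterium.
TAXA: dict[int, tuple[tuple[str, str], ...]] = {
    10090: (
        ("superkingdom", "Eukaryota"), ("class", "Mammalia"),
        ("order", "Rodentia"), ("species", "Mus musculus"),
    ),
    10036: (
        ("superkingdom", "Eukaryota"), ("class", "Mammalia"),
        ("order", "Rodentia"), ("species", "Mesocricetus auratus"),
    ),
    9606: (
        ("superkingdom", "Eukaryota"), ("class", "Mammalia"),
        ("order", "Primates"), ("species", "Homo sapiens"),
    ),
    7955: (
        ("superkingdom", "Eukaryota"), ("class", "Actinopteri"),
        ("order", "Cypriniformes"), ("species", "Danio rerio"),
    ),
    562: (
        ("superkingdom", "Bacteria"), ("class", "Gammaproteobacteria"),
        ("order", "Enterobacterales"), ("species", "Escherichia coli"),
    ),
}
RODENT_TAXIDS = (10090, 10036)
HUMAN_TAXID = 9606


def default_lineages() -> dict[int, TaxonLineage]:
    return {
        taxid: TaxonLineage(taxid=taxid, ranked_names=names)
        for taxid, names in TAXA.items()
    }


def _random_seq(nprng: np.random.Generator, length: int) -> str:
    return nprng.choice(_NT, size=length).tobytes().decode()


@dataclass
class FixtureLedger:
    """Planted truth of one generated fixture set."""

    seed: int
    planted_contaminants: list[tuple[str, str]] = field(default_factory=list)
    planted_defects: list[dict] = field(default_factory=list)
    gene_layout: list[dict] = field(default_factory=list)
    expected: dict = field(default_factory=dict)

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Screening fixtures


@dataclass
class AssemblyFixture:
    fasta: Path
    manifest: Path
    blast: Path
    lineage: Path
    ledger_path: Path
    ledger: FixtureLedger


def read_manifest(path: str | os.PathLike) -> dict[str, PriorLabel]:
    """Read a contig -> prior-label TSV manifest."""
    manifest: dict[str, PriorLabel] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, label = line.split("\t")
            manifest[cid] = PriorLabel(label)
    return manifest


def write_manifest(
    manifest: dict[str, PriorLabel], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for cid, label in manifest.items():
            fh.write(f"{cid}\t{label.value}\n")


def make_assembly(
    outdir: str | os.PathLike,
    seed: int,
    n_target: int = 2028,
    n_bacteria: int = 3,
    n_flagged: int = 74,
    n_unclassified: int = 3,
    n_flagged_retain: int = 47,
    length_range: tuple[int, int] = (1_000, 50_000),
) -> AssemblyFixture:
    """Emit a screening fixture: contig FASTA, prior-label manifest,
    BLAST tabular hits for the flagged contigs, and a lineage table.

    Exactly ``n_flagged_retain`` of the flagged contigs are constructed
    to satisfy the adjudication rule — alternating between a rodent
    top summed score and no hit passing the e-value threshold — and the
    remaining flagged contigs get a non-rodent (human) top score from
    passing hits, so they adjudicate to drop. The ledger records every
    contig's true category and the expected retained count.
    """
    if n_flagged_retain > n_flagged:
        raise ValueError("n_flagged_retain cannot exceed n_flagged")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    nprng = np.random.default_rng(rng.randrange(2**31))
    ledger = FixtureLedger(seed=seed)

    contigs: list[Contig] = []
    manifest: dict[str, PriorLabel] = {}
    categories: list[tuple[str, str]] = []

    def add_contig(idx: int, label: PriorLabel, category: str) -> str:
        cid = f"tig{idx:05d}"
        length = rng.randint(*length_range)
        contigs.append(Contig(id=cid, length=length, sequence=_random_seq(nprng, length)))
        manifest[cid] = label
        categories.append((cid, category))
        return cid

    idx = 0
    flagged_ids: list[str] = []
    plan = (
        [(PriorLabel.TARGET_SPECIES, "target")] * n_target
        + [(PriorLabel.UNCLASSIFIED, "unclassified")] * n_unclassified
        + [(PriorLabel.BACTERIA, "bacteria")] * n_bacteria
        + [(PriorLabel.FLAGGED, "flagged")] * n_flagged
    )
    rng.shuffle(plan)
    for label, cat in plan:
        cid = add_contig(idx, label, cat)
        idx += 1
        if label is PriorLabel.FLAGGED:
            flagged_ids.append(cid)

    # Adjudication outcomes for flagged contigs: first n_flagged_retain
    # (in contig order) retain, alternating retention mode.
    hits = []
    for i, cid in enumerate(flagged_ids):
        if i < n_flagged_retain:
            if i % 2 == 0:  # rodent top score
                rodent = RODENT_TAXIDS[i % len(RODENT_TAXIDS)]
                top = rng.uniform(400, 900)
                hits.append(aio.BlastHit(cid, f"sbj{i}a", 10 ** -rng.uniform(30, 60), top, rodent))
                hits.append(aio.BlastHit(cid, f"sbj{i}b", 10 ** -rng.uniform(26, 60),
                                         rng.uniform(50, top - 10), HUMAN_TAXID))
                mode = "flagged_retain_lineage"
            else:  # no hit passes the threshold (or no hits at all)
                if i % 4 == 1:
                    hits.append(aio.BlastHit(cid, f"sbj{i}a", 10 ** -rng.uniform(5, 24),
                                             rng.uniform(50, 400), HUMAN_TAXID))
                mode = "flagged_retain_nohit"
        else:
            top = rng.uniform(400, 900)
            hits.append(aio.BlastHit(cid, f"sbj{i}a", 10 ** -rng.uniform(30, 60), top, HUMAN_TAXID))
            if i % 3 == 0:
                hits.append(aio.BlastHit(cid, f"sbj{i}b", 10 ** -rng.uniform(26, 60),
                                         rng.uniform(10, top - 10), RODENT_TAXIDS[0]))
            mode = "flagged_drop"
        ledger.planted_contaminants.append((cid, mode))

    for cid, cat in categories:
        if cat != "flagged":
            ledger.planted_contaminants.append((cid, cat))
    ledger.planted_contaminants.sort()
    ledger.expected = {
        "n_contigs": len(contigs),
        "n_retained": n_target + n_unclassified + n_flagged_retain,
        "n_dropped": n_bacteria + (n_flagged - n_flagged_retain),
    }

    fasta = outdir / "assembly.fa"
    manifest_path = outdir / "labels.tsv"
    blast = outdir / "hits.tsv"
    lineage = outdir / "lineage.tsv"
    ledger_path = outdir / "ledger.json"
    aio.write_fasta(contigs, fasta)
    write_manifest(manifest, manifest_path)
    aio.write_blast_tab(hits, blast)
    aio.write_lineage_table(default_lineages(), lineage)
    ledger.write_json(ledger_path)
    return AssemblyFixture(fasta, manifest_path, blast, lineage, ledger_path, ledger)


# ---------------------------------------------------------------------------
# Annotation fixtures


@dataclass(frozen=True)
class DefectSpec:
    """How many annotation defects of each kind to plant."""

    name_conflicts: int = 0
    duplicate_named_loci: int = 0
    shared_exons: int = 0
    short_exons: int = 0
    noncanonical_introns: int = 0
    identical_isoforms: int = 0

    def total_genes_needed(self) -> int:
        return (
            self.name_conflicts
            + 2 * self.duplicate_named_loci
            + 2 * self.shared_exons
            + self.short_exons
            + self.noncanonical_introns
            + self.identical_isoforms
        )


@dataclass
class AnnotationFixture:
    genome: Path
    gff3: Path
    ledger_path: Path
    ledger: FixtureLedger
    contigs: list[Contig]
    annotation: list[GeneLocus]


class _GenomePlan:
    """Mutable per-contig sequence buffer with planted motifs."""

    def __init__(self, seqid: str, length: int, nprng: np.random.Generator):
        self.seqid = seqid
        self.buf = bytearray(_random_seq(nprng, length).encode())

    def plant(self, pos1: int, motif: str) -> None:
        """Overwrite bases at 1-based position pos1."""
        self.buf[pos1 - 1 : pos1 - 1 + len(motif)] = motif.encode()

    def plant_intron(self, lo: int, hi: int, strand: str, canonical: bool = True) -> None:
        if canonical:
            left, right = ("GT", "AG") if strand == "+" else ("CT", "AC")
        else:
            # AA..CC is noncanonical read from either strand
            left, right = "AA", "CC"
        self.plant(lo, left)
        self.plant(hi - 1, right)

    def contig(self) -> Contig:
        seq = self.buf.decode()
        return Contig(id=self.seqid, length=len(seq), sequence=seq)


def _make_gene(
    rng: random.Random,
    plan: _GenomePlan,
    gene_id: str,
    gene_name: str,
    start: int,
    strand: str,
    n_exons: int,
    score: float,
) -> tuple[GeneLocus, int]:
    """Build one clean gene starting at ``start``; returns (locus, end)."""
    exons: list[ExonInterval] = []
    pos = start
    for i in range(n_exons):
        elen = rng.randint(80, 240)
        exons.append(ExonInterval(pos, pos + elen - 1))
        pos += elen
        if i < n_exons - 1:
            ilen = rng.randint(60, 200)
            plan.plant_intron(pos, pos + ilen - 1, strand, canonical=True)
            pos += ilen
    # CDS: exon set trimmed by 10 bp at both transcript extremities
    cds = []
    for i, ex in enumerate(exons):
        s = ex.start + 10 if i == 0 else ex.start
        e = ex.end - 10 if i == len(exons) - 1 else ex.end
        cds.append(ExonInterval(s, e))
    tx = TranscriptModel(
        id=f"{gene_id}.t1",
        gene_id=gene_id,
        seqid=plan.seqid,
        strand=strand,
        score=score,
        exons=exons,
        cds=cds,
        gene_name=gene_name,
    )
    locus = GeneLocus(id=gene_id, seqid=plan.seqid, strand=strand, transcripts=[tx])
    return locus, pos - 1


def make_annotation(
    outdir: str | os.PathLike,
    seed: int,
    n_genes: int = 20,
    defects: DefectSpec = DefectSpec(),
    gap_choices: tuple[int, ...] = (1_500, 2_500, 2_999, 3_000, 3_500, 6_000),
) -> AnnotationFixture:
    """Emit a genome FASTA plus a GFF3 annotation with planted defects.

    Genes are laid out left to right on one contig with inter-gene gaps
    drawn from ``gap_choices`` — the default set straddles the 3,000 bp
    UTR-extension gate on both sides, and the first two gaps are always
    2,999 and 3,000 (with the flanking genes on the forward strand) so
    the gate boundary is always exercised. Introns of
    non-defective transcripts carry the canonical GT-AG consensus by
    construction. The ledger records the gene layout (spans, strands,
    gaps) and every planted defect with the entity ids involved.
    """
    needed = defects.total_genes_needed()
    if needed > n_genes:
        raise ValueError(
            f"defect spec needs {needed} genes but only {n_genes} requested"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    nprng = np.random.default_rng(rng.randrange(2**31))
    ledger = FixtureLedger(seed=seed)

    # Assign defect roles to distinct gene indices.
    roles: dict[int, str] = {}
    cursor = 0

    def take(n: int, role: str) -> list[int]:
        nonlocal cursor
        out = list(range(cursor, cursor + n))
        for g in out:
            roles[g] = role
        cursor += n
        return out

    conflict_hosts = take(defects.name_conflicts, "name_conflict")
    dup_pairs = [
        (a, b)
        for a, b in zip(
            take(defects.duplicate_named_loci, "dup_name_winner"),
            take(defects.duplicate_named_loci, "dup_name_loser"),
        )
    ]
    share_pairs = []
    for _ in range(defects.shared_exons):
        a, b = take(2, "shared_exon")  # adjacent genes
        share_pairs.append((a, b))
    short_hosts = take(defects.short_exons, "short_exon")
    noncanon_hosts = take(defects.noncanonical_introns, "noncanonical_intron")
    iso_hosts = take(defects.identical_isoforms, "identical_isoform")

    shared_b_set = {b for _, b in share_pairs}
    shared_involved = {g for pair in share_pairs for g in pair}

    # Gap after each gene: first two fixed at the gate boundary.
    gaps = []
    for i in range(n_genes):
        if i == 0:
            gaps.append(2_999)
        elif i == 1:
            gaps.append(3_000)
        else:
            gaps.append(rng.choice(gap_choices))

    # Lay genes on a single contig, left to right.
    sizes_guess = n_genes * 2_000 + sum(gaps) + 10_000
    plan = _GenomePlan("chr_syn1", sizes_guess, nprng)
    annotation: list[GeneLocus] = []
    pos = 2_000
    gene_names: dict[int, str] = {}
    starts_ends: list[tuple[int, int]] = []
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        name = f"Sym{g:04d}"
        gene_names[g] = name
        # strand: shared-exon pairs forced to '+' to keep splice planting
        # on one orientation; the first three genes forced to '+' so the
        # 2,999/3,000 gate-boundary gaps are always experienced 3' of a
        # transcript (gene 0 sees the 2,999 gap, gene 1 the 3,000 gap).
        strand = "+" if g in shared_involved or g < 3 else rng.choice("+-")
        n_exons = rng.randint(2, 3)
        score = round(rng.uniform(50, 100), 2)
        locus, end = _make_gene(rng, plan, gid, name, pos, strand, n_exons, score)
        annotation.append(locus)
        starts_ends.append((pos, end))
        pos = end + 1 + gaps[g]

    contig_len = len(plan.buf)
    for g, locus in enumerate(annotation):
        ledger.gene_layout.append(
            {
                "gene_id": locus.id,
                "seqid": locus.seqid,
                "strand": locus.strand,
                "span": list(locus.span),
                "gap_after": gaps[g] if g < n_genes - 1 else contig_len - starts_ends[g][1],
                "gap_before": gaps[g - 1] if g > 0 else starts_ends[g][0] - 1,
                "last_on_contig": g == n_genes - 1,
                "first_on_contig": g == 0,
            }
        )

    # --- plant defects ------------------------------------------------
    def locus_of(g: int) -> GeneLocus:
        return annotation[g]

    for g in conflict_hosts:
        locus = locus_of(g)
        main = locus.transcripts[0]
        # alternative transcript skipping the middle exon (or the last of
        # two): its novel intron joins planted GT..AG halves, so it stays
        # canonical and is removed by the name rule alone.
        alt_exons = [main.exons[0], main.exons[-1]] if len(main.exons) > 2 else [main.exons[0]]
        alt = TranscriptModel(
            id=f"{locus.id}.t2",
            gene_id=locus.id,
            seqid=locus.seqid,
            strand=locus.strand,
            score=main.score - 10,
            exons=alt_exons,
            cds=[],
            gene_name=f"Alt{g:04d}",
        )
        locus.transcripts.append(alt)
        ledger.planted_defects.append(
            {"kind": "name_conflict", "entities": [alt.id], "rule": "resolve_gene_names"}
        )

    for winner, loser in dup_pairs:
        lw, ll = locus_of(winner), locus_of(loser)
        for t in ll.transcripts:
            t.gene_name = gene_names[winner]
            t.score = min(t.score, lw.top_transcript().score - 5)
        gene_names[loser] = gene_names[winner]
        ledger.planted_defects.append(
            {
                "kind": "duplicate_named_locus",
                "entities": [ll.id] + [t.id for t in ll.transcripts],
                "rule": "dedupe_named_loci",
            }
        )

    for a, b in share_pairs:
        la, lb = locus_of(a), locus_of(b)
        # place a non-coding exon midway in the gap between the two genes
        a_end = la.span[1]
        b_start = lb.span[0]
        assert b_start - a_end > 400, "gap too small for a shared exon"
        mid = (a_end + b_start) // 2
        ex = ExonInterval(mid, mid + 120)
        # gene a: shared exon appended 3'-terminal; intron a_end+1 .. mid-1
        plan.plant_intron(a_end + 1, mid - 1, "+", canonical=True)
        # gene b: shared exon prepended 5'-terminal; intron ex.end+1 .. b_start-1
        plan.plant_intron(ex.end + 1, b_start - 1, "+", canonical=True)
        la.transcripts[0].exons.append(ex)
        lb.transcripts[0].exons.insert(0, ex)
        ledger.planted_defects.append(
            {
                "kind": "shared_exon",
                "entities": [la.transcripts[0].id, lb.transcripts[0].id],
                "exon": [ex.start, ex.end],
                "rule": "strip_shared_exons",
            }
        )

    for g in short_hosts:
        locus = locus_of(g)
        main = locus.transcripts[0]
        # shrink the first exon to 14 bp; drop CDS so containment holds
        first = main.exons[0]
        main.exons[0] = ExonInterval(first.end - 13, first.end)
        main.cds = []
        main.validate()
        ledger.planted_defects.append(
            {"kind": "short_exon", "entities": [main.id], "rule": "filter_structural"}
        )

    for g in noncanon_hosts:
        locus = locus_of(g)
        main = locus.transcripts[0]
        lo, hi = main.introns()[0]
        plan.plant_intron(lo, hi, locus.strand, canonical=False)
        ledger.planted_defects.append(
            {"kind": "noncanonical_intron", "entities": [main.id], "rule": "filter_structural"}
        )

    for g in iso_hosts:
        locus = locus_of(g)
        main = locus.transcripts[0]
        twin = main.copy()
        twin.id = f"{locus.id}.t2"
        twin.score = main.score - 1
        # same exon boundaries, strictly shorter CDS
        twin.cds = [ExonInterval(c.start + 3, c.end) if i == 0 else c
                    for i, c in enumerate(main.cds)]
        locus.transcripts.append(twin)
        ledger.planted_defects.append(
            {"kind": "identical_isoform", "entities": [twin.id], "rule": "dedupe_identical_isoforms"}
        )

    n_tx = sum(len(l.transcripts) for l in annotation)
    ledger.expected = {
        "n_genes": n_genes,
        "n_transcripts": n_tx,
        "clean_genes": [annotation[g].id for g in range(n_genes) if g not in roles],
        "transcripts_removed": (
            defects.name_conflicts
            + defects.duplicate_named_loci
            + defects.short_exons
            + defects.noncanonical_introns
            + defects.identical_isoforms
        ),
        "loci_removed": (
            defects.duplicate_named_loci
            + defects.short_exons
            + defects.noncanonical_introns
        ),
        "exon_trims": 2 * defects.shared_exons,
    }

    contig = plan.contig()
    genome_path = outdir / "genome.fa"
    gff_path = outdir / "annotation.gff3"
    ledger_path = outdir / "ledger.json"
    aio.write_fasta([contig], genome_path)
    aio.write_annotation(annotation, gff_path, dialect="gff3")
    ledger.write_json(ledger_path)
    return AnnotationFixture(
        genome=genome_path,
        gff3=gff_path,
        ledger_path=ledger_path,
        ledger=ledger,
        contigs=[contig],
        annotation=annotation,
    )


# ---------------------------------------------------------------------------
# BUSCO summary fixtures


def make_busco_summary(
    outdir: str | os.PathLike,
    seed: int,
    single: int = 12_467,
    duplicated: int = 225,
    fragmented: int = 267,
    missing: int = 839,
    consistent: bool = True,
) -> Path:
    """Write a BUSCO short-summary text file with the given category
    counts; in inconsistent mode the stated complete count is perturbed
    so that exactly one arithmetic identity fails."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    complete = single + duplicated
    if not consistent:
        # perturbing the stated complete count breaks C = S + D while the
        # stated total still equals C + F + M
        complete += random.Random(seed).randint(1, 10)
    total = complete + fragmented + missing
    summary = BuscoSummary(
        complete=complete,
        single=single,
        duplicated=duplicated,
        fragmented=fragmented,
        missing=missing,
        total=total,
    )
    path = outdir / "short_summary.txt"
    aio.write_busco_summary(summary, path)
    return path
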