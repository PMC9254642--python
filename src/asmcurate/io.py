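"""Readers and writers for every external format the toolkit touches.

Formats: multi-record FASTA, BLAST tabular (outfmt 6 plus a subject-taxid
column), a taxid-to-lineage TSV, GFF3/GTF gene annotations, and BUSCO
short-summary text. All writers emit deterministic ordering: FASTA in
input order, annotation features sorted by (seqid, start).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BlastHit,
    BuscoSummary,
    Contig,
    ExonInterval,
    GeneLocus,
    ParseError,
    TaxonLineage,
    TranscriptModel,
)

log = logging.getLogger(__name__)

# Full IUPAC nucleotide alphabet incl. ambiguity codes and gaps.
_IUPAC_NT = set("ACGTUNRYSWKMBDHV") | set("acgtunryswkmbdhv") | {"-", "*"}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`, order preserved.

    Raises :class:`ParseError` naming the offending line for malformed
    headers or non-IUPAC residues.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    contigs = []
    for rec in records:
        seq = str(rec.seq)
        bad = next((c for c in seq if c not in _IUPAC_NT), None)
        if bad is not None:
            raise ParseError(
                f"{path}: non-IUPAC residue {bad!r} at "
                f"line {_locate_residue_line(path, rec.id, bad)} "
                f"(record {rec.id})"
            )
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        contigs.append(Contig(id=rec.id, length=len(seq), sequence=seq))
    return contigs


def _locate_residue_line(path: str | os.PathLike, rec_id: str, bad: str) -> int:
    """Best-effort line number of the first bad residue in a record."""
    in_rec = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
                continue
            if in_rec and bad in line:
                return lineno
    return -1


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike, width: int = 70) -> None:
    """Write contigs in input order; sequences wrapped at ``width``."""
    records = []
    for c in contigs:
        if c.sequence is None:
            raise ValueError(f"contig {c.id} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6 + staxids)


def read_blast_tab(path: str | os.PathLike) -> list[BlastHit]:
    """Parse BLAST tabular output: the standard 12 columns plus staxids.

    Column 11 (0-based 10) is the e-value, column 12 the bitscore and
    column 13 the subject taxid. Semicolon-joined multi-taxid cells take
    the first taxid (a warning is logged). Comment lines (``#``) are
    skipped so ``-outfmt "7 std staxids"`` output parses too.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 13 tab-separated columns, "
                    f"got {len(fields)}"
                )
            taxid_cell = fields[12]
            if ";" in taxid_cell:
                log.warning(
                    "%s:%d: multi-taxid cell %r; taking the first taxid",
                    path, lineno, taxid_cell,
                )
                taxid_cell = taxid_cell.split(";")[0]
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_taxid=int(taxid_cell),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | os.PathLike) -> None:
    """Write hits in outfmt-6 + staxids layout (unused std columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            std = [
                h.query_id, h.subject_id, "100.000", "100", "0", "0",
                "1", "100", "1", "100",
                f"{h.evalue:.2g}", f"{h.bitscore:.1f}", str(h.subject_taxid),
            ]
            fh.write("\t".join(std) + "\n")


# ---------------------------------------------------------------------------
# Lineage TSV


def read_lineage_table(path: str | os.PathLike) -> dict[int, TaxonLineage]:
    """Read a TSV of ``taxid<TAB>rank:name;rank:name;...`` rows.

    Duplicate taxids and malformed rank:name pairs are rejected.
    """
    lineages: dict[int, TaxonLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                taxid = int(parts[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad taxid {parts[0]!r}") from exc
            if taxid in lineages:
                raise ParseError(f"{path}:{lineno}: duplicate taxid {taxid}")
            pairs = []
            for chunk in parts[1].split(";"):
                if ":" not in chunk:
                    raise ParseError(
                        f"{path}:{lineno}: malformed rank:name pair {chunk!r}"
                    )
                rank, name = chunk.split(":", 1)
                pairs.append((rank, name))
            lineages[taxid] = TaxonLineage(taxid=taxid, ranked_names=tuple(pairs))
    return lineages


def write_lineage_table(
    lineages: dict[int, TaxonLineage], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for taxid in sorted(lineages):
            pairs = ";".join(f"{r}:{n}" for r, n in lineages[taxid].ranked_names)
            fh.write(f"{taxid}\t{pairs}\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF annotation


def read_annotation(
    path: str | os.PathLike,
    dialect: str = "gff3",
    score_attr: str = "score",
    gene_name_attr: str = "gene_name",
) -> list[GeneLocus]:
    """Read a GFF3 or GTF annotation into :class:`GeneLocus` models.

    The predictor score is taken from the mRNA/transcript feature's score
    column, falling back to the attribute named by ``score_attr``; the
    source-reference gene symbol is read from ``gene_name_attr``.

    Parameters
    ----------
    dialect
        ``"gff3"`` (ID/Parent hierarchy) or ``"gtf"``
        (gene_id/transcript_id attributes).
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    is_gtf = dialect == "gtf"
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )

    transcript_types = {"mRNA", "transcript"}
    child_types = {"exon", "CDS"}

    # id -> (transcript skeleton); preserve file order via gffutils order_by
    transcripts: dict[str, TranscriptModel] = {}
    tx_span: dict[str, tuple[int, int]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []

    def _attr_first(feat, key) -> Optional[str]:
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in transcript_types:
            continue
        if is_gtf:
            tid = _attr_first(feat, "transcript_id")
            gid = _attr_first(feat, "gene_id")
        else:
            tid = feat.id
            parents = feat.attributes.get("Parent")
            gid = parents[0] if parents else tid
        if tid is None or gid is None:
            raise ParseError(f"{path}: transcript feature without an id: {feat}")
        score = None
        if feat.score not in (".", "", None):
            score = float(feat.score)
        else:
            raw = _attr_first(feat, score_attr)
            if raw is not None:
                score = float(raw)
        transcripts[tid] = TranscriptModel(
            id=tid,
            gene_id=gid,
            seqid=feat.seqid,
            strand=feat.strand,
            score=score if score is not None else 0.0,
            exons=[ExonInterval(feat.start, feat.end)],  # placeholder, replaced
            gene_name=_attr_first(feat, gene_name_attr),
        )
        transcripts[tid].exons = []
        tx_span[tid] = (feat.start, feat.end)
        tx_gene[tid] = gid
        order.append(tid)

    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in child_types:
            continue
        if is_gtf:
            tids = feat.attributes.get("transcript_id") or []
        else:
            tids = feat.attributes.get("Parent") or []
        if not tids:
            raise ParseError(f"{path}: {feat.featuretype} feature without a parent")
        for tid in tids:
            if tid not in transcripts:
                raise ParseError(
                    f"{path}: {feat.featuretype} refers to unknown transcript "
                    f"{tid!r}"
                )
            tx = transcripts[tid]
            lo, hi = tx_span[tid]
            if feat.start < lo or feat.end > hi:
                raise ParseError(
                    f"{path}: {feat.featuretype} [{feat.start},{feat.end}] "
                    f"outside span of transcript {tid}"
                )
            if feat.strand != tx.strand:
                raise ParseError(
                    f"{path}: mixed strands within transcript {tid}"
                )
            iv = ExonInterval(feat.start, feat.end)
            if feat.featuretype == "exon":
                tx.exons.append(iv)
            else:
                tx.cds.append(iv)

    loci: dict[str, GeneLocus] = {}
    gene_order: list[str] = []
    for tid in order:
        tx = transcripts[tid]
        if not tx.exons:
            raise ParseError(f"{path}: transcript {tid} has no exons")
        tx.validate()
        gid = tx_gene[tid]
        if gid not in loci:
            loci[gid] = GeneLocus(
                id=gid, seqid=tx.seqid, strand=tx.strand, transcripts=[tx]
            )
            gene_order.append(gid)
        else:
            locus = loci[gid]
            if tx.seqid != locus.seqid or tx.strand != locus.strand:
                raise ParseError(
                    f"{path}: transcript {tid} disagrees with locus {gid} on "
                    "seqid/strand"
                )
            locus.transcripts.append(tx)
    return [loci[g] for g in gene_order]


def _gff3_attrs(pairs: list[tuple[str, Optional[str]]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v is not None)


def _gtf_attrs(pairs: list[tuple[str, Optional[str]]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs if v is not None)


def write_annotation(
    annotation: Iterable[GeneLocus],
    path: str | os.PathLike,
    dialect: str = "gff3",
    source: str = "asmcurate",
    gene_name_attr: str = "gene_name",
) -> None:
    """Write loci as GFF3 or GTF, features sorted by (seqid, start)."""
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    is_gtf = dialect == "gtf"
    lines: list[tuple[str, int, int, str]] = []  # (seqid, start, rank, text)

    def emit(seqid, ftype, start, end, score, strand, frame, attrs, rank):
        text = "\t".join(
            [seqid, source, ftype, str(start), str(end), score, strand, frame, attrs]
        )
        lines.append((seqid, start, rank, text))

    for locus in annotation:
        lo, hi = locus.span
        if is_gtf:
            gattrs = _gtf_attrs([("gene_id", locus.id)])
        else:
            gattrs = _gff3_attrs([("ID", locus.id)])
        emit(locus.seqid, "gene", lo, hi, ".", locus.strand, ".", gattrs, 0)
        for tx in locus.transcripts:
            base = [("gene_id", locus.id), ("transcript_id", tx.id)]
            if is_gtf:
                tattrs = _gtf_attrs(base + [(gene_name_attr, tx.gene_name)])
            else:
                tattrs = _gff3_attrs(
                    [("ID", tx.id), ("Parent", locus.id),
                     (gene_name_attr, tx.gene_name)]
                )
            emit(
                locus.seqid, "mRNA" if not is_gtf else "transcript",
                tx.start, tx.end, f"{tx.score:g}", tx.strand, ".", tattrs, 1,
            )
            for ex in tx.exons:
                attrs = _gtf_attrs(base) if is_gtf else _gff3_attrs(
                    [("Parent", tx.id)]
                )
                emit(locus.seqid, "exon", ex.start, ex.end, ".", tx.strand, ".",
                     attrs, 2)
            for c in tx.cds:
                attrs = _gtf_attrs(base) if is_gtf else _gff3_attrs(
                    [("Parent", tx.id)]
                )
                emit(locus.seqid, "CDS", c.start, c.end, ".", tx.strand, "0",
                     attrs, 3)

    lines.sort(key=lambda rec: (rec[0], rec[1], rec[2]))
    with open(path, "w") as fh:
        if not is_gtf:
            fh.write("##gff-version 3\n")
        for _, _, _, text in lines:
            fh.write(text + "\n")


# ---------------------------------------------------------------------------
# BUSCO short summary

_BUSCO_LABELS = {
    "Complete BUSCOs (C)": "complete",
    "Complete and single-copy BUSCOs (S)": "single",
    "Complete and duplicated BUSCOs (D)": "duplicated",
    "Fragmented BUSCOs (F)": "fragmented",
    "Missing BUSCOs (M)": "missing",
    "Total BUSCO groups searched": "total",
}


def read_busco_summary(path: str | os.PathLike) -> BuscoSummary:
    """Parse a BUSCO ``short_summary`` text file into category counts.

    Expects the six labelled count lines (C/S/D/F/M and the searched
    total); a missing label raises :class:`ParseError`.
    """
    found: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            for label, field_name in _BUSCO_LABELS.items():
                if stripped.endswith(label):
                    count_part = stripped[: -len(label)].strip()
                    try:
                        found[field_name] = int(count_part.replace(",", ""))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: unparsable count {count_part!r}"
                        ) from exc
    missing = [k for k in _BUSCO_LABELS.values() if k not in found]
    if missing:
        raise ParseError(f"{path}: missing BUSCO label(s): {', '.join(missing)}")
    return BuscoSummary(**found)


def write_busco_summary(s: BuscoSummary, path: str | os.PathLike) -> None:
    """Write counts in the short_summary text layout."""
    pct = (100.0 * s.complete / s.total) if s.total else 0.0
    with open(path, "w") as fh:
        fh.write("# BUSCO short summary\n")
        fh.write(f"\tC:{pct:.1f}%,n:{s.total}\n")
        for label, field_name in _BUSCO_LABELS.items():
            fh.write(f"\t{getattr(s, field_name)}\t{label}\n")
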