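"""In-memory model builders shared by the unit tests."""

from asmcurate.model import Contig, ExonInterval, GeneLocus, TranscriptModel


def tx(
    tid,
    exons,
    gene_id=None,
    seqid="chr1",
    strand="+",
    score=50.0,
    cds=(),
    name=None,
):
    return TranscriptModel(
        id=tid,
        gene_id=gene_id or tid.split(".")[0],
        seqid=seqid,
        strand=strand,
        score=score,
        exons=[ExonInterval(s, e) for s, e in exons],
        cds=[ExonInterval(s, e) for s, e in cds],
        gene_name=name,
    )


def locus(lid, transcripts, seqid="chr1", strand="+"):
    return GeneLocus(id=lid, seqid=seqid, strand=strand, transcripts=transcripts)


def contig_with(length, plants, cid="chr1"):
    """Contig of 'A's with (1-based position, motif) plants."""
    buf = bytearray(b"A" * length)
    for pos, motif in plants:
        buf[pos - 1 : pos - 1 + len(motif)] = motif.encode()
    return Contig(id=cid, length=length, sequence=buf.decode())
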