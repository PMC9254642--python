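"""Domain types shared across the toolkit.

Coordinate convention: all intervals are 1-based and inclusive at both
ends (the GFF convention). The length of an interval is therefore
``end - start + 1``. Any half-open arithmetic is confined to the format
conversion helpers in :mod:`asmcurate.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class AsmcurateError(Exception):
    """Base class for all toolkit errors."""


class ParseError(AsmcurateError):
    """A file did not conform to its expected dialect."""


class ValidationError(AsmcurateError):
    """An in-memory object violates a structural invariant."""


class PriorLabel(str, enum.Enum):
    """Outcome of the upstream k-mer classification stage for a contig."""

    TARGET_SPECIES = "target_species"
    UNCLASSIFIED = "unclassified"
    BACTERIA = "bacteria"
    FLAGGED = "flagged"


class Verdict(str, enum.Enum):
    RETAIN = "retain"
    DROP = "drop"


class Reason(str, enum.Enum):
    PRIOR_RETAIN = "prior_retain"
    PRIOR_DROP = "prior_drop"
    ADJUDICATED_LINEAGE_RETAIN = "adjudicated_lineage_retain"
    ADJUDICATED_NO_HITS_RETAIN = "adjudicated_no_hits_retain"
    ADJUDICATED_DROP = "adjudicated_drop"


@dataclass(frozen=True)
class Contig:
    """One assembled sequence, the unit of screening and contiguity stats."""

    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        if self.length < 0:
            raise ValidationError(f"contig {self.id}: negative length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"contig {self.id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (outfmt 6 plus subject taxid)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    subject_taxid: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError("e-value must be non-negative")
        if self.bitscore < 0:
            raise ValidationError("bitscore must be non-negative")
        if self.subject_taxid <= 0:
            raise ValidationError("taxid must be positive")


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered rank path of one taxon, from root towards the leaf.

    ``ranked_names`` is a tuple of ``(rank, name)`` pairs, e.g.
    ``(("superkingdom", "Eukaryota"), ("order", "Rodentia"), ...)``.
    """

    taxid: int
    ranked_names: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise ValidationError("taxid must be positive")
        if not self.ranked_names:
            raise ValidationError(f"taxid {self.taxid}: empty lineage")
        ranks = [r for r, _ in self.ranked_names]
        if len(ranks) != len(set(ranks)):
            raise ValidationError(f"taxid {self.taxid}: duplicate ranks in lineage")

    def name_at(self, rank: str) -> Optional[str]:
        for r, n in self.ranked_names:
            if r == rank:
                return n
        return None

    def contains(self, rank: str, name: str) -> bool:
        """True when the lineage assigns exactly ``name`` to ``rank``."""
        return self.name_at(rank) == name


@dataclass(frozen=True)
class ClassificationDecision:
    """Audit record of the screening verdict for one contig."""

    contig_id: str
    prior_label: PriorLabel
    taxid_scores: dict[int, float] = field(default_factory=dict)
    assigned_taxid: Optional[int] = None
    verdict: Verdict = Verdict.RETAIN
    reason: Reason = Reason.PRIOR_RETAIN

    def __post_init__(self) -> None:
        if self.assigned_taxid is not None and self.taxid_scores:
            best = max(self.taxid_scores.values())
            if self.taxid_scores.get(self.assigned_taxid) != best:
                raise ValidationError(
                    f"{self.contig_id}: assigned taxid is not the top-scoring one"
                )
        if self.verdict is Verdict.DROP and self.reason not in (
            Reason.PRIOR_DROP,
            Reason.ADJUDICATED_DROP,
        ):
            raise ValidationError(
                f"{self.contig_id}: drop verdict with retain-type reason {self.reason}"
            )


class Role(str, enum.Enum):
    EXON = "exon"
    CDS = "cds"
    UTR3 = "utr3"
    UTR5 = "utr5"


@dataclass(frozen=True)
class ExonInterval:
    """A 1-based inclusive interval on a contig."""

    start: int
    end: int
    role: Role = Role.EXON

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One predicted mRNA model: stranded, scored exon/CDS intervals.

    ``score`` carries the homology predictor's confidence used for
    ranking during curation; ``gene_name`` is the reference gene symbol
    transferred from the source species, when known.
    """

    id: str
    gene_id: str
    seqid: str
    strand: str
    score: float
    exons: list[ExonInterval] = field(default_factory=list)
    cds: list[ExonInterval] = field(default_factory=list)
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-'")
        self.validate()

    def validate(self) -> None:
        exs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exs, exs[1:]):
            if b.start <= a.end:
                raise ValidationError(f"{self.id}: overlapping exons")
        self.exons = exs
        self.cds = sorted(self.cds, key=lambda c: c.start)
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValidationError(
                    f"{self.id}: CDS [{c.start},{c.end}] not contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript's 3' terminus."""
        return self.end if self.strand == "+" else self.start

    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (1-based inclusive), left to right."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    def exon_boundaries(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)

    def copy(self) -> "TranscriptModel":
        return TranscriptModel(
            id=self.id,
            gene_id=self.gene_id,
            seqid=self.seqid,
            strand=self.strand,
            score=self.score,
            exons=list(self.exons),
            cds=list(self.cds),
            gene_name=self.gene_name,
        )


@dataclass
class GeneLocus:
    """A gene region holding one or more transcript models."""

    id: str
    seqid: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"locus {self.id}: no transcripts")
        for t in self.transcripts:
            if t.seqid != self.seqid or t.strand != self.strand:
                raise ValidationError(
                    f"locus {self.id}: transcript {t.id} on a different "
                    "seqid/strand"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    def top_transcript(self) -> TranscriptModel:
        """Highest-scoring transcript; ties keep input order."""
        return max(self.transcripts, key=lambda t: t.score)

    def copy(self) -> "GeneLocus":
        return GeneLocus(
            id=self.id,
            seqid=self.seqid,
            strand=self.strand,
            transcripts=[t.copy() for t in self.transcripts],
        )


@dataclass(frozen=True)
class AssemblyStats:
    """Thresholded contig counts/lengths plus N50 and L50."""

    thresholds: tuple[int, ...]
    counts_at: dict[int, int]
    lengths_at: dict[int, int]
    n50: int
    l50: int


@dataclass(frozen=True)
class BuscoSummary:
    """BUSCO completeness category counts."""

    complete: int
    single: int
    duplicated: int
    fragmented: int
    missing: int
    total: int

    def __post_init__(self) -> None:
        for name in ("complete", "single", "duplicated", "fragmented", "missing", "total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"BUSCO count {name} negative")


@dataclass(frozen=True)
class BuscoValidation:
    """Result of checking a summary's category arithmetic."""

    ok: bool
    recomputed_complete: int
    recomputed_total: int


def validate_busco_summary(s: BuscoSummary) -> BuscoValidation:
    """Check that C = S + D and that the categories sum to the total.

    The check is reported, never raised: a failing summary is a data
    finding, not a programming error.
    """
    complete = s.single + s.duplicated
    total = s.complete + s.fragmented + s.missing
    ok = complete == s.complete and total == s.total
    return BuscoValidation(ok=ok, recomputed_complete=complete, recomputed_total=total)


__all__ = [
    "AsmcurateError",
    "ParseError",
    "ValidationError",
    "PriorLabel",
    "Verdict",
    "Reason",
    "Contig",
    "BlastHit",
    "TaxonLineage",
    "ClassificationDecision",
    "Role",
    "ExonInterval",
    "TranscriptModel",
    "GeneLocus",
    "AssemblyStats",
    "BuscoSummary",
    "BuscoValidation",
    "validate_busco_summary",
    "replace",
]
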