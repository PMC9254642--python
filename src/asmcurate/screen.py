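"""Contamination screen for a polished assembly.

An upstream k-mer classifier has already labelled every contig. Labels
decide most contigs outright: target-species and unclassified contigs
are retained, bacterial contigs are dropped. Contigs flagged as possible
contaminants (e.g. classified as human) are adjudicated from their
nucleotide BLAST hits: bitscores are summed per subject taxon over all
hits with e-value strictly below a threshold (default 1e-25), the contig
is assigned the top-scoring taxon, and it is retained when that taxon's
lineage belongs to the retain clade (default order Rodentia) or when no
hit passed the threshold at all; otherwise it is dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import (
    AsmcurateError,
    BlastHit,
    ClassificationDecision,
    Contig,
    PriorLabel,
    Reason,
    TaxonLineage,
    ValidationError,
    Verdict,
)


class ScreenError(AsmcurateError):
    """Raised for unresolvable inputs during screening."""


@dataclass(frozen=True)
class ScreenPolicy:
    """Parameters of the retention rule.

    ``any_hit_mode`` switches to the alternative reading of the lineage
    rule: retain when ANY passing hit's taxon is in the retain clade,
    rather than only when the assigned (top summed-score) taxon is.
    """

    evalue_max: float = 1e-25
    retain_rank: str = "order"
    retain_name: str = "Rodentia"
    prior_retain_labels: frozenset[PriorLabel] = frozenset(
        {PriorLabel.TARGET_SPECIES, PriorLabel.UNCLASSIFIED}
    )
    prior_drop_labels: frozenset[PriorLabel] = frozenset({PriorLabel.BACTERIA})
    adjudicate_labels: frozenset[PriorLabel] = frozenset({PriorLabel.FLAGGED})
    any_hit_mode: bool = False

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        sets = [self.prior_retain_labels, self.prior_drop_labels, self.adjudicate_labels]
        seen: set[PriorLabel] = set()
        for s in sets:
            if seen & s:
                raise ValidationError("policy label sets must be disjoint")
            seen |= s


def aggregate_hit_scores(
    hits: Iterable[BlastHit], evalue_max: float = 1e-25
) -> dict[str, dict[int, float]]:
    """Sum bitscores per (contig, taxid) over hits with e-value < threshold.

    The threshold is strict: a hit at exactly ``evalue_max`` does not
    contribute. Contigs with no passing hit are absent from the result.
    """
    scores: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for hit in hits:
        if hit.evalue < evalue_max:
            scores[hit.query_id][hit.subject_taxid] += hit.bitscore
    return {contig: dict(per_taxid) for contig, per_taxid in scores.items()}


def assign_contig_taxon(taxid_scores: dict[int, float]) -> Optional[int]:
    """Taxon with the highest summed bitscore; ties break to the smallest
    taxid; an empty map yields ``None``."""
    if not taxid_scores:
        return None
    return min(taxid_scores, key=lambda t: (-taxid_scores[t], t))


def decide_retention(
    assigned: Optional[int],
    lineages: dict[int, TaxonLineage],
    policy: ScreenPolicy,
) -> tuple[Verdict, Reason]:
    """Apply the retain clade / no-passing-hit rule to an assigned taxon."""
    if assigned is None:
        return Verdict.RETAIN, Reason.ADJUDICATED_NO_HITS_RETAIN
    lineage = lineages.get(assigned)
    if lineage is None:
        raise ScreenError(f"assigned taxid {assigned} absent from lineage table")
    if lineage.contains(policy.retain_rank, policy.retain_name):
        return Verdict.RETAIN, Reason.ADJUDICATED_LINEAGE_RETAIN
    return Verdict.DROP, Reason.ADJUDICATED_DROP


def screen_assembly(
    contigs: list[Contig],
    prior_manifest: dict[str, PriorLabel],
    hits: Iterable[BlastHit],
    lineages: dict[int, TaxonLineage],
    policy: ScreenPolicy = ScreenPolicy(),
) -> tuple[list[Contig], list[ClassificationDecision]]:
    """Screen an assembly; returns retained contigs (input order) and a
    per-contig audit trail.

    Every contig must carry a prior label belonging to one of the
    policy's three label sets.
    """
    hit_list = list(hits)
    scores = aggregate_hit_scores(hit_list, policy.evalue_max)
    retained: list[Contig] = []
    decisions: list[ClassificationDecision] = []

    any_hit_taxa: dict[str, set[int]] = defaultdict(set)
    if policy.any_hit_mode:
        for h in hit_list:
            if h.evalue < policy.evalue_max:
                any_hit_taxa[h.query_id].add(h.subject_taxid)

    for contig in contigs:
        label = prior_manifest.get(contig.id)
        if label is None:
            raise ScreenError(f"contig {contig.id} missing from prior manifest")
        if label in policy.prior_retain_labels:
            verdict, reason = Verdict.RETAIN, Reason.PRIOR_RETAIN
            taxid_scores: dict[int, float] = {}
            assigned = None
        elif label in policy.prior_drop_labels:
            verdict, reason = Verdict.DROP, Reason.PRIOR_DROP
            taxid_scores = {}
            assigned = None
        elif label in policy.adjudicate_labels:
            taxid_scores = scores.get(contig.id, {})
            assigned = assign_contig_taxon(taxid_scores)
            verdict, reason = decide_retention(assigned, lineages, policy)
            if policy.any_hit_mode and verdict is Verdict.DROP:
                for taxid in sorted(any_hit_taxa.get(contig.id, ())):
                    lin = lineages.get(taxid)
                    if lin is None:
                        raise ScreenError(
                            f"hit taxid {taxid} absent from lineage table"
                        )
                    if lin.contains(policy.retain_rank, policy.retain_name):
                        verdict, reason = (
                            Verdict.RETAIN,
                            Reason.ADJUDICATED_LINEAGE_RETAIN,
                        )
                        break
        else:
            raise ScreenError(
                f"contig {contig.id}: label {label.value!r} outside all policy sets"
            )
        decisions.append(
            ClassificationDecision(
                contig_id=contig.id,
                prior_label=label,
                taxid_scores=taxid_scores,
                assigned_taxid=assigned,
                verdict=verdict,
                reason=reason,
            )
        )
        if verdict is Verdict.RETAIN:
            retained.append(contig)
    return retained, decisions


def write_decision_report(
    decisions: Iterable[ClassificationDecision], path: str
) -> None:
    """TSV audit report: one row per contig."""
    with open(path, "w") as fh:
        fh.write("contig_id\tprior_label\tassigned_taxid\ttop_score\tverdict\treason\n")
        for d in decisions:
            top = (
                f"{d.taxid_scores[d.assigned_taxid]:g}"
                if d.assigned_taxid is not None
                else ""
            )
            fh.write(
                f"{d.contig_id}\t{d.prior_label.value}\t"
                f"{d.assigned_taxid if d.assigned_taxid is not None else ''}\t"
                f"{top}\t{d.verdict.value}\t{d.reason.value}\n"
            )
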