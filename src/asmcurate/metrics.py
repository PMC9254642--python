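"""Assembly contiguity statistics: thresholded counts/lengths, N50, L50.

N50 follows the cumulative-sum convention used by standard assembly QC
tools: sort contig lengths in descending order; N50 is the length of the
contig at which the running total first reaches at least half the
assembly total, and L50 is that contig's 1-based rank.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import AssemblyStats, AsmcurateError, Contig


class MetricsError(AsmcurateError):
    pass


DEFAULT_THRESHOLDS = (0, 25_000, 50_000)


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """(N50, L50) of a non-empty collection of contig lengths."""
    if not lengths:
        raise MetricsError("N50/L50 undefined for an empty assembly")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for rank, length in enumerate(ordered, start=1):
        running += length
        if running >= half:
            return length, rank
    raise AssertionError("unreachable: running total must reach half")


def contiguity_stats(
    lengths: Sequence[int],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> AssemblyStats:
    """Thresholded contig counts and total lengths plus N50/L50.

    ``counts_at[t]`` counts contigs of length >= t; ``lengths_at[t]``
    sums their lengths. Thresholds must be sorted ascending.
    """
    if list(thresholds) != sorted(thresholds):
        raise MetricsError("thresholds must be sorted ascending")
    counts_at = {t: sum(1 for l in lengths if l >= t) for t in thresholds}
    lengths_at = {t: sum(l for l in lengths if l >= t) for t in thresholds}
    n50, l50 = n50_l50(lengths)
    return AssemblyStats(
        thresholds=tuple(thresholds),
        counts_at=counts_at,
        lengths_at=lengths_at,
        n50=n50,
        l50=l50,
    )


def stats_from_contigs(
    contigs: Iterable[Contig],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> AssemblyStats:
    return contiguity_stats([c.length for c in contigs], thresholds)


def write_stats_tsv(stats: AssemblyStats, path: str) -> None:
    """TSV mirroring the usual assembly-report row labels."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for t in stats.thresholds:
            fh.write(f"# contigs (>={t:,} bp)\t{stats.counts_at[t]:,}\n")
        for t in stats.thresholds:
            fh.write(f"Total length (>={t:,} bp)\t{stats.lengths_at[t]:,}\n")
        fh.write(f"N50\t{stats.n50:,}\n")
        fh.write(f"L50\t{stats.l50:,}\n")
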