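"""Read QC and enrichment accounting for Cas9-targeted nanopore runs.

The quantities mirror how target-enrichment experiments are reported:
genome-wide coverage is total read yield over genome size; per-locus depth
is the mean primary-alignment pileup over the locus; and the enrichment
rate is their ratio — the fold excess of on-target depth over what the
same yield would give if spread uniformly across the genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .regions import TargetLocus

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP_BP = 200


@dataclass(frozen=True)
class ReadStats:
    """Summary of a read set after quality filtering."""

    n_reads: int
    total_bases: int
    n50: int
    min_qscore_applied: float


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-locus on-target accounting."""

    locus: TargetLocus
    n_on_target_reads: int
    mean_depth: float
    genome_coverage: float
    enrichment_rate: float


def mean_read_quality(quality: Sequence[int]) -> float:
    """Mean read Q-score via the mean per-base error probability.

    This matches basecaller-reported read Q-scores: errors average on the
    probability scale, then convert back to Phred, so a few very bad bases
    dominate as they should.
    """
    q = np.asarray(quality, dtype=float)
    if q.size == 0:
        return 0.0
    mean_err = np.mean(10.0 ** (-q / 10.0))
    return -10.0 * math.log10(mean_err)


def filter_reads_by_qscore(
    reads: str | Path | Iterable[tuple[str, str, Sequence[int]]],
    min_q: float = 8.0,
) -> tuple[ReadStats, list[tuple[str, str, list[int]]]]:
    """Retain reads whose mean quality exceeds *min_q*; summarise the rest.

    *reads* is a FASTQ path or an iterable of (name, sequence,
    per-base qualities).  A read is kept iff its mean quality — computed
    as ``-10*log10(mean per-base error probability)`` — is strictly
    greater than *min_q*.  Empty input yields zero stats, not an error.
    """
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)

    retained: list[tuple[str, str, list[int]]] = []
    for name, seq, qual in reads:
        if mean_read_quality(qual) > min_q:
            retained.append((name, seq, list(qual)))

    lengths = [len(seq) for _, seq, _ in retained]
    stats = ReadStats(
        n_reads=len(retained),
        total_bases=sum(lengths),
        n50=compute_n50(lengths) if lengths else 0,
        min_qscore_applied=min_q,
    )
    return stats, retained


def _iter_fastq(path: str | Path):
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.quality is None:
                raise ValueError(f"read {entry.name!r} has no quality string")
            yield entry.name, entry.sequence, entry.get_quality_array()


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest read length L such that reads of length >= L hold half the yield."""
    if not lengths:
        raise ValueError("N50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("read lengths must be positive")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, arr.size - 1)])


def _is_primary(aln: pysam.AlignedSegment) -> bool:
    return not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)


def _open_alignments(alignments) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments), check_sq=False), True
    return alignments, False


def _check_references(af: pysam.AlignmentFile, loci: Iterable[TargetLocus]) -> None:
    refs = set(af.references or ())
    for locus in loci:
        if locus.reference_id not in refs:
            raise ValueError(
                f"locus {locus.name!r}: reference {locus.reference_id!r} "
                "is absent from the alignment header"
            )


def classify_on_target(
    alignments,
    loci: Sequence[TargetLocus],
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> dict[str, set[str]]:
    """Assign read names to loci by primary-alignment overlap.

    A read is on-target for a locus iff its primary alignment overlaps the
    locus interval by at least *min_overlap_bp* aligned reference bases.
    Unmapped, secondary and supplementary records are ignored, so each
    read is counted at most once per locus.  Returns ``{locus.name:
    set(read names)}``.
    """
    af, owned = _open_alignments(alignments)
    try:
        _check_references(af, loci)
        hits: dict[str, set[str]] = {locus.name: set() for locus in loci}
        for aln in af.fetch(until_eof=True):
            if not _is_primary(aln):
                continue
            for locus in loci:
                if aln.reference_name != locus.reference_id:
                    continue
                overlap = aln.get_overlap(locus.start, locus.end)
                if overlap is not None and overlap >= min_overlap_bp:
                    hits[locus.name].add(aln.query_name)
        return hits
    finally:
        if owned:
            af.close()


def mean_target_depth(alignments, locus: TargetLocus) -> float:
    """Mean per-position primary-alignment depth over the locus.

    A position is covered by the aligned (M/=/X) bases of a primary
    alignment; deletions in the read do not cover, insertions do not add.
    """
    af, owned = _open_alignments(alignments)
    try:
        _check_references(af, [locus])
        covered = 0
        for aln in af.fetch(until_eof=True):
            if not _is_primary(aln) or aln.reference_name != locus.reference_id:
                continue
            for b_start, b_end in aln.get_blocks():
                covered += max(0, min(b_end, locus.end) - max(b_start, locus.start))
        return covered / locus.length
    finally:
        if owned:
            af.close()


def genome_coverage(total_bases: int, genome_size: int) -> float:
    """Genome-wide coverage (x) from total read yield and genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_bases / genome_size


def enrichment_rate(mean_depth: float, genome_cov: float) -> float:
    """Fold enrichment: on-target mean depth over genome-wide coverage."""
    if genome_cov <= 0:
        raise ValueError("genome coverage must be positive to compute enrichment")
    return mean_depth / genome_cov


def on_target_fraction(
    per_locus_reads: Mapping[str, set[str]] | Mapping[str, int],
    n_total_reads: int,
) -> float:
    """Fraction of all reads that are on-target for at least one locus.

    Accepts either the read-name sets from :func:`classify_on_target`
    (unioned, so a read spanning two loci counts once) or plain per-locus
    counts (summed).
    """
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    values = list(per_locus_reads.values())
    if values and isinstance(values[0], (set, frozenset)):
        n_on = len(set().union(*values))
    else:
        n_on = sum(values)
    return n_on / n_total_reads


def enrichment_report(
    alignments,
    loci: Sequence[TargetLocus],
    total_bases: int,
    genome_size: int,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> list[EnrichmentReport]:
    """Full per-locus accounting: counts, depth, coverage, enrichment."""
    if not isinstance(alignments, (str, Path)):
        raise TypeError(
            "enrichment_report needs an alignment file path: it scans the "
            "records once per locus"
        )
    cov = genome_coverage(total_bases, genome_size)
    hits = classify_on_target(alignments, loci, min_overlap_bp=min_overlap_bp)
    reports = []
    for locus in loci:
        depth = mean_target_depth(alignments, locus)
        reports.append(
            EnrichmentReport(
                locus=locus,
                n_on_target_reads=len(hits[locus.name]),
                mean_depth=depth,
                genome_coverage=cov,
                enrichment_rate=enrichment_rate(depth, cov) if cov > 0 else float("nan"),
            )
        )
    return reports
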