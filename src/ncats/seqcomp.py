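"""Sequence-composition characterisation: CpG islands and self-similarity.

CpG islands follow the classical sliding-window definition (length >= 200
bp, GC fraction > 0.5, observed/expected CpG > 0.6): qualifying windows
are merged and each merged run is trimmed to its maximal qualifying
extents.  Repeats are delineated by an exact k-mer self-match dot plot —
deterministic and directly checkable, in place of scored local-alignment
dot plots — whose off-diagonal match coverage marks low-complexity /
repetitive tracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequtil import revcomp, validate_dna

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 200
DEFAULT_GC_MIN = 0.5
DEFAULT_OE_MIN = 0.6


@dataclass(frozen=True)
class CpGIsland:
    """A maximal interval meeting all three island criteria."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatSegment:
    """A tract whose bases are covered by off-diagonal k-mer self-matches."""

    start: int
    end: int
    self_match_density: float

    @property
    def length(self) -> int:
        return self.end - self.start


class _IslandCriteria:
    """O(1) interval statistics via prefix sums, plus the qualifying test.

    GC fraction excludes N bases from the denominator; the CpG
    observed/expected ratio is ``n_CpG / (n_C * n_G / length)`` with the
    interval length as printed in the classical definition.
    """

    def __init__(self, seq: str, min_length: int, gc_min: float, oe_min: float):
        self.min_length = min_length
        self.gc_min = gc_min
        self.oe_min = oe_min
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        is_n = arr == b"N"
        is_cpg = np.zeros(len(seq), dtype=bool)
        if len(seq) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        self._c = np.concatenate([[0], np.cumsum(is_c)])
        self._g = np.concatenate([[0], np.cumsum(is_g)])
        self._n = np.concatenate([[0], np.cumsum(is_n)])
        self._cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    def stats(self, a: int, b: int) -> tuple[float, float]:
        """(gc_fraction, obs_exp_cpg) of [a, b); 0.0 where undefined."""
        n_c = int(self._c[b] - self._c[a])
        n_g = int(self._g[b] - self._g[a])
        denom = (b - a) - int(self._n[b] - self._n[a])
        gc = (n_c + n_g) / denom if denom > 0 else 0.0
        # CpG dinucleotides must lie wholly inside [a, b)
        n_cpg = int(self._cpg[b - 1] - self._cpg[a]) if b - 1 > a else 0
        oe = n_cpg * (b - a) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
        return gc, oe

    def qualifies(self, a: int, b: int) -> bool:
        if b - a < self.min_length:
            return False
        gc, oe = self.stats(a, b)
        return gc > self.gc_min and oe > self.oe_min

    def qualifying_windows(self) -> np.ndarray:
        """Boolean vector over all start positions of min_length windows."""
        L = self.min_length
        n = len(self._c) - 1
        if n < L:
            return np.zeros(0, dtype=bool)
        starts = np.arange(n - L + 1)
        n_c = self._c[starts + L] - self._c[starts]
        n_g = self._g[starts + L] - self._g[starts]
        denom = L - (self._n[starts + L] - self._n[starts])
        n_cpg = self._cpg[starts + L - 1] - self._cpg[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(denom > 0, (n_c + n_g) / np.maximum(denom, 1), 0.0)
            prod = n_c * n_g
            oe = np.where(prod > 0, n_cpg * L / np.maximum(prod, 1), 0.0)
        return (gc > self.gc_min) & (oe > self.oe_min)


def find_cpg_islands(
    seq: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    gc_min: float = DEFAULT_GC_MIN,
    oe_min: float = DEFAULT_OE_MIN,
) -> list[CpGIsland]:
    """Find CpG islands by qualifying-window merge and maximal trimming.

    Every window of exactly *min_length* (step 1) is tested against the
    three criteria; overlapping qualifying windows merge into candidate
    runs; within each run the maximal qualifying subintervals (those not
    contained in a larger qualifying subinterval of the run) are kept and
    overlaps among them resolved left-to-right, longest first.  The
    result is sorted and non-overlapping.  Sequences shorter than
    *min_length* yield an empty list.
    """
    seq = validate_dna(seq, what="sequence")
    n = len(seq)
    if n < min_length:
        return []
    crit = _IslandCriteria(seq, min_length, gc_min, oe_min)

    # 1. qualifying seed windows -> merged candidate runs
    runs: list[list[int]] = []
    for a in np.flatnonzero(crit.qualifying_windows()):
        a = int(a)
        if runs and a <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], a + min_length)
        else:
            runs.append([a, a + min_length])

    islands: list[CpGIsland] = []
    for run_start, run_end in runs:
        maximal = _maximal_qualifying(crit, run_start, run_end)
        islands.extend(
            CpGIsland(a, b, *crit.stats(a, b))
            for a, b in _greedy_nonoverlapping(maximal)
        )
    islands.sort(key=lambda i: i.start)
    return islands


def _maximal_qualifying(
    crit: _IslandCriteria, run_start: int, run_end: int
) -> list[tuple[int, int]]:
    """All qualifying subintervals of the run not contained in a larger one.

    Processed by descending length, so containment only needs checking
    against already-accepted (longer or equal) intervals.
    """
    accepted: list[tuple[int, int]] = []
    for length in range(run_end - run_start, crit.min_length - 1, -1):
        for a in range(run_start, run_end - length + 1):
            b = a + length
            if not crit.qualifies(a, b):
                continue
            if any(aa <= a and b <= bb and (aa, bb) != (a, b) for aa, bb in accepted):
                continue
            accepted.append((a, b))
    return accepted


def _greedy_nonoverlapping(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Resolve overlaps left-to-right, preferring longer intervals on ties."""
    chosen: list[tuple[int, int]] = []
    for a, b in sorted(intervals, key=lambda iv: (iv[0], -(iv[1] - iv[0]))):
        if all(b <= ca or cb <= a for ca, cb in chosen):
            chosen.append((a, b))
    return sorted(chosen)


def dotplot_matches(
    seq: str,
    k: int = 15,
    max_offset_merge: int = 10,
    min_density: float = 1.0,
    max_pairs_per_kmer: int = 200,
) -> tuple[list[RepeatSegment], list[tuple[int, int, str]]]:
    """Exact k-mer self-matches off the main diagonal, on both strands.

    Returns ``(segments, matches)`` where matches are ``(i, j, strand)``
    start-position pairs with ``i < j`` (``strand`` '+' for direct,
    '-' for reverse-complement matches; the symmetric pair is implied)
    and segments are maximal tracts whose per-base off-diagonal match
    coverage is at least *min_density*, with gaps up to
    *max_offset_merge* bridged.  K-mers containing N are skipped.  A
    k-mer occurring pathologically often still contributes coverage but
    its pair list is truncated (logged).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    seq = validate_dna(seq, what="sequence")
    n = len(seq)
    if n < k:
        return [], []

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        positions.setdefault(kmer, []).append(i)

    coverage = np.zeros(n, dtype=np.int64)
    matches: list[tuple[int, int, str]] = []

    def cover(i: int, j: int) -> None:
        coverage[i:i + k] += 1
        coverage[j:j + k] += 1

    for kmer, pos_list in positions.items():
        # direct repeats
        if len(pos_list) > 1:
            n_pairs = len(pos_list) * (len(pos_list) - 1) // 2
            if n_pairs > max_pairs_per_kmer:
                logger.warning(
                    "k-mer occurs %d times; match list truncated", len(pos_list)
                )
                for p in pos_list:
                    coverage[p:p + k] += len(pos_list) - 1
            else:
                for x in range(len(pos_list)):
                    for y in range(x + 1, len(pos_list)):
                        matches.append((pos_list[x], pos_list[y], "+"))
                        cover(pos_list[x], pos_list[y])
        # inverted repeats: this k-mer vs occurrences of its reverse complement
        rc = revcomp(kmer)
        if rc > kmer:
            continue  # handle each {kmer, rc} pair once
        rc_list = positions.get(rc, []) if rc != kmer else pos_list
        if rc == kmer:
            # palindromic k-mer: i == j is the trivial anti-diagonal hit
            pairs = [
                (a, b) for ai, a in enumerate(pos_list)
                for b in pos_list[ai + 1:]
            ]
        else:
            pairs = [
                (min(a, b), max(a, b)) for a in pos_list for b in rc_list
                if a != b
            ]
        if len(pairs) > max_pairs_per_kmer:
            logger.warning("inverted-repeat match list truncated")
            pairs = pairs[:max_pairs_per_kmer]
        for a, b in pairs:
            matches.append((a, b, "-"))
            cover(a, b)

    segments = _segments_from_coverage(
        coverage, min_density, max_offset_merge, k
    )
    matches.sort()
    return segments, matches


def _segments_from_coverage(
    coverage: np.ndarray, min_density: float, merge_gap: int, k: int
) -> list[RepeatSegment]:
    above = coverage >= min_density
    segments: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append([start, i])
            start = None
    if start is not None:
        segments.append([start, len(above)])
    # bridge short gaps
    merged: list[list[int]] = []
    for s, e in segments:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        RepeatSegment(s, e, float(coverage[s:e].mean()))
        for s, e in merged
        if e - s >= k
    ]


def unique_region(
    seq_length: int,
    repeat_segments: Sequence[RepeatSegment],
    upstream_of_first_repeat: bool = False,
) -> list[tuple[int, int]]:
    """Complement of the repeat segments within [0, seq_length).

    With *upstream_of_first_repeat*, only the interval before the first
    repeat is returned (the non-repetitive part of a coding sequence
    upstream of a low-complexity tract).
    """
    segs = sorted((s.start, s.end) for s in repeat_segments)
    out: list[tuple[int, int]] = []
    cursor = 0
    for s, e in segs:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < seq_length:
        out.append((cursor, seq_length))
    if upstream_of_first_repeat:
        if not segs:
            return [(0, seq_length)]
        first = segs[0][0]
        return [(s, e) for s, e in out if e <= first]
    return out
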