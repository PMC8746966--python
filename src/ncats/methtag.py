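"""Per-read methylation calls -> standard SAM MM/ML base-modification tags.

Nanopore methylation callers emit one row per cytosine per read, anchored
to reference coordinates.  Genome browsers, by contrast, colour modified
bases from the MM:Z/ML:B tags defined on the read's own sequence in its
original (pre-alignment) orientation.  This module is the bridge: it maps
each reference-anchored call onto the read through the alignment CIGAR,
re-expresses the coordinate in original orientation, and encodes the
listed cytosines as delta-skip counts with 0-255 probabilities.

Skip mode is ``?`` (unlisted cytosines have *unknown* status): calls from
a targeted run are sparse per read, and the implicit-unmodified mode
would silently assert unmodified status for every C the caller never
scored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from .sequtil import revcomp

logger = logging.getLogger(__name__)

#: column layouts for per-read caller tables (all tab-separated).
#: ``deepsignal-plant``: chrom, pos, strand, pos_in_strand, read name,
#: read strand, prob_unmeth, prob_meth, called label, k-mer context.
DIALECTS: dict[str, dict[str, int]] = {
    "deepsignal-plant": {
        "reference_id": 0,
        "ref_pos": 1,
        "ref_strand": 2,
        "read_id": 4,
        "prob_meth": 7,
        "called_label": 8,
        "context": 9,
    },
}

_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class PerReadMethCall:
    """One cytosine call on one read, anchored to the reference.

    ``ref_pos`` is the 0-based forward-reference coordinate of the called
    base; for ``ref_strand == '-'`` the cytosine sits on the reverse
    strand (the forward base there is a G).
    """

    read_id: str
    reference_id: str
    ref_pos: int
    ref_strand: str
    prob_meth: float
    context: str | None = None
    called_label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_meth <= 1.0:
            raise ValueError(f"prob_meth outside [0,1]: {self.prob_meth}")
        if self.ref_pos < 0:
            raise ValueError(f"negative ref_pos: {self.ref_pos}")
        if self.ref_strand not in "+-":
            raise ValueError(f"ref_strand must be '+' or '-', got {self.ref_strand!r}")


@dataclass
class ParseReport:
    """Outcome of parsing a caller table."""

    calls: list[PerReadMethCall]
    n_rows: int = 0
    n_rejected: int = 0


def parse_meth_calls(
    table: str | Path | Iterable[str],
    dialect: str = "deepsignal-plant",
) -> ParseReport:
    """Parse a per-read methylation-call table into :class:`PerReadMethCall`.

    Rows for reads absent from any downstream alignment are retained
    (filtering happens at tagging time).  Malformed rows — wrong column
    count, non-numeric fields, probability outside [0,1] — are rejected
    with a warning and counted in the report.
    """
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    cols = DIALECTS[dialect]
    n_cols_needed = max(cols.values()) + 1

    if isinstance(table, (str, Path)):
        stream: Iterable[str] = open(table)
        close = True
    else:
        stream, close = table, False

    report = ParseReport(calls=[])
    try:
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.n_rows += 1
            fields = line.split("\t")
            try:
                if len(fields) < n_cols_needed:
                    raise ValueError(f"{len(fields)} columns, need {n_cols_needed}")
                call = PerReadMethCall(
                    read_id=fields[cols["read_id"]],
                    reference_id=fields[cols["reference_id"]],
                    ref_pos=int(fields[cols["ref_pos"]]),
                    ref_strand=fields[cols["ref_strand"]],
                    prob_meth=float(fields[cols["prob_meth"]]),
                    context=fields[cols["context"]] or None,
                    called_label=int(fields[cols["called_label"]]),
                )
            except (ValueError, IndexError) as exc:
                report.n_rejected += 1
                logger.warning("rejected call row (%s): %s", exc, line[:120])
                continue
            report.calls.append(call)
    finally:
        if close:
            stream.close()
    return report


def parse_cigar(cigar: str | Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    """Normalise a CIGAR string or (op, length) list to (op, length) tuples."""
    if isinstance(cigar, str):
        ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
        if "".join(f"{n}{o}" for o, n in ops) != cigar:
            raise ValueError(f"malformed CIGAR string {cigar!r}")
        return ops
    return [(op, int(n)) for op, n in cigar]


def aligned_pairs(
    cigar: str | Sequence[tuple[str, int]], aln_start: int
) -> Iterator[tuple[int, int]]:
    """Yield (ref_pos, query_pos) for every aligned (M/=/X) base of the CIGAR."""
    ref, query = aln_start, 0
    for op, n in parse_cigar(cigar):
        if op in "M=X":
            for i in range(n):
                yield ref + i, query + i
            ref += n
            query += n
        elif op in "IS":
            query += n
        elif op in "DN":
            ref += n
        # H and P consume nothing


def ref_to_read_positions(
    cigar: str | Sequence[tuple[str, int]],
    aln_start: int,
    is_reverse: bool,
    read_length: int,
    ref_positions: Sequence[int],
) -> dict[int, int]:
    """Map sorted reference positions to read positions in original orientation.

    Positions that fall in deletions/skips or outside the aligned span are
    absent from the result.  For reverse-strand alignments the returned
    coordinate is re-expressed in the read's original orientation:
    ``read_pos_original = read_length - 1 - read_pos_in_SEQ``.
    """
    ops = parse_cigar(cigar)
    query_len = sum(n for op, n in ops if op in _QUERY_CONSUMING)
    if query_len != read_length:
        raise ValueError(
            f"CIGAR consumes {query_len} query bases but read_length is "
            f"{read_length}"
        )

    targets = sorted(ref_positions)
    mapping: dict[int, int] = {}
    ti = 0
    ref, query = aln_start, 0
    for op, n in ops:
        if ti >= len(targets):
            break
        if op in "M=X":
            while ti < len(targets) and targets[ti] < ref + n:
                t = targets[ti]
                if t >= ref:
                    mapping[t] = query + (t - ref)
                ti += 1
            ref += n
            query += n
        elif op in "IS":
            query += n
        elif op in "DN":
            # positions inside a deletion/skip have no read base
            while ti < len(targets) and targets[ti] < ref + n:
                ti += 1
            ref += n
    if is_reverse:
        mapping = {t: read_length - 1 - q for t, q in mapping.items()}
    return mapping


def encode_mm(
    read_seq_original_orientation: str,
    mod_positions: Sequence[int],
    probs: Sequence[float],
    base: str = "C",
    code: str = "m",
    skip_mode: str = "?",
) -> tuple[str, list[int]]:
    """Encode modified positions on a read as an (MM, ML) tag pair.

    *mod_positions* are strictly increasing indices into the read's
    original-orientation sequence, each of which must hold *base*.  The
    MM deltas count the *skipped* canonical bases between consecutive
    listed positions; ML holds ``floor(prob * 256)`` capped at 255.
    Returns ``("", [])`` when there is nothing to encode.
    """
    if len(mod_positions) != len(probs):
        raise ValueError("mod_positions and probs differ in length")
    if not mod_positions:
        return "", []
    seq = read_seq_original_orientation
    deltas = []
    prev_end = 0  # scan cursor: one past the previously listed position
    last = -1
    for pos in mod_positions:
        if pos <= last:
            raise ValueError("mod_positions must be strictly increasing")
        last = pos
        if pos >= len(seq) or seq[pos] != base:
            found = seq[pos] if pos < len(seq) else "<end>"
            raise ValueError(
                f"modified position {pos} holds {found!r}, expected {base!r} "
                "(upstream coordinate mapping is inconsistent with the read)"
            )
        deltas.append(seq.count(base, prev_end, pos))
        prev_end = pos + 1
    mm = f"{base}+{code}{skip_mode}," + ",".join(str(d) for d in deltas) + ";"
    ml = [min(int(p * 256), 255) for p in probs]
    return mm, ml


_MM_BLOCK_RE = re.compile(
    r"(?P<base>[ACGTUN])(?P<strand>[-+])(?P<codes>[a-z]+|\d+)"
    r"(?P<skip>[.?]?)(?P<deltas>(?:,\d+)*);"
)


def decode_mm(
    read_seq_original_orientation: str,
    mm_tag: str,
    ml_values: Sequence[int] | None = None,
) -> tuple[list[int], list[float]]:
    """Decode an MM/ML tag pair back to read positions and probabilities.

    Inverse of :func:`encode_mm` up to the 1/256 probability quantisation.
    Probabilities come back as ``ml / 256`` (the low edge of the encoded
    bin); when *ml_values* is None, probabilities are returned as NaN.
    """
    if not mm_tag:
        return [], []
    blocks = list(_MM_BLOCK_RE.finditer(mm_tag))
    if not blocks or "".join(b.group(0) for b in blocks) != mm_tag:
        raise ValueError(f"malformed MM tag {mm_tag!r}")

    seq = read_seq_original_orientation
    positions: list[int] = []
    probs: list[float] = []
    ml_cursor = 0
    for block in blocks:
        base = block.group("base")
        deltas = [int(d) for d in block.group("deltas").split(",")[1:]]
        base_positions = [i for i, c in enumerate(seq) if c == base]
        cursor = 0
        for delta in deltas:
            cursor += delta
            if cursor >= len(base_positions):
                raise ValueError(
                    f"MM tag skips past the last {base!r} in the read "
                    f"(delta run exceeds {len(base_positions)} bases)"
                )
            positions.append(base_positions[cursor])
            cursor += 1
        n = len(deltas)
        if ml_values is not None:
            chunk = ml_values[ml_cursor: ml_cursor + n]
            if len(chunk) != n:
                raise ValueError("ML has fewer values than MM lists positions")
            probs.extend(v / 256.0 for v in chunk)
        else:
            probs.extend([float("nan")] * n)
        ml_cursor += n
    if ml_values is not None and ml_cursor != len(ml_values):
        raise ValueError("ML has more values than MM lists positions")
    return positions, probs


@dataclass
class TagReport:
    """Counters from a tagging run."""

    n_alignments: int = 0
    n_tagged: int = 0
    n_passed_through: int = 0
    n_calls_mapped: int = 0
    n_calls_dropped_unmapped: int = 0   # deletion/clip/outside aligned span
    n_calls_dropped_strand: int = 0     # call strand opposite the read's strand
    n_calls_dropped_not_c: int = 0      # sequencing error under the call


def index_calls(
    calls: Iterable[PerReadMethCall],
) -> dict[str, list[PerReadMethCall]]:
    """Group calls by read id for tagging."""
    by_read: dict[str, list[PerReadMethCall]] = {}
    for call in calls:
        by_read.setdefault(call.read_id, []).append(call)
    return by_read


def tag_alignment(
    aln: pysam.AlignedSegment,
    read_calls: Sequence[PerReadMethCall],
    report: TagReport,
    emit_ml: bool = True,
) -> bool:
    """Attach MM (and optionally ML) tags for one primary alignment in place.

    Only calls on the strand the read was sequenced from can present as a
    cytosine on the read, so opposite-strand calls are dropped (counted).
    Calls landing in deletions, or on a non-C read base (a sequencing
    error), are likewise dropped with counters.  Existing MM/ML tags are
    replaced, never duplicated.  Returns True if tags were written.
    """
    # a '+' strand call is a C on the forward reference strand; the read
    # presents it as 'C' only if it was sequenced from that same strand
    keep = [
        c for c in read_calls
        if (c.reference_id == aln.reference_name)
        and ((c.ref_strand == "+") != aln.is_reverse)
    ]
    report.n_calls_dropped_strand += len(read_calls) - len(keep)
    if not keep:
        return False

    seq = aln.query_sequence
    if seq is None:
        logger.warning("read %s has no SEQ; skipped", aln.query_name)
        return False
    read_length = len(seq)
    seq_original = revcomp(seq) if aln.is_reverse else seq

    by_pos = {c.ref_pos: c for c in keep}
    mapping = ref_to_read_positions(
        aln.cigarstring, aln.reference_start, aln.is_reverse,
        read_length, sorted(by_pos),
    )
    report.n_calls_dropped_unmapped += len(by_pos) - len(mapping)

    items = []
    for ref_pos, read_pos in mapping.items():
        if seq_original[read_pos] != "C":
            report.n_calls_dropped_not_c += 1
            continue
        items.append((read_pos, by_pos[ref_pos].prob_meth))
    if not items:
        return False
    items.sort()
    positions = [p for p, _ in items]
    probs = [pr for _, pr in items]
    report.n_calls_mapped += len(items)

    mm, ml = encode_mm(seq_original, positions, probs)
    # idempotent: clear any prior modification tags before writing
    for tag in ("MM", "ML", "Mm", "Ml"):
        if aln.has_tag(tag):
            aln.set_tag(tag, None)
    aln.set_tag("MM", mm, value_type="Z")
    if emit_ml:
        aln.set_tag("ML", array_to_ml(ml))
    return True


def array_to_ml(values: Sequence[int]):
    """ML tag payload as an unsigned 8-bit array (B:C in SAM text)."""
    from array import array

    return array("B", values)


def tag_alignments(
    alignments: str | Path,
    calls: Iterable[PerReadMethCall] | Mapping[str, Sequence[PerReadMethCall]],
    out_path: str | Path,
    emit_ml: bool = True,
) -> TagReport:
    """Tag every primary alignment that has mappable calls; write SAM/BAM.

    Alignments without calls pass through with identical content.  The
    output mode follows the *out_path* suffix (``.bam`` binary, otherwise
    SAM with header).
    """
    by_read = calls if isinstance(calls, Mapping) else index_calls(calls)
    report = TagReport()
    mode = "wb" if str(out_path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(alignments), check_sq=False) as in_f:
        with pysam.AlignmentFile(str(out_path), mode, template=in_f) as out_f:
            for aln in in_f.fetch(until_eof=True):
                report.n_alignments += 1
                read_calls = by_read.get(aln.query_name, ())
                tagged = False
                if (
                    read_calls
                    and not aln.is_unmapped
                    and not aln.is_secondary
                    and not aln.is_supplementary
                ):
                    tagged = tag_alignment(aln, read_calls, report, emit_ml=emit_ml)
                if tagged:
                    report.n_tagged += 1
                else:
                    report.n_passed_through += 1
                out_f.write(aln)
    logger.info(
        "tagged %d/%d alignments (%d calls mapped; dropped: %d unmapped, "
        "%d strand, %d not-C)",
        report.n_tagged, report.n_alignments, report.n_calls_mapped,
        report.n_calls_dropped_unmapped, report.n_calls_dropped_strand,
        report.n_calls_dropped_not_c,
    )
    return report


def calls_from_alignment(aln: pysam.AlignedSegment) -> list[PerReadMethCall]:
    """Decode MM/ML tags of one alignment back to reference-anchored calls.

    The round-trip complement of :func:`tag_alignment`: read positions are
    decoded from the tag, then pushed back through the CIGAR to reference
    coordinates.  Positions that no longer map (should not happen for tags
    this package wrote) are silently dropped.
    """
    if not aln.has_tag("MM"):
        return []
    seq = aln.query_sequence
    if seq is None:
        return []
    read_length = len(seq)
    seq_original = revcomp(seq) if aln.is_reverse else seq
    ml = list(aln.get_tag("ML")) if aln.has_tag("ML") else None
    positions, probs = decode_mm(seq_original, aln.get_tag("MM"), ml)

    # invert: original-orientation position -> SEQ index -> ref position
    if aln.is_reverse:
        seq_indices = {read_length - 1 - p: p for p in positions}
    else:
        seq_indices = {p: p for p in positions}
    prob_by_orig = dict(zip(positions, probs))

    strand = "-" if aln.is_reverse else "+"
    calls = []
    for ref_pos, q_pos in aligned_pairs(aln.cigarstring, aln.reference_start):
        if q_pos in seq_indices:
            orig = seq_indices[q_pos]
            calls.append(
                PerReadMethCall(
                    read_id=aln.query_name,
                    reference_id=aln.reference_name,
                    ref_pos=ref_pos,
                    ref_strand=strand,
                    prob_meth=prob_by_orig[orig],
                )
            )
    return calls
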