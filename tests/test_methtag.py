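"""MM/ML tag encoding, CIGAR coordinate mapping, and BAM tagging."""

import io

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncats.methtag import (
    PerReadMethCall,
    calls_from_alignment,
    decode_mm,
    encode_mm,
    parse_meth_calls,
    ref_to_read_positions,
    tag_alignments,
)
from ncats.sequtil import revcomp

from _samutil import write_sam


def _call(read_id="r1", ref="chr1", pos=10, strand="+", prob=0.9):
    return PerReadMethCall(
        read_id=read_id, reference_id=ref, ref_pos=pos,
        ref_strand=strand, prob_meth=prob,
    )


class TestParseCalls:
    @staticmethod
    def _row(pos=5, prob=0.9, read="r1"):
        return (
            f"chr1\t{pos}\t+\t{pos}\t{read}\tt\t{1 - prob:.3f}\t{prob:.3f}\t1\tACGCACGCACGCA"
        )

    def test_toy_table_round_trips_fields(self):
        rows = [self._row(5, 0.9), self._row(9, 0.1, "r2"), self._row(12, 0.5)]
        report = parse_meth_calls(iter(rows))
        assert report.n_rows == 3 and report.n_rejected == 0
        assert [c.prob_meth for c in report.calls] == [0.9, 0.1, 0.5]
        assert report.calls[1].read_id == "r2"
        assert report.calls[0].ref_pos == 5
        assert report.calls[0].context == "ACGCACGCACGCA"

    def test_probability_outside_unit_interval_rejected(self):
        rows = [self._row(5, 0.9), self._row(6, 1.3), self._row(7, 0.2)]
        report = parse_meth_calls(iter(rows))
        assert report.n_rejected == 1
        assert len(report.calls) == 2

    def test_short_row_rejected(self):
        report = parse_meth_calls(iter(["chr1\t5\t+"]))
        assert report.n_rejected == 1 and report.calls == []

    def test_unknown_dialect(self):
        with pytest.raises(ValueError, match="dialect"):
            parse_meth_calls(iter([]), dialect="nonexistent")

    def test_simulated_table_count_preserved(self, sim_files):
        paths, _ = sim_files
        n_lines = sum(1 for _ in open(paths["calls"]))
        report = parse_meth_calls(paths["calls"])
        assert len(report.calls) == n_lines and report.n_rejected == 0


class TestRefToReadPositions:
    def test_simple_forward_match(self):
        assert ref_to_read_positions("10M", 100, False, 10, [102]) == {102: 2}

    def test_softclip_and_deletion(self):
        m = ref_to_read_positions("2S4M1D4M", 50, False, 10, [54, 55])
        assert 54 not in m          # deleted base has no read coordinate
        assert m[55] == 6

    def test_reverse_strand_reports_original_orientation(self):
        m = ref_to_read_positions("10M", 100, True, 10, [102])
        assert m == {102: 7}        # SEQ index 2 -> original index 10-1-2

    def test_positions_outside_alignment_absent(self):
        m = ref_to_read_positions("10M", 100, False, 10, [99, 100, 109, 110])
        assert m == {100: 0, 109: 9}

    def test_cigar_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="read_length"):
            ref_to_read_positions("5M", 0, False, 10, [2])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_pysam_aligned_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cigar, read_len = _random_cigar(rng)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 100_000}]}
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.reference_id = 0
        a.reference_start = 500
        a.cigarstring = cigar
        a.query_sequence = "A" * read_len
        oracle = {
            r: q for q, r in a.get_aligned_pairs(matches_only=True)
        }
        span_positions = list(range(500, a.reference_end + 1))
        got = ref_to_read_positions(cigar, 500, False, read_len, span_positions)
        assert got == oracle


def _random_cigar(rng) -> tuple[str, int]:
    """Random valid CIGAR with ops M/I/D/S/=/X, soft clips only at the ends."""
    n_ops = int(rng.integers(1, 50))
    ops = []
    prev = None
    for _ in range(n_ops):
        op = str(rng.choice(["M", "I", "D", "=", "X"]))
        if op == prev or (prev is not None and op in "ID" and prev in "ID"):
            op = "M"
        ops.append((op, int(rng.integers(1, 30))))
        prev = op
    # ensure the alignment starts and ends with a reference-consuming op
    ops = [("M", int(rng.integers(1, 30)))] + ops + [("M", int(rng.integers(1, 30)))]
    if rng.random() < 0.5:
        ops = [("S", int(rng.integers(1, 10)))] + ops
    if rng.random() < 0.5:
        ops = ops + [("S", int(rng.integers(1, 10)))]
    merged = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += ln
        else:
            merged.append([op, ln])
    cigar = "".join(f"{ln}{op}" for op, ln in merged)
    read_len = sum(ln for op, ln in merged if op in "MIS=X")
    return cigar, read_len


class TestEncodeMM:
    def test_single_position_counts_skipped_cs(self):
        mm, ml = encode_mm("ACGCA", [3], [1.0])
        assert mm == "C+m?,1;"
        assert ml == [255]

    def test_no_positions_no_tags(self):
        assert encode_mm("ACGT", [], []) == ("", [])

    def test_consecutive_deltas_and_probability_quantisation(self):
        mm, ml = encode_mm("CCCC", [0, 3], [0.5, 0.25])
        assert mm == "C+m?,0,2;"
        assert ml == [128, 64]

    def test_position_not_on_c_is_an_error(self):
        with pytest.raises(ValueError, match="expected 'C'"):
            encode_mm("ACGT", [0], [0.5])

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            encode_mm("CCCC", [2, 1], [0.5, 0.5])


class TestDecodeMM:
    @pytest.mark.parametrize(
        "seq,positions,probs",
        [
            ("ACGCA", [3], [1.0]),
            ("CCCC", [0, 3], [0.5, 0.25]),
            ("CGCGCGCG", [0, 2, 6], [0.1, 0.9, 0.7]),
        ],
    )
    def test_round_trip(self, seq, positions, probs):
        mm, ml = encode_mm(seq, positions, probs)
        got_pos, got_probs = decode_mm(seq, mm, ml)
        assert got_pos == positions
        for got, orig in zip(got_probs, probs):
            assert abs(got - orig) <= 1 / 256

    def test_empty_tag(self):
        assert decode_mm("ACGT", "", []) == ([], [])

    def test_malformed_tag_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            decode_mm("ACGT", "C+m?not-a-tag", [])

    def test_tampered_delta_shifts_or_breaks(self):
        mm, ml = encode_mm("CCCC", [0, 3], [0.5, 0.25])
        tampered = mm.replace(",0,", ",1,")
        try:
            pos, _ = decode_mm("CCCC", tampered, ml)
        except ValueError:
            return  # shifted deltas ran past the last C: detected
        assert pos != [0, 3]

    def test_delta_past_last_c_is_an_error(self):
        with pytest.raises(ValueError, match="skips past"):
            decode_mm("CC", "C+m?,5;", [10])

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_round_trip_property(self, data):
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=1, max_size=120), label="seq"
        )
        c_positions = [i for i, ch in enumerate(seq) if ch == "C"]
        if not c_positions:
            return
        chosen = sorted(
            data.draw(
                st.sets(st.sampled_from(c_positions), min_size=1),
                label="positions",
            )
        )
        probs = data.draw(
            st.lists(
                st.floats(0, 1), min_size=len(chosen), max_size=len(chosen)
            ),
            label="probs",
        )
        mm, ml = encode_mm(seq, chosen, probs)
        got_pos, got_probs = decode_mm(seq, mm, ml)
        assert got_pos == chosen
        assert all(abs(g - p) <= 1 / 256 for g, p in zip(got_probs, probs))


REF = "chr1"


def _aligned_record(name, start, seq, flag=0, cigar=None):
    return {"name": name, "start": start, "seq": seq,
            "cigar": cigar or f"{len(seq)}M", "flag": flag}


class TestTagAlignments:
    def test_only_reads_with_calls_gain_tags(self, tmp_path):
        seq = "ACGCATTCGA"
        records = [_aligned_record(f"r{i}", 100, seq) for i in range(5)]
        path = write_sam(tmp_path / "in.sam", records)
        calls = [
            _call(read_id="r0", pos=101, prob=0.9),
            _call(read_id="r1", pos=103, prob=0.8),
            _call(read_id="r2", pos=107, prob=0.2),
        ]
        out = tmp_path / "out.sam"
        report = tag_alignments(path, calls, out)
        assert report.n_tagged == 3 and report.n_passed_through == 2
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            tags = {a.query_name: a.has_tag("MM") for a in af.fetch(until_eof=True)}
        assert tags == {"r0": True, "r1": True, "r2": True, "r3": False, "r4": False}

    def test_calls_in_deletions_are_dropped_not_fatal(self, tmp_path):
        # 5M2D5M over ref 100-111; positions 105/106 are deleted
        rec = _aligned_record("r", 100, "ACGCAACGCA", cigar="5M2D5M")
        path = write_sam(tmp_path / "in.sam", [rec])
        calls = [_call(read_id="r", pos=105), _call(read_id="r", pos=106)]
        out = tmp_path / "out.sam"
        report = tag_alignments(path, calls, out)
        assert report.n_tagged == 0
        assert report.n_calls_dropped_unmapped == 2

    def test_opposite_strand_calls_are_dropped(self, tmp_path):
        rec = _aligned_record("r", 100, "ACGCATTCGA")
        path = write_sam(tmp_path / "in.sam", [rec])
        calls = [_call(read_id="r", pos=102, strand="-")]  # G on forward read
        report = tag_alignments(path, calls, tmp_path / "o.sam")
        assert report.n_tagged == 0 and report.n_calls_dropped_strand == 1

    def test_reverse_strand_read_round_trips(self, tmp_path):
        # reference-forward bases at 100..109; read aligned on '-'
        seq_fwd = "ACGCATTCGA"
        rec = _aligned_record("r", 100, seq_fwd, flag=16)
        path = write_sam(tmp_path / "in.sam", [rec])
        # '-' strand cytosine at ref 102 (forward base G)
        calls = [_call(read_id="r", pos=102, strand="-", prob=0.75)]
        out = tmp_path / "out.sam"
        report = tag_alignments(path, calls, out)
        assert report.n_tagged == 1
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            aln = next(af.fetch(until_eof=True))
        decoded = calls_from_alignment(aln)
        assert [c.ref_pos for c in decoded] == [102]
        assert decoded[0].ref_strand == "-"
        assert abs(decoded[0].prob_meth - 0.75) <= 1 / 256

    def test_retagging_replaces_instead_of_duplicating(self, tmp_path):
        rec = _aligned_record("r", 100, "ACGCATTCGA")
        path = write_sam(tmp_path / "in.sam", [rec])
        calls = [_call(read_id="r", pos=101, prob=0.9)]
        once = tmp_path / "once.sam"
        twice = tmp_path / "twice.sam"
        tag_alignments(path, calls, once)
        tag_alignments(once, calls, twice)
        def read_tags(p):
            with pysam.AlignmentFile(str(p), check_sq=False) as af:
                a = next(af.fetch(until_eof=True))
                return a.get_tag("MM"), list(a.get_tag("ML"))
        assert read_tags(once) == read_tags(twice)

    def test_no_ml_mode_emits_mm_only(self, tmp_path):
        rec = _aligned_record("r", 100, "ACGCATTCGA")
        path = write_sam(tmp_path / "in.sam", [rec])
        calls = [_call(read_id="r", pos=101, prob=0.9)]
        out = tmp_path / "out.sam"
        tag_alignments(path, calls, out, emit_ml=False)
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            a = next(af.fetch(until_eof=True))
        assert a.has_tag("MM") and not a.has_tag("ML")

    def test_every_tagged_position_is_c_in_original_orientation(self, sim_files):
        paths, _ = sim_files
        out = paths["sam"].parent / "tagged.sam"
        report = parse_meth_calls(paths["calls"])
        tag_alignments(paths["sam"], report.calls, out)
        n_checked = 0
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            for aln in af.fetch(until_eof=True):
                if not aln.has_tag("MM"):
                    continue
                seq = aln.query_sequence
                orig = revcomp(seq) if aln.is_reverse else seq
                positions, _ = decode_mm(orig, aln.get_tag("MM"),
                                         list(aln.get_tag("ML")))
                assert all(orig[p] == "C" for p in positions)
                n_checked += 1
        assert n_checked > 10
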