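"""Tiny SAM fixture builder for tests."""

from __future__ import annotations

import pysam


def write_sam(
    path,
    records: list[dict],
    references: dict[str, int] = None,
) -> str:
    """Write alignment records (dicts of AlignedSegment attributes) as SAM.

    Recognised keys: name, ref, start, cigar, seq, flag (default 0),
    mapq (default 60), tags (list of (tag, value, type)).
    """
    references = references or {"chr1": 100_000}
    names = list(references)
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": references[n]} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.flag = rec.get("flag", 0)
            ref = rec.get("ref", names[0])
            if ref is not None:
                a.reference_id = idx[ref]
                a.reference_start = rec["start"]
                a.cigarstring = rec["cigar"]
            a.mapping_quality = rec.get("mapq", 60)
            seq = rec.get("seq")
            if seq is not None:
                a.query_sequence = seq
                a.query_qualities = [20] * len(seq)
            for tag, value, vtype in rec.get("tags", ()):
                a.set_tag(tag, value, value_type=vtype)
            out.write(a)
    return str(path)
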