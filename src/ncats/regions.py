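"""Named reference intervals and the two coordinate dialects.

Internally every interval is 0-based half-open.  Human-facing reports and
CLI arguments use the GenBank-style 1-based inclusive ``ref:start..end``
notation (the notation target-locus tables in enrichment studies are
printed in); BED files are the 0-based half-open alternative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

_REGION_RE = re.compile(
    r"^(?P<ref>[^:]+):(?P<start>[\d,]+)\.\.(?P<end>[\d,]+)$"
)


@dataclass(frozen=True)
class TargetLocus:
    """A named reference interval to be enriched.

    ``start``/``end`` are 0-based half-open.  ``span_1based`` renders the
    GenBank-style representation used in reports.
    """

    name: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"locus {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def span_1based(self) -> str:
        return f"{self.reference_id}:{self.start + 1:,}..{self.end:,}"

    @classmethod
    def from_region_string(cls, text: str, name: str | None = None) -> "TargetLocus":
        """Parse ``ref:start..end`` (1-based inclusive, commas allowed)."""
        m = _REGION_RE.match(text.strip())
        if not m:
            raise ValueError(
                f"cannot parse region {text!r}; expected ref:start..end "
                "(1-based inclusive)"
            )
        start1 = int(m.group("start").replace(",", ""))
        end1 = int(m.group("end").replace(",", ""))
        if start1 < 1 or end1 < start1:
            raise ValueError(f"bad coordinates in region {text!r}")
        return cls(
            name=name or text.strip(),
            reference_id=m.group("ref"),
            start=start1 - 1,
            end=end1,
        )


def read_bed(path: str | Path) -> list[TargetLocus]:
    """Read loci from a 3+-column BED file (0-based half-open)."""
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: BED line has <3 columns")
            ref, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{ref}:{start}-{end}"
            loci.append(TargetLocus(name=name, reference_id=ref, start=start, end=end))
    return loci


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (ref, start, end, name) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for ref, start, end, name in intervals:
            fh.write(f"{ref}\t{start}\t{end}\t{name}\n")


def merge_intervals(
    intervals: Iterable[tuple[int, int]], gap: int = 0
) -> Iterator[tuple[int, int]]:
    """Merge overlapping (or within *gap* of each other) sorted-or-not intervals."""
    ivs = sorted(intervals)
    if not ivs:
        return
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + gap:
            cur_e = max(cur_e, e)
        else:
            yield cur_s, cur_e
            cur_s, cur_e = s, e
    yield cur_s, cur_e
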