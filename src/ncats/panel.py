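"""Cas9 guide-panel geometry.

A guide RNA directs SpCas9 to a 20-nt protospacer that must be followed
by an NGG-like PAM; the enzyme cuts bluntly 3 bp on the 5' side of the
PAM (between protospacer positions 17 and 18).  A panel of guide pairs
excises the fragments that the sequencer preferentially adapts, so the
panel's cut geometry predicts the fragment lengths seen in the reads.

Matching here is exact (no mismatch tolerance): the module verifies a
designed panel against a reference, it does not score candidate guides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping, Sequence

from .sequtil import IUPAC, matches_iupac, revcomp, validate_dna

logger = logging.getLogger(__name__)

SPACER_LENGTH = 20
#: blunt cut this many bases 5' of the PAM (canonical SpCas9 geometry)
CUT_OFFSET_FROM_PAM = 3


@dataclass(frozen=True)
class GuideRNA:
    """A single guide: 20-nt spacer plus its PAM requirement."""

    name: str
    spacer: str
    pam_pattern: str = "NGG"
    intended_orientation: str = "forward"

    def __post_init__(self) -> None:
        spacer = validate_dna(self.spacer, what=f"spacer of {self.name!r}",
                              allow_n=False)
        object.__setattr__(self, "spacer", spacer)
        if len(spacer) != SPACER_LENGTH:
            raise ValueError(
                f"guide {self.name!r}: spacer must be {SPACER_LENGTH} nt, "
                f"got {len(spacer)}"
            )
        pam = self.pam_pattern.upper()
        if not pam:
            raise ValueError(f"guide {self.name!r}: empty PAM pattern")
        for c in pam:
            if c not in IUPAC:
                raise ValueError(
                    f"guide {self.name!r}: invalid IUPAC code {c!r} in PAM"
                )
        object.__setattr__(self, "pam_pattern", pam)
        if self.intended_orientation not in ("forward", "reverse"):
            raise ValueError("intended_orientation must be 'forward' or 'reverse'")


@dataclass(frozen=True)
class CutSite:
    """A predicted blunt double-strand break.

    ``position`` is the 0-based offset of the cut: the break falls between
    reference positions ``position - 1`` and ``position``.
    """

    reference_id: str
    position: int
    strand: str
    guide_name: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position < 0:
            raise ValueError("cut position must be >= 0")


@dataclass(frozen=True)
class TargetFragment:
    """The excised interval between an upstream and a downstream cut."""

    reference_id: str
    start: int
    end: int
    guide_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"fragment needs start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class _SiteMatch:
    """Internal: one protospacer+PAM occurrence with its footprint."""

    strand: str
    footprint_start: int  # leftmost base of spacer+PAM in forward coords
    footprint_end: int    # past-the-end
    cut_position: int


def _scan_sites(reference: str, guide: GuideRNA) -> Iterator[_SiteMatch]:
    """Yield every exact protospacer+PAM occurrence on either strand."""
    spacer = guide.spacer
    pam = guide.pam_pattern
    k, p = len(spacer), len(pam)

    # forward strand: spacer then PAM; cut 3 bp 5' of the PAM
    start = reference.find(spacer)
    while start != -1:
        pam_seq = reference[start + k: start + k + p]
        if len(pam_seq) == p and matches_iupac(pam_seq, pam):
            yield _SiteMatch(
                strand="+",
                footprint_start=start,
                footprint_end=start + k + p,
                cut_position=start + k - CUT_OFFSET_FROM_PAM,
            )
        start = reference.find(spacer, start + 1)

    # reverse strand: forward sequence holds revcomp(PAM) then revcomp(spacer);
    # the cut lies 3 bp into the spacer from its PAM-proximal end, i.e. at
    # PAM end + 3 in forward coordinates.
    rc_spacer = revcomp(spacer)
    rc_pam = revcomp(pam)
    start = reference.find(rc_spacer)
    while start != -1:
        pam_seq = reference[start - p: start]
        if start - p >= 0 and matches_iupac(pam_seq, rc_pam):
            yield _SiteMatch(
                strand="-",
                footprint_start=start - p,
                footprint_end=start + k,
                cut_position=start + CUT_OFFSET_FROM_PAM,
            )
        start = reference.find(rc_spacer, start + 1)


def find_protospacers(
    reference: str, guide: GuideRNA, reference_id: str = "ref"
) -> list[CutSite]:
    """Locate every exact protospacer+PAM site of *guide* on both strands.

    Returns one :class:`CutSite` per occurrence, sorted by position; an
    empty list when the guide does not match.  Non-DNA characters in the
    reference are rejected.
    """
    if not reference:
        raise ValueError("reference sequence is empty")
    reference = validate_dna(reference, what="reference")
    sites = [
        CutSite(
            reference_id=reference_id,
            position=m.cut_position,
            strand=m.strand,
            guide_name=guide.name,
        )
        for m in _scan_sites(reference, guide)
    ]
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def predict_fragments(
    cut_sites: Sequence[CutSite],
    pairing: Sequence[tuple[str, str]],
) -> list[TargetFragment]:
    """Predict excised fragments for explicit (upstream, downstream) guide pairs.

    For each pair, every combination of an upstream-guide cut and a
    downstream-guide cut with upstream < downstream yields one fragment.
    Cuts of a pair on different references are an error; if no combination
    is ordered, the pair contributes nothing (with a warning).
    """
    by_guide: dict[str, list[CutSite]] = {}
    for site in cut_sites:
        by_guide.setdefault(site.guide_name, []).append(site)

    fragments: list[TargetFragment] = []
    for up_name, down_name in pairing:
        ups = by_guide.get(up_name, [])
        downs = by_guide.get(down_name, [])
        if not ups or not downs:
            raise ValueError(
                f"pair ({up_name!r}, {down_name!r}): both guides need "
                "at least one cut site"
            )
        refs = {s.reference_id for s in ups} | {s.reference_id for s in downs}
        if len(refs) > 1:
            raise ValueError(
                f"pair ({up_name!r}, {down_name!r}) has cuts on multiple "
                f"references: {sorted(refs)}"
            )
        pair_frags = [
            TargetFragment(
                reference_id=u.reference_id,
                start=u.position,
                end=d.position,
                guide_pair=(up_name, down_name),
            )
            for u, d in product(ups, downs)
            if u.position < d.position
        ]
        if not pair_frags:
            warnings.warn(
                f"pair ({up_name!r}, {down_name!r}): no upstream cut lies "
                "before a downstream cut; pair skipped",
                stacklevel=2,
            )
        fragments.extend(pair_frags)
    fragments.sort(key=lambda f: (f.reference_id, f.start, f.end))
    return fragments


def offtarget_exact_count(
    references: Mapping[str, str],
    guide: GuideRNA,
    targets: Iterable[tuple[str, int, int]] = (),
) -> int:
    """Count exact protospacer+PAM occurrences outside the declared targets.

    *targets* are (reference_id, start, end) 0-based half-open intervals; an
    occurrence is on-target when its spacer+PAM footprint overlaps one of
    them.  Both strands are scanned.  This is a panel sanity check, not a
    scored off-target prediction.
    """
    target_list = list(targets)
    count = 0
    for ref_id, seq in references.items():
        seq = validate_dna(seq, what=f"reference {ref_id!r}")
        for m in _scan_sites(seq, guide):
            on_target = any(
                ref_id == t_ref and m.footprint_start < t_end and t_start < m.footprint_end
                for t_ref, t_start, t_end in target_list
            )
            if not on_target:
                count += 1
    return count


def read_guide_table(path) -> list[GuideRNA]:
    """Read guides from a TSV with columns name, spacer[, orientation[, pam]]."""
    guides = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{i}: need at least name and spacer")
            name, spacer = fields[0], fields[1]
            orientation = fields[2] if len(fields) > 2 and fields[2] else "forward"
            pam = fields[3] if len(fields) > 3 and fields[3] else "NGG"
            guides.append(
                GuideRNA(name=name, spacer=spacer, pam_pattern=pam,
                         intended_orientation=orientation)
            )
    return guides
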