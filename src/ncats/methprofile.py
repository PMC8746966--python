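"""Per-read and per-site methylation summaries over a target region.

The central object is a reads x sites matrix of binarised methylation
states (the tabular form of a per-read browser display).  From it come
per-site frequencies, the promoter-versus-gene-body contrast that
characterises gene-body methylation (gbM), and per-haplotype profiles
when reads carry phase labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .methtag import PerReadMethCall
from .regions import TargetLocus

logger = logging.getLogger(__name__)

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1

#: plant cytosine contexts; H is A, C or T
CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class MethylationMatrix:
    """Binarised reads x sites methylation states for one region.

    ``states`` holds 1 (methylated), 0 (unmethylated) or -1 (missing);
    ``probs`` holds the raw caller probability where a state is present,
    NaN otherwise.  ``site_positions`` are sorted 0-based reference
    coordinates; a CpG contributes two sites, one per strand.
    """

    region: TargetLocus
    site_positions: np.ndarray
    read_ids: list[str]
    states: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        n_reads, n_sites = len(self.read_ids), len(self.site_positions)
        if self.states.shape != (n_reads, n_sites):
            raise ValueError(
                f"states shape {self.states.shape} != ({n_reads}, {n_sites})"
            )
        if self.probs.shape != self.states.shape:
            raise ValueError("probs shape differs from states shape")
        present = self.states != MISSING
        if np.isnan(self.probs[present]).any():
            raise ValueError("every non-missing state needs a probability")

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def subset_reads(self, read_ids: Sequence[str]) -> "MethylationMatrix":
        """Row subset preserving site axis (sites may become all-missing)."""
        idx = [i for i, r in enumerate(self.read_ids) if r in set(read_ids)]
        return MethylationMatrix(
            region=self.region,
            site_positions=self.site_positions,
            read_ids=[self.read_ids[i] for i in idx],
            states=self.states[idx],
            probs=self.probs[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """States as a DataFrame (reads x site positions), NaN for missing."""
        df = pd.DataFrame(
            np.where(self.states == MISSING, np.nan, self.states),
            index=self.read_ids,
            columns=self.site_positions,
        )
        return df


@dataclass
class RegionProfile:
    """Per-site methylation frequency and coverage for one region."""

    region: TargetLocus
    site_positions: np.ndarray
    frequency: np.ndarray  # NaN where no read covers the site
    coverage: np.ndarray
    n_reads: int


@dataclass
class GbmContrast:
    """Promoter-vs-body methylation contrast (gene-body methylation test)."""

    promoter_mean: float
    body_mean: float
    difference: float
    n_promoter_sites: int
    n_body_sites: int
    p_value: float | None = None
    n_permutations: int = 0


def build_matrix(
    calls: Iterable[PerReadMethCall],
    region: TargetLocus,
    binarize_threshold: float = 0.5,
) -> MethylationMatrix:
    """Binarise region calls into a reads x sites matrix.

    An entry is methylated iff ``prob >= binarize_threshold`` (single cut,
    ties methylated — the caller's argmax label at the default 0.5).
    Sites with zero coverage are excluded; an empty region overlap yields
    an empty matrix, not an error.  Duplicate calls for the same read and
    site keep the last occurrence.
    """
    in_region = [
        c for c in calls
        if c.reference_id == region.reference_id
        and region.start <= c.ref_pos < region.end
    ]
    sites = np.array(sorted({c.ref_pos for c in in_region}), dtype=int)
    read_ids = sorted({c.read_id for c in in_region})
    site_idx = {p: j for j, p in enumerate(sites)}
    read_idx = {r: i for i, r in enumerate(read_ids)}

    states = np.full((len(read_ids), len(sites)), MISSING, dtype=np.int8)
    probs = np.full_like(states, np.nan, dtype=float)
    for c in in_region:
        i, j = read_idx[c.read_id], site_idx[c.ref_pos]
        states[i, j] = METHYLATED if c.prob_meth >= binarize_threshold else UNMETHYLATED
        probs[i, j] = c.prob_meth
    return MethylationMatrix(
        region=region, site_positions=sites, read_ids=read_ids,
        states=states, probs=probs,
    )


def site_frequency(matrix: MethylationMatrix) -> RegionProfile:
    """Per-site methylation frequency: methylated / covered, missing excluded.

    A site covered by no read in the matrix (possible after a haplotype
    subset) gets frequency NaN and coverage 0.
    """
    meth = (matrix.states == METHYLATED).sum(axis=0)
    covered = (matrix.states != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(covered > 0, meth / np.maximum(covered, 1), np.nan)
    return RegionProfile(
        region=matrix.region,
        site_positions=matrix.site_positions,
        frequency=freq,
        coverage=covered,
        n_reads=matrix.n_reads,
    )


def context_classify(reference_seq: str, pos: int, strand: str) -> str:
    """Classify a cytosine into the plant CpG / CHG / CHH trinucleotide context.

    *pos* must hold a cytosine on the given strand of *reference_seq*
    (i.e. a C on '+', a G on '+' for strand '-').  Bases running off the
    sequence end count as H.
    """
    seq = reference_seq.upper()
    if strand == "+":
        if pos >= len(seq) or seq[pos] != "C":
            raise ValueError(f"position {pos} (+) is not a cytosine")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else ""
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else ""
    elif strand == "-":
        if pos >= len(seq) or seq[pos] != "G":
            raise ValueError(f"position {pos} (-) is not a cytosine")
        # minus strand reads right-to-left; complement the bases to the left
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        nxt = comp.get(seq[pos - 1], "") if pos - 1 >= 0 else ""
        nxt2 = comp.get(seq[pos - 2], "") if pos - 2 >= 0 else ""
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def gbm_contrast(
    profile: RegionProfile,
    promoter_interval: tuple[int, int],
    body_interval: tuple[int, int],
    n_permutations: int = 0,
    seed: int | None = None,
) -> GbmContrast:
    """Contrast mean per-site methylation between promoter and gene body.

    Intervals are 0-based half-open reference coordinates and must be
    disjoint, each containing at least one covered site.  With
    ``n_permutations > 0`` a two-sided permutation p-value on the absolute
    difference is computed by reshuffling site-to-interval labels; this is
    a quantitative extension of what per-read displays show visually.
    """
    (p_start, p_end), (b_start, b_end) = promoter_interval, body_interval
    if p_start < b_end and b_start < p_end:
        raise ValueError("promoter and body intervals must be disjoint")

    pos = profile.site_positions
    ok = ~np.isnan(profile.frequency)
    in_prom = (pos >= p_start) & (pos < p_end) & ok
    in_body = (pos >= b_start) & (pos < b_end) & ok
    if not in_prom.any():
        raise ValueError("promoter interval contains no covered sites")
    if not in_body.any():
        raise ValueError("body interval contains no covered sites")

    prom = profile.frequency[in_prom]
    body = profile.frequency[in_body]
    diff = float(body.mean() - prom.mean())

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([prom, body])
        n_p = prom.size
        n_extreme = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            d = perm[n_p:].mean() - perm[:n_p].mean()
            if abs(d) >= abs(diff) - 1e-12:
                n_extreme += 1
        p_value = (1 + n_extreme) / (n_permutations + 1)

    return GbmContrast(
        promoter_mean=float(prom.mean()),
        body_mean=float(body.mean()),
        difference=diff,
        n_promoter_sites=int(in_prom.sum()),
        n_body_sites=int(in_body.sum()),
        p_value=p_value,
        n_permutations=n_permutations,
    )


def split_by_haplotype(
    matrix: MethylationMatrix,
    read_to_haplotype: Mapping[str, int | None],
) -> dict[str, RegionProfile]:
    """Per-haplotype site frequencies from a read -> haplotype mapping.

    Keys of the result are ``"HP1"``, ``"HP2"`` and ``"unassigned"``
    (reads mapped to None, or absent from the mapping).  Read ids in the
    mapping that are not in the matrix are ignored with a warning.
    """
    known = set(matrix.read_ids)
    unknown = set(read_to_haplotype) - known
    if unknown:
        logger.warning(
            "%d read ids in the haplotype mapping are not in the matrix "
            "(e.g. %s)", len(unknown), sorted(unknown)[:3],
        )
    groups: dict[str, list[str]] = {"HP1": [], "HP2": [], "unassigned": []}
    for read_id in matrix.read_ids:
        hp = read_to_haplotype.get(read_id)
        if hp == 1:
            groups["HP1"].append(read_id)
        elif hp == 2:
            groups["HP2"].append(read_id)
        else:
            groups["unassigned"].append(read_id)
    return {
        name: site_frequency(matrix.subset_reads(reads))
        for name, reads in groups.items()
    }


def filter_sites_by_context(
    matrix: MethylationMatrix, reference_seq: str, context: str
) -> MethylationMatrix:
    """Keep only sites of one trinucleotide context (CpG, CHG or CHH).

    A site's strand follows its forward-reference base: C means the plus
    strand, G the minus strand (after :func:`destrand_cpg`, merged CpG
    sites sit on the C and classify as CpG).
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    seq = reference_seq.upper()
    keep = []
    for j, p in enumerate(matrix.site_positions):
        strand = "+" if seq[p] == "C" else "-"
        try:
            if context_classify(seq, int(p), strand) == context:
                keep.append(j)
        except ValueError:
            continue  # site no longer a cytosine on this reference
    return MethylationMatrix(
        region=matrix.region,
        site_positions=matrix.site_positions[keep],
        read_ids=matrix.read_ids,
        states=matrix.states[:, keep],
        probs=matrix.probs[:, keep],
    )


def destrand_cpg(matrix: MethylationMatrix, reference_seq: str) -> MethylationMatrix:
    """Merge the two strands of each symmetric CpG onto the C position.

    CpG methylation is strand-symmetric, and a nanopore read reports only
    the strand it was sequenced from, so per-site coverage roughly doubles
    after destranding.  A site at position ``p`` whose forward base is the
    G of a CpG (``reference_seq[p-1:p+1] == "CG"``) is remapped to
    ``p - 1``; all other sites keep their position.  Within one merged
    site each read contributes at most one state (it covers one strand);
    should duplicates occur, the higher-probability call wins.
    """
    seq = reference_seq.upper()
    new_pos = []
    for p in matrix.site_positions:
        if 1 <= p < len(seq) and seq[p] == "G" and seq[p - 1] == "C":
            new_pos.append(p - 1)
        else:
            new_pos.append(int(p))
    merged_sites = np.array(sorted(set(new_pos)), dtype=int)
    col_of = {p: j for j, p in enumerate(merged_sites)}

    states = np.full((matrix.n_reads, merged_sites.size), MISSING, dtype=np.int8)
    probs = np.full_like(states, np.nan, dtype=float)
    for old_j, p in enumerate(new_pos):
        j = col_of[p]
        col_states = matrix.states[:, old_j]
        col_probs = matrix.probs[:, old_j]
        take = (col_states != MISSING) & (
            (states[:, j] == MISSING) | (col_probs > probs[:, j])
        )
        states[take, j] = col_states[take]
        probs[take, j] = col_probs[take]
    return MethylationMatrix(
        region=matrix.region,
        site_positions=merged_sites,
        read_ids=matrix.read_ids,
        states=states,
        probs=probs,
    )


def read_haplotype_table(path) -> dict[str, int | None]:
    """Read a read-id <TAB> haplotype table (1, 2, or anything else = unassigned)."""
    mapping: dict[str, int | None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                hp: int | None = int(fields[1])
                if hp not in (1, 2):
                    hp = None
            except (IndexError, ValueError):
                hp = None
            mapping[fields[0]] = hp
    return mapping


def haplotypes_from_bam(alignments) -> dict[str, int | None]:
    """Extract HP tags (as set by phasing tools) from primary alignments."""
    import pysam
    from pathlib import Path

    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    else:
        af, close = alignments, False
    mapping: dict[str, int | None] = {}
    try:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mapping[aln.query_name] = (
                int(aln.get_tag("HP")) if aln.has_tag("HP") else None
            )
    finally:
        if close:
            af.close()
    return mapping
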