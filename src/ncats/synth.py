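"""Synthetic nCATS-like data with machine-readable ground truth.

The generator emulates the observed regime of a Cas9-targeted nanopore
run on a large plant genome, scaled down so the whole pipeline runs in
seconds: a background genome with a few designed target loci (promoter,
gene body, CpG island, tandem-repeat tract, flanking guide sites), reads
that span the excised cut-to-cut fragments at 5-17x target depth over a
diffuse low-coverage background, per-read methylation calls with
gene-body-methylation truth (hypomethylated promoter, hypermethylated
CpG sites in the body, near-zero CHG/CHH), and an optional two-haplotype
mode with read labels.

All randomness flows from one integer seed through per-stage
``numpy.random.default_rng([seed, stage])`` streams, in the order
reference (0), reads (1), calls (2), so each stage is reproducible
independently of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .methtag import PerReadMethCall
from .panel import GuideRNA, find_protospacers
from .regions import TargetLocus
from .seqcomp import dotplot_matches, find_cpg_islands
from .sequtil import revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class LocusSpec:
    """Architecture of one designed target locus (intervals locus-relative)."""

    name: str
    start: int
    length: int
    promoter: tuple[int, int] = (0, 1000)
    body: tuple[int, int] | None = None  # default: promoter end .. length
    island: tuple[int, int] = (1500, 1800)
    repeat: tuple[int, int] = (2500, 3100)
    target_depth: float = 15.0

    def __post_init__(self) -> None:
        if self.body is None:
            self.body = (self.promoter[1], self.length)
        if self.target_depth <= 0:
            raise ValueError(f"locus {self.name!r}: target_depth must be > 0")
        for label, (a, b) in (
            ("promoter", self.promoter), ("body", self.body),
            ("island", self.island), ("repeat", self.repeat),
        ):
            if not (0 <= a < b <= self.length):
                raise ValueError(
                    f"locus {self.name!r}: {label} interval ({a}, {b}) "
                    f"exceeds locus length {self.length}"
                )

    @property
    def end(self) -> int:
        return self.start + self.length

    def as_target_locus(self, chrom: str) -> TargetLocus:
        return TargetLocus(
            name=self.name, reference_id=chrom, start=self.start, end=self.end
        )


def _default_loci() -> list[LocusSpec]:
    # three loci mirroring the 3.4 / 5.1 / 3.6 kb target fragments at
    # depths spanning the observed 5-17x range
    return [
        LocusSpec(name="gene1", start=2_000_000, length=3_400, target_depth=5.0),
        LocusSpec(name="gene2", start=5_000_000, length=5_100, target_depth=8.0),
        LocusSpec(name="gene3", start=8_000_000, length=3_600, target_depth=15.0),
    ]


def _default_meth_probs() -> dict[str, dict[str, float]]:
    # gene-body methylation truth: CpG-only methylation in the body,
    # hypomethylated promoter, near-zero non-CpG everywhere in the locus
    return {
        "promoter": {"CpG": 0.05, "CHG": 0.01, "CHH": 0.01},
        "body": {"CpG": 0.95, "CHG": 0.01, "CHH": 0.01},
        "background": {"CpG": 0.60, "CHG": 0.30, "CHH": 0.08},
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; the defaults are the study conditions."""

    seed: int
    genome_size: int = 10_000_000
    chrom_name: str = "synth1"
    loci: list[LocusSpec] = field(default_factory=_default_loci)
    background_gc: float = 0.42
    meth_probs: dict[str, dict[str, float]] = field(default_factory=_default_meth_probs)
    hp2_meth_probs: dict[str, dict[str, float]] | None = None
    background_yield: int = 150_000
    read_length_mean: float = 3_100.0
    read_length_sd: float = 2_500.0
    end_jitter_sd: float = 30.0
    substitution_rate: float = 0.05
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    two_haplotypes: bool = False
    n_snps: int = 30
    meth_call_high: float = 0.90
    meth_call_low: float = 0.10
    meth_call_sd: float = 0.05
    mean_qscore: float = 13.0
    qscore_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for group in [self.meth_probs] + (
            [self.hp2_meth_probs] if self.hp2_meth_probs else []
        ):
            for region, by_ctx in group.items():
                for ctx, p in by_ctx.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"meth prob {region}/{ctx} = {p} outside [0,1]"
                        )
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must be in [0, 1)")
        for locus in self.loci:
            if locus.start < 100 or locus.end > self.genome_size - 100:
                raise ValueError(
                    f"locus {locus.name!r} too close to the genome edge"
                )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SimRead:
    """One simulated read, in aligned (forward-reference) orientation."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str
    seq_aligned: str
    qualities: list[int]
    locus: str | None = None
    haplotype: int | None = None

    @property
    def is_on_target(self) -> bool:
        return self.locus is not None

    @property
    def seq_original(self) -> str:
        return revcomp(self.seq_aligned) if self.strand == "-" else self.seq_aligned

    @property
    def qualities_original(self) -> list[int]:
        return self.qualities[::-1] if self.strand == "-" else self.qualities


@dataclass
class GroundTruth:
    """Machine-readable truth emitted alongside the synthetic files."""

    config_seed: int
    chrom: str
    genome_size: int
    fragments: dict[str, tuple[int, int]] = field(default_factory=dict)
    guides: dict[str, dict] = field(default_factory=dict)
    island_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    repeat_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    promoter_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    body_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    snp_positions: dict[str, list[int]] = field(default_factory=dict)
    meth_probs: dict = field(default_factory=dict)
    hp2_meth_probs: dict | None = None
    read_origin: dict[str, dict] = field(default_factory=dict)
    n_on_target: dict[str, int] = field(default_factory=dict)
    realized_depth: dict[str, float] = field(default_factory=dict)
    total_bases: int = 0
    genome_coverage: float = 0.0
    true_enrichment: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _island_tract(rng: np.random.Generator, n: int) -> np.ndarray:
    """CpG-rich, GC-rich tract: 40% designed CG dinucleotides."""
    out: list[str] = []
    while len(out) < n:
        if rng.random() < 0.4:
            out.extend("CG")
        else:
            out.extend(_random_dna(rng, 2, gc=0.55))
    return np.array(out[:n])


def make_reference(
    config: SimulationConfig, audit: bool = True
) -> tuple[dict[str, str], GroundTruth]:
    """Build the designed reference and its ground truth.

    Deterministic under the config seed.  With *audit* (default) the
    designed CpG island, repeat tract and guide sites are re-detected by
    the package's own detectors and any failure raises.
    """
    rng = config.rng(0)
    genome = _random_dna(rng, config.genome_size, config.background_gc)
    # plant genomes are CpG-depleted (methylation-driven deamination of
    # 5mC); suppress most background CpG dinucleotides so observed/expected
    # CpG sits near the ~0.3 typical of bulk genomic DNA
    cg = np.flatnonzero((genome[:-1] == "C") & (genome[1:] == "G"))
    hit = cg[rng.random(cg.size) < 0.7]
    genome[hit + 1] = np.where(rng.random(hit.size) < 0.5, "A", "T")

    truth = GroundTruth(
        config_seed=config.seed,
        chrom=config.chrom_name,
        genome_size=config.genome_size,
        meth_probs=config.meth_probs,
        hp2_meth_probs=config.hp2_meth_probs,
    )

    for locus in config.loci:
        s = locus.start
        # CpG island and tandem repeat inside the gene body
        isl_a, isl_b = locus.island
        genome[s + isl_a: s + isl_b] = _island_tract(rng, isl_b - isl_a)
        rep_a, rep_b = locus.repeat
        unit = _random_dna(rng, 60, config.background_gc)
        tiles = np.tile(unit, math.ceil((rep_b - rep_a) / 60))[: rep_b - rep_a]
        genome[s + rep_a: s + rep_b] = tiles

        # guide sites cutting exactly at the locus boundaries:
        # forward guide cuts at locus start, reverse guide at locus end
        f_spacer = "".join(rng.choice(_BASES, size=20))
        genome[s - 17: s + 3] = np.array(list(f_spacer))
        genome[s + 3: s + 6] = np.array(list("AGG"))
        e = locus.end
        r_spacer = "".join(rng.choice(_BASES, size=20))
        genome[e - 6: e - 3] = np.array(list(revcomp("TGG")))
        genome[e - 3: e + 17] = np.array(list(revcomp(r_spacer)))

        truth.fragments[locus.name] = (s, e)
        truth.guides[f"{locus.name}_F"] = {
            "spacer": f_spacer, "strand": "+", "cut": s, "locus": locus.name,
        }
        truth.guides[f"{locus.name}_R"] = {
            "spacer": r_spacer, "strand": "-", "cut": e, "locus": locus.name,
        }
        truth.island_intervals[locus.name] = (s + isl_a, s + isl_b)
        truth.repeat_intervals[locus.name] = (s + rep_a, s + rep_b)
        truth.promoter_intervals[locus.name] = (
            s + locus.promoter[0], s + locus.promoter[1]
        )
        truth.body_intervals[locus.name] = (s + locus.body[0], s + locus.body[1])

        if config.two_haplotypes:
            # SNPs only at A/T positions (A<->T substitution), so both
            # haplotypes share an identical cytosine landscape
            lo = s + locus.promoter[0]
            hi = s + locus.body[1]
            at = np.flatnonzero(
                (genome[lo:hi] == "A") | (genome[lo:hi] == "T")
            ) + lo
            # keep SNPs clear of the guide footprints at the boundaries
            at = at[(at >= s + 20) & (at < e - 20)]
            n = min(config.n_snps, at.size)
            truth.snp_positions[locus.name] = sorted(
                int(x) for x in rng.choice(at, size=n, replace=False)
            )

    reference = {config.chrom_name: genome.astype("S1").tobytes().decode()}
    if audit:
        _audit_reference(config, reference, truth)
    return reference, truth


def _audit_reference(
    config: SimulationConfig, reference: dict[str, str], truth: GroundTruth
) -> None:
    seq = reference[config.chrom_name]
    for locus in config.loci:
        sub = seq[locus.start: locus.end]
        isl_a, isl_b = locus.island
        islands = find_cpg_islands(sub)
        if not any(i.start < isl_b and isl_a < i.end for i in islands):
            raise RuntimeError(
                f"self-audit: designed island of {locus.name!r} not detected"
            )
        segments, _ = dotplot_matches(sub, k=15)
        rep_a, rep_b = locus.repeat
        if not any(g.start < rep_b and rep_a < g.end for g in segments):
            raise RuntimeError(
                f"self-audit: designed repeat of {locus.name!r} not detected"
            )
    for name, info in truth.guides.items():
        guide = GuideRNA(name=name, spacer=info["spacer"])
        sites = find_protospacers(seq, guide, reference_id=config.chrom_name)
        hits = [s for s in sites if s.position == info["cut"] and s.strand == info["strand"]]
        if len(hits) != 1 or len(sites) != 1:
            raise RuntimeError(
                f"self-audit: guide {name!r} matched {len(sites)} sites "
                f"(expected exactly one at {info['cut']})"
            )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _apply_errors(
    rng: np.random.Generator, seq: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, str]:
    """Substitutions (vectorised) and optional indels; returns (seq, CIGAR)."""
    n = len(seq)
    sub_mask = rng.random(n) < config.substitution_rate
    if sub_mask.any():
        seq = seq.copy()
        # shift each hit base by 1-3 in alphabet order: always a different base
        idx = np.flatnonzero(sub_mask)
        base_idx = np.searchsorted(_BASES, seq[idx])
        seq[idx] = _BASES[(base_idx + rng.integers(1, 4, size=idx.size)) % 4]
    if config.insertion_rate == 0.0 and config.deletion_rate == 0.0:
        return seq, f"{n}M"

    out: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, ln: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    for base in seq:
        r = rng.random()
        if r < config.deletion_rate:
            push("D")
            continue
        if r < config.deletion_rate + config.insertion_rate:
            out.append(str(rng.choice(_BASES)))
            push("I")
        out.append(str(base))
        push("M")
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    return np.array(out), cigar


def simulate_reads(
    config: SimulationConfig,
    reference: Mapping[str, str],
    truth: GroundTruth,
) -> list[SimRead]:
    """Simulate on-target (cut-to-cut) and uniform background reads.

    On-target reads start and end near the predicted cut sites (Gaussian
    jitter); background reads have lognormal lengths and uniform positions
    re-drawn if they touch a target fragment, so the per-read origin truth
    stays unambiguous.  Updates the pileup/coverage fields of *truth*.
    """
    rng = config.rng(1)
    chrom = config.chrom_name
    genome = np.frombuffer(reference[chrom].encode(), dtype="S1").astype("U1")
    reads: list[SimRead] = []

    snps_by_locus = {
        name: np.array(pos, dtype=int)
        for name, pos in truth.snp_positions.items()
    }

    def build_read(
        read_id: str, start: int, end: int, locus: str | None, hp: int | None
    ) -> SimRead:
        seq = genome[start:end]
        if hp == 2 and locus in snps_by_locus:
            snps = snps_by_locus[locus]
            hits = snps[(snps >= start) & (snps < end)] - start
            if hits.size:
                seq = seq.copy()
                # haplotype-2 allele: A <-> T swap at each SNP position
                seq[hits] = np.where(seq[hits] == "A", "T", "A")
        seq, cigar = _apply_errors(rng, seq, config)
        strand = "+" if rng.random() < 0.5 else "-"
        quals = np.clip(
            rng.normal(config.mean_qscore, config.qscore_sd, size=len(seq)),
            2, 40,
        ).astype(int)
        return SimRead(
            read_id=read_id,
            chrom=chrom,
            ref_start=start,
            ref_end=start + sum(
                int(ln) for ln, op in _iter_cigar(cigar) if op in "MD"
            ),
            strand=strand,
            cigar=cigar,
            seq_aligned="".join(seq),
            qualities=[int(q) for q in quals],
            locus=locus,
            haplotype=hp,
        )

    for locus in config.loci:
        frag_start, frag_end = truth.fragments[locus.name]
        n_reads = int(round(locus.target_depth))
        for i in range(n_reads):
            start = int(frag_start + rng.normal(0, config.end_jitter_sd))
            end = int(frag_end + rng.normal(0, config.end_jitter_sd))
            start = max(0, min(start, frag_end - 100))
            end = min(config.genome_size, max(end, start + 100))
            hp = int(rng.integers(1, 3)) if config.two_haplotypes else None
            reads.append(
                build_read(f"{locus.name}_read{i:04d}", start, end, locus.name, hp)
            )

    mu, sigma = _lognormal_params(config.read_length_mean, config.read_length_sd)
    total_bg = 0
    i = 0
    fragments = list(truth.fragments.values())
    while total_bg < config.background_yield:
        length = max(200, int(rng.lognormal(mu, sigma)))
        length = min(length, config.genome_size // 2)
        for _ in range(100):
            start = int(rng.integers(0, config.genome_size - length))
            end = start + length
            if not any(start < fe and fs < end for fs, fe in fragments):
                break
        else:
            raise RuntimeError("could not place a background read off-target")
        reads.append(build_read(f"bg_read{i:05d}", start, end, None, None))
        total_bg += length
        i += 1

    # ---- pileup / coverage audit -> truth
    for r in reads:
        truth.read_origin[r.read_id] = {
            "locus": r.locus, "haplotype": r.haplotype, "strand": r.strand,
        }
    truth.total_bases = sum(len(r.seq_aligned) for r in reads)
    truth.genome_coverage = truth.total_bases / config.genome_size
    for locus in config.loci:
        frag_start, frag_end = truth.fragments[locus.name]
        frag_len = frag_end - frag_start
        covered = sum(
            max(0, min(r.ref_end, frag_end) - max(r.ref_start, frag_start))
            for r in reads
        )
        truth.n_on_target[locus.name] = sum(
            1 for r in reads if r.locus == locus.name
        )
        truth.realized_depth[locus.name] = covered / frag_len
        truth.true_enrichment[locus.name] = (
            truth.realized_depth[locus.name] / truth.genome_coverage
        )
    return reads


def _iter_cigar(cigar: str):
    import re

    for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar):
        yield int(m.group(1)), m.group(2)


class _MethTruthIndex:
    """Per-strand cytosine positions, contexts and truth probabilities."""

    def __init__(self, config: SimulationConfig, seq: str, truth: GroundTruth):
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n = len(seq)
        is_c, is_g = arr == b"C", arr == b"G"

        self.plus_pos = np.flatnonzero(is_c)
        nxt_g = np.zeros(n, bool); nxt_g[:-1] = is_g[1:]
        nxt2_g = np.zeros(n, bool); nxt2_g[:-2] = is_g[2:]
        self.plus_ctx = np.where(
            nxt_g[self.plus_pos], 0, np.where(nxt2_g[self.plus_pos], 1, 2)
        )

        self.minus_pos = np.flatnonzero(is_g)
        prv_c = np.zeros(n, bool); prv_c[1:] = is_c[:-1]
        prv2_c = np.zeros(n, bool); prv2_c[2:] = is_c[:-2]
        self.minus_ctx = np.where(
            prv_c[self.minus_pos], 0, np.where(prv2_c[self.minus_pos], 1, 2)
        )

        ctx_names = ("CpG", "CHG", "CHH")
        region_names = ("background", "promoter", "body")

        def prob_array(pos, ctx, probs) -> np.ndarray:
            region = np.zeros(pos.size, dtype=np.int8)
            for a, b in truth.promoter_intervals.values():
                region[(pos >= a) & (pos < b)] = 1
            for a, b in truth.body_intervals.values():
                region[(pos >= a) & (pos < b)] = 2
            lut = np.array(
                [[probs[r][c] for c in ctx_names] for r in region_names]
            )
            return lut[region, ctx]

        self.plus_prob = {1: prob_array(self.plus_pos, self.plus_ctx, config.meth_probs)}
        self.minus_prob = {1: prob_array(self.minus_pos, self.minus_ctx, config.meth_probs)}
        hp2 = config.hp2_meth_probs or config.meth_probs
        if config.two_haplotypes and config.hp2_meth_probs:
            self.plus_prob[2] = prob_array(self.plus_pos, self.plus_ctx, hp2)
            self.minus_prob[2] = prob_array(self.minus_pos, self.minus_ctx, hp2)
        else:
            self.plus_prob[2] = self.plus_prob[1]
            self.minus_prob[2] = self.minus_prob[1]


def simulate_meth_calls(
    config: SimulationConfig,
    reference: Mapping[str, str],
    reads: Sequence[SimRead],
    truth: GroundTruth,
) -> list[PerReadMethCall]:
    """Emit caller-style per-read calls for every covered cytosine.

    Calls are reference-anchored on the strand the read was sequenced
    from.  Per (read, site) the molecule's true state is Bernoulli with
    the region/context truth probability; the emitted probability is a
    clipped Gaussian around 0.9 (methylated) or 0.1 (unmethylated).
    """
    rng = config.rng(2)
    seq = reference[config.chrom_name]
    index = _MethTruthIndex(config, seq, truth)

    calls: list[PerReadMethCall] = []
    for read in reads:
        if read.strand == "+":
            pos_all, prob_all = index.plus_pos, index.plus_prob
        else:
            pos_all, prob_all = index.minus_pos, index.minus_prob
        lo = np.searchsorted(pos_all, read.ref_start)
        hi = np.searchsorted(pos_all, read.ref_end)
        if hi <= lo:
            continue
        pos = pos_all[lo:hi]
        p_true = prob_all[read.haplotype or 1][lo:hi]
        meth = rng.random(pos.size) < p_true
        emitted = np.where(
            meth,
            rng.normal(config.meth_call_high, config.meth_call_sd, pos.size),
            rng.normal(config.meth_call_low, config.meth_call_sd, pos.size),
        )
        emitted = np.clip(emitted, 0.0, 1.0)
        for p, pr in zip(pos, emitted):
            calls.append(
                PerReadMethCall(
                    read_id=read.read_id,
                    reference_id=read.chrom,
                    ref_pos=int(p),
                    ref_strand=read.strand,
                    prob_meth=float(pr),
                    called_label=int(pr >= 0.5),
                )
            )
    return calls


# ---------------------------------------------------------------- writers

def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities_original)
            fh.write(f"@{r.read_id}\n{r.seq_original}\n+\n{qual}\n")


def write_sam(
    reads: Sequence[SimRead],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """Coordinate-sorted SAM with HP tags where haplotypes are simulated."""
    import pysam

    names = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(reference[n])} for n in names],
    }
    ref_index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sorted(reads, key=lambda x: (ref_index[x.chrom], x.ref_start)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = ref_index[r.chrom]
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.seq_aligned
            a.query_qualities = r.qualities
            if r.haplotype is not None:
                a.set_tag("HP", r.haplotype, value_type="i")
            out.write(a)


def write_calls_tsv(
    calls: Sequence[PerReadMethCall],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write calls in the documented caller dialect (10 tab-separated columns)."""
    with open(path, "w") as fh:
        for c in calls:
            seq = reference[c.reference_id]
            if c.ref_strand == "+":
                pos_in_strand = c.ref_pos
                kmer = seq[max(0, c.ref_pos - 6): c.ref_pos + 7]
            else:
                pos_in_strand = len(seq) - 1 - c.ref_pos
                kmer = revcomp(seq[max(0, c.ref_pos - 6): c.ref_pos + 7])
            label = c.called_label if c.called_label is not None else int(c.prob_meth >= 0.5)
            fh.write(
                f"{c.reference_id}\t{c.ref_pos}\t{c.ref_strand}\t{pos_in_strand}"
                f"\t{c.read_id}\tt\t{1 - c.prob_meth:.4f}\t{c.prob_meth:.4f}"
                f"\t{label}\t{kmer}\n"
            )


def write_haplotypes_tsv(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            hp = r.haplotype if r.haplotype is not None else "none"
            fh.write(f"{r.read_id}\t{hp}\n")


def write_architecture_bed(
    config: SimulationConfig, truth: GroundTruth, path: str | Path
) -> None:
    rows = []
    for name in truth.fragments:
        for kind, table in (
            ("fragment", truth.fragments),
            ("promoter", truth.promoter_intervals),
            ("body", truth.body_intervals),
            ("island", truth.island_intervals),
            ("repeat", truth.repeat_intervals),
        ):
            a, b = table[name]
            rows.append((config.chrom_name, a, b, f"{name}_{kind}"))
    rows.sort(key=lambda r: (r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, a, b, label in rows:
            fh.write(f"{chrom}\t{a}\t{b}\t{label}\n")


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Run the full generator and write every output file to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, truth = make_reference(config)
    reads = simulate_reads(config, reference, truth)
    calls = simulate_meth_calls(config, reference, reads, truth)

    paths = {
        "fasta": outdir / "reference.fasta",
        "fastq": outdir / "reads.fastq",
        "sam": outdir / "alignments.sam",
        "calls": outdir / "meth_calls.tsv",
        "haplotypes": outdir / "haplotypes.tsv",
        "architecture": outdir / "architecture.bed",
        "truth": outdir / "ground_truth.json",
    }
    write_fasta(reference, paths["fasta"])
    write_fastq(reads, paths["fastq"])
    write_sam(reads, reference, paths["sam"])
    write_calls_tsv(calls, reference, paths["calls"])
    write_haplotypes_tsv(reads, paths["haplotypes"])
    write_architecture_bed(config, truth, paths["architecture"])
    truth.to_json(paths["truth"])
    logger.info(
        "simulated %d reads (%d on-target), %d methylation calls",
        len(reads), sum(1 for r in reads if r.is_on_target), len(calls),
    )
    return paths, truth
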