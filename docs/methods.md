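# Methods

This note documents the models and conventions the package implements,
the synthetic-data generator's assumptions, and the numerical choices
made where the design was genuinely open.

## Coordinates and formats

Internally every interval is 0-based half-open.  Human-facing reports
and CLI arguments use the GenBank-style 1-based inclusive
`ref:start..end` dialect; BED files are the 0-based alternative.  SAM
I/O goes through pysam throughout; caller tables are tab-separated in
the documented `deepsignal-plant` column layout (chrom, position,
strand, position-in-strand, read name, read strand, prob-unmethylated,
prob-methylated, label, k-mer).

## Guide-panel geometry (`panel`)

Protospacer search is **exact**: a site is a verbatim 20-nt spacer
match immediately adjacent to an IUPAC-matched PAM, scanned on both
strands.  The blunt cut is placed 3 bp 5′ of the PAM (between
protospacer positions 17/18), the canonical SpCas9 geometry.  Exact
matching fits the verification use-case — confirming a designed panel
against its design reference — and keeps every result checkable by
direct string slicing; it is not an off-target *predictor*, so the
off-target count here is likewise a plain exact-occurrence census
outside the declared targets, not a scored search.

## Enrichment accounting (`ontarget`)

- **Genome coverage** is total retained read bases over genome size —
  all bases, aligned or not, matching how run yield is reported.
- **Mean locus depth** counts primary alignments only (one molecule,
  one count); a position is covered by M/=/X bases, deletions do not
  cover, insertions do not add.
- **Enrichment rate** is mean locus depth ÷ genome coverage.  This is
  the only definition under which published per-locus enrichment and
  depth figures are mutually consistent (enrichment × coverage
  reproduces the printed depths), so it is adopted as the formula.
- **On-target classification**: a read is on-target for a locus when
  its primary alignment overlaps the locus by ≥ 200 aligned bases
  (configurable).  The 200 bp default excludes adapter-scale spurious
  touches at nanopore read lengths.
- **Read quality** averages on the error-probability scale
  (Q = −10·log₁₀(mean per-base error)), matching basecaller-reported
  read Q-scores; the retention rule is strict (`mean Q > threshold`).
- **N50** is the largest length L such that reads ≥ L hold at least
  half the total yield; it is always the length of an actual read.

## MM/ML tagging (`methtag`)

Calls are mapped reference→read with a hand-written CIGAR walk
(M/I/D/N/S/H/P/=/X), validated in tests against pysam's aligned-pairs
as an independent oracle.  Reverse-strand alignments re-express the
coordinate in the read's original orientation
(`read_len − 1 − seq_index`), because MM/ML are defined on the
original-orientation sequence.

Choices:

- **Skip mode `?`** (unlisted cytosines = unknown).  Targeted-run calls
  are sparse per read; the implicit-unmodified mode would assert
  unmodified status for every unscored C.
- **ML alongside MM.**  Probabilities are available, so both tags are
  written (`floor(p·256)` capped at 255); `--no-ml` suppresses ML for
  minimal output.
- **Strand discipline.**  A call on the − reference strand is a C only
  on a read sequenced from that strand; opposite-strand calls are
  dropped with a counter.  After mapping, a position whose read base is
  not `C` (a sequencing error under the call) is dropped with its own
  counter; inside `encode_mm` the same condition is an *error*, since
  there it signals a coordinate-mapping bug rather than read noise.
- **Code `m` for all contexts.**  CpG/CHG/CHH all carry 5mC; context is
  a property of the reference neighbourhood and is preserved in the
  profiling layer, not in the tag.
- **Idempotence.**  Existing MM/ML tags are removed before writing, so
  re-tagging replaces rather than duplicates.

The decoder inverts the encoding exactly in position and within 1/256
in probability (decoded probability is `ml/256`, the low edge of the
bin).

## Methylation profiling (`methprofile`)

Binarisation uses a single cut at 0.5 with ties methylated — the
argmax label a two-class caller would emit; the threshold is a
parameter.  Per-site frequency is methylated/(methylated+unmethylated)
with missing entries excluded; a site left uncovered (e.g. after a
haplotype subset) reports NaN, and pooled frequencies equal the
coverage-weighted mean of the per-group frequencies by construction.

**Destranding.**  CpG methylation is strand-symmetric, and one nanopore
read reports one strand, so per-site CpG coverage is roughly half the
read depth unless the two strands are merged.  `destrand_cpg` remaps
the G-side site of each CpG onto its C position (standard practice in
methylation callers); non-CpG sites are unaffected.

**Promoter/body contrast.**  Interval boundaries are user inputs — gene
annotation is upstream knowledge, not inferred here.  The permutation
test (reshuffling site-to-interval labels, two-sided on the absolute
difference of means, p = (1+k)/(n+1)) is an *extension*: it puts a
number on a contrast that per-read displays show visually.  Sites are
treated as exchangeable under the null; spatial autocorrelation of
methylation makes this anti-conservative for closely spaced sites, a
known limitation.

**Haplotypes.**  Reads labelled HP1/HP2 (from a phasing tool's `HP`
tags or a TSV) yield one profile each; unassigned reads are excluded
from per-allele profiles but included in the pooled one.

## Sequence composition (`seqcomp`)

**CpG islands** use the classical thresholds (length ≥ 200 bp,
GC > 0.5, O/E CpG > 0.6) as defaults, all configurable.  The detector
slides a 200 bp window (step 1), merges overlapping qualifying windows
into candidate runs, and within each run keeps every *maximal*
qualifying subinterval (one not contained in a larger qualifying
subinterval of the run), resolving overlaps left-to-right, longest
first.  GC excludes N from the denominator; O/E counts only CpGs wholly
inside the interval; an interval with no C or no G fails by definition.
A consequence of maximality worth knowing: a very CpG-dense tract can
carry flanking sequence into its island as long as the union still
qualifies, so reported islands can be wider than the dense core.

**Dot plot** matches are exact k-mer self-identities (default k = 15)
off the main diagonal, on both strands; repeat segments are maximal
tracts whose bases are covered by at least one off-diagonal match, with
gaps ≤ 10 bp bridged and sub-k fragments discarded.  This replaces
scored local alignment with a deterministic, oracle-testable primitive
that reproduces low-complexity delineation; it will not find diverged
repeats below the exact-k-mer identity floor.

## Synthetic data (`synth`)

The generator emulates the observed regime of a Cas9-targeted nanopore
run on a large plant genome, scaled so the full pipeline runs in
seconds.

- **Reference.**  An i.i.d. background at GC 0.42 with ~70 % of
  background CpG dinucleotides suppressed, mimicking the
  methylation-driven CpG depletion of bulk plant genomic DNA (O/E ≈
  0.3), so designed islands stand out as they do in real sequence.
  Each locus carries: a promoter (first 1 kb), a gene body, a designed
  CpG-rich island tract (40 % forced CG dinucleotides), a tandem-repeat
  tract (60-mer unit), and two flanking guide sites whose predicted
  cuts fall exactly on the locus boundaries.  `make_reference`
  self-audits: the designed island, repeat and unique guide sites must
  be re-detected by the package's own detectors.
- **Default study conditions.**  Three loci of 3.4 / 5.1 / 3.6 kb at
  target depths 5× / 8× / 15× — the fragment sizes and depth range of
  the motivating experiment — with lognormal background read lengths
  (mean 3.1 kb, the observed N50 scale).  The default genome is 10 Mb
  with 150 kb background yield; tests and the acceptance script use a
  1 Mb genome with 30 kb background, stated here as the problem size.
  A scaled background cannot reproduce the *absolute* on-target
  fraction of a 24 Gb genome (~0.03 %); that quantity is covered by
  desk arithmetic, while the simulation covers depth, enrichment and
  methylation recovery.
- **Reads.**  On-target reads span cut-to-cut with Gaussian end jitter
  (σ = 30 bp); background reads are uniform, re-drawn if they touch a
  fragment so per-read origin truth is unambiguous.  Errors are
  substitution-only by default (5 %, shifted-base model) to keep
  coordinate-mapping tests interpretable; indel rates are available and
  produce consistent CIGARs.  Base qualities are Gaussian around Q13.
- **Methylation truth.**  Gene-body methylation: promoter CpG 0.05,
  body CpG 0.95, CHG/CHH 0.01 throughout the locus — gbM is
  CpG-specific, and the near-deterministic levels match a consistently
  methylated island rather than a mosaic.  Background regions use
  wheat-like bulk levels (CpG 0.6, CHG 0.3, CHH 0.08).  Per (read,
  site) the molecule state is Bernoulli in the regional probability;
  the emitted caller probability is a clipped Gaussian around 0.9
  (methylated) or 0.1 (unmethylated), σ = 0.05, so binarisation noise
  is negligible and recovery error is dominated by molecular sampling,
  as in real data.
- **Haplotypes.**  Two-allele mode plants SNPs only at A/T positions
  (A↔T swap), so both alleles share an identical cytosine landscape and
  methylation comparisons between haplotypes are not confounded by
  sequence differences.  Reads draw their haplotype 50/50 and carry
  `HP` tags.
- **Determinism.**  One integer seed; stages draw from
  `default_rng([seed, stage])` with stage 0 = reference, 1 = reads,
  2 = calls.  Same seed, byte-identical outputs.

What the generator does **not** model: raw-signal/basecalling error
structure (homopolymer bias, strand-specific error), chimeric or
adapter-contaminated reads, mappability artefacts, copy-number
variation, or spatially correlated methylation within a molecule.
Passing recovery tests therefore demonstrates the *accounting and
conversion* pipeline is correct under known truth, not that upstream
callers are accurate on real signal.

## Numerical conventions

- Frequency comparisons in recovery checks carry a 1e-9 epsilon so
  exact ties at a tolerance boundary (e.g. |3/15 − 0.05| = 0.15) do not
  fail on floating-point representation.
- Permutation p-values use the add-one estimator (1+k)/(n+1), never 0.
- ML probabilities quantise by floor to 1/256 bins; round trips are
  asserted within one bin.
- Empty inputs: empty FASTQ yields zero stats (not an error); an empty
  region overlap yields an empty matrix; N50 of an empty set and
  enrichment at zero coverage are errors.
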