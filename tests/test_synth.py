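"""Generator self-consistency: determinism, architecture audits, truth recovery."""

import numpy as np
import pysam
import pytest

from ncats.methprofile import build_matrix, destrand_cpg, site_frequency, split_by_haplotype
from ncats.ontarget import classify_on_target
from ncats.regions import TargetLocus
from ncats.seqcomp import dotplot_matches, find_cpg_islands
from ncats.synth import (
    LocusSpec,
    SimulationConfig,
    make_reference,
    simulate_meth_calls,
    simulate_reads,
)

from conftest import small_sim_config


class TestConfigValidation:
    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError, match="target_depth"):
            LocusSpec(name="x", start=1000, length=3000, target_depth=0)

    def test_architecture_must_fit_locus(self):
        with pytest.raises(ValueError, match="exceeds locus length"):
            LocusSpec(name="x", start=1000, length=2000, island=(1500, 2500))

    def test_probabilities_validated(self):
        cfg = small_sim_config()
        bad = {k: dict(v) for k, v in cfg.meth_probs.items()}
        bad["body"]["CpG"] = 1.5
        with pytest.raises(ValueError, match="outside"):
            small_sim_config(meth_probs=bad)

    def test_locus_near_genome_edge_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            SimulationConfig(
                seed=1, genome_size=10_000,
                loci=[LocusSpec(name="x", start=50, length=3200)],
            )


class TestMakeReference:
    def test_same_seed_identical_reference(self):
        cfg = small_sim_config(seed=5)
        ref1, _ = make_reference(cfg, audit=False)
        ref2, _ = make_reference(small_sim_config(seed=5), audit=False)
        assert ref1 == ref2
        ref3, _ = make_reference(small_sim_config(seed=6), audit=False)
        assert ref1 != ref3

    def test_designed_island_and_repeat_are_redetected(self, sim_memory):
        reference, truth, _, _ = sim_memory
        seq = reference[truth.chrom]
        for name, (a, b) in truth.island_intervals.items():
            frag_a, frag_b = truth.fragments[name]
            islands = find_cpg_islands(seq[frag_a:frag_b])
            assert any(i.start + frag_a < b and a < i.end + frag_a for i in islands)
        for name, (a, b) in truth.repeat_intervals.items():
            frag_a, frag_b = truth.fragments[name]
            segs, _ = dotplot_matches(seq[frag_a:frag_b], k=15)
            assert any(s.start + frag_a < b and a < s.end + frag_a for s in segs)

    def test_locus_without_designed_repeat_yields_no_segments(self):
        cfg = small_sim_config()
        reference, truth = make_reference(cfg, audit=False)
        seq = reference[truth.chrom]
        # a window of plain background sequence has no self-similarity
        background = seq[50_000:55_000]
        segs, _ = dotplot_matches(background, k=15)
        assert segs == []


class TestSimulateReads:
    def test_realized_depth_matches_target(self, sim_memory, sim_config):
        _, truth, _, _ = sim_memory
        for spec in sim_config.loci:
            assert truth.realized_depth[spec.name] == pytest.approx(
                spec.target_depth, abs=2.0
            )

    def test_zero_error_rate_reproduces_reference(self):
        cfg = small_sim_config(substitution_rate=0.0, background_yield=5_000)
        reference, truth = make_reference(cfg, audit=False)
        reads = simulate_reads(cfg, reference, truth)
        seq = reference[truth.chrom]
        for r in reads[:10]:
            assert r.seq_aligned == seq[r.ref_start:r.ref_end]

    def test_on_target_counts_recovered_by_classifier(self, sim_files):
        paths, truth = sim_files
        loci = [
            TargetLocus(name=n, reference_id=truth.chrom, start=a, end=b)
            for n, (a, b) in truth.fragments.items()
        ]
        hits = classify_on_target(str(paths["sam"]), loci)
        for name, n_true in truth.n_on_target.items():
            assert len(hits[name]) == n_true

    def test_on_target_reads_start_near_cut_sites(self, sim_memory, sim_config):
        _, truth, reads, _ = sim_memory
        for r in reads:
            if r.locus is None:
                continue
            frag_start, frag_end = truth.fragments[r.locus]
            assert abs(r.ref_start - frag_start) <= 5 * sim_config.end_jitter_sd
            assert abs(r.ref_end - frag_end) <= 5 * sim_config.end_jitter_sd

    def test_background_reads_avoid_fragments(self, sim_memory):
        _, truth, reads, _ = sim_memory
        for r in reads:
            if r.locus is None:
                for fs, fe in truth.fragments.values():
                    assert r.ref_end <= fs or fe <= r.ref_start

    def test_indel_mode_produces_consistent_cigars(self):
        cfg = small_sim_config(insertion_rate=0.01, deletion_rate=0.01,
                              background_yield=3_000)
        reference, truth = make_reference(cfg, audit=False)
        reads = simulate_reads(cfg, reference, truth)
        from ncats.methtag import parse_cigar

        for r in reads[:20]:
            ops = parse_cigar(r.cigar)
            q = sum(n for op, n in ops if op in "MIS=X")
            assert q == len(r.seq_aligned)
            assert any(op in "ID" for op, _ in ops) or len(r.cigar) <= 12


class TestSimulateMethCalls:
    def test_fully_methylated_region_gives_unit_frequency(self):
        probs = {
            "promoter": {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            "body": {"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            "background": {"CpG": 0.5, "CHG": 0.5, "CHH": 0.5},
        }
        cfg = small_sim_config(meth_probs=probs, background_yield=2_000)
        reference, truth = make_reference(cfg, audit=False)
        reads = simulate_reads(cfg, reference, truth)
        calls = simulate_meth_calls(cfg, reference, reads, truth)
        a, b = truth.fragments["gene3"]
        region = TargetLocus(name="g3", reference_id=truth.chrom, start=a, end=b)
        prof = site_frequency(build_matrix(calls, region))
        assert np.nanmean(prof.frequency) > 0.99

    def test_gbm_architecture_recovered(self, sim_memory, sim_config):
        reference, truth, _, calls = sim_memory
        a, b = truth.fragments["gene3"]
        region = TargetLocus(name="g3", reference_id=truth.chrom, start=a, end=b)
        matrix = destrand_cpg(build_matrix(calls, region), reference[truth.chrom])
        prof = site_frequency(matrix)
        pa, pb = truth.promoter_intervals["gene3"]
        ba, bb = truth.body_intervals["gene3"]
        seq = reference[truth.chrom]
        pos = prof.site_positions
        is_cpg = np.array([seq[p:p + 2] == "CG" for p in pos])
        prom_cpg = prof.frequency[(pos >= pa) & (pos < pb) & is_cpg]
        body_cpg = prof.frequency[(pos >= ba) & (pos < bb) & is_cpg]
        assert np.nanmean(prom_cpg) == pytest.approx(
            sim_config.meth_probs["promoter"]["CpG"], abs=0.05
        )
        assert np.nanmean(body_cpg) == pytest.approx(
            sim_config.meth_probs["body"]["CpG"], abs=0.05
        )

    def test_haplotype_specific_truth_separates(self):
        hp2 = {
            "promoter": {"CpG": 0.05, "CHG": 0.01, "CHH": 0.01},
            "body": {"CpG": 0.2, "CHG": 0.01, "CHH": 0.01},
            "background": {"CpG": 0.6, "CHG": 0.3, "CHH": 0.08},
        }
        cfg = small_sim_config(
            seed=21, two_haplotypes=True, hp2_meth_probs=hp2,
            background_yield=2_000,
        )
        # haplotype 1 keeps the default 0.9-ish body truth; haplotype 2 is 0.2
        cfg.meth_probs["body"]["CpG"] = 0.9
        reference, truth = make_reference(cfg, audit=False)
        reads = simulate_reads(cfg, reference, truth)
        calls = simulate_meth_calls(cfg, reference, reads, truth)
        a, b = truth.body_intervals["gene3"]
        region = TargetLocus(name="body3", reference_id=truth.chrom, start=a, end=b)
        matrix = destrand_cpg(build_matrix(calls, region), reference[truth.chrom])
        mapping = {
            rid: info["haplotype"] for rid, info in truth.read_origin.items()
        }
        per_hp = split_by_haplotype(matrix, mapping)
        seq = reference[truth.chrom]
        def cpg_mean(prof):
            is_cpg = np.array([seq[p:p + 2] == "CG" for p in prof.site_positions])
            vals = prof.frequency[is_cpg]
            return np.nanmean(vals)
        assert cpg_mean(per_hp["HP1"]) == pytest.approx(0.9, abs=0.12)
        assert cpg_mean(per_hp["HP2"]) == pytest.approx(0.2, abs=0.12)

    def test_haplotypes_share_cytosine_landscape(self):
        cfg = small_sim_config(seed=22, two_haplotypes=True, background_yield=2_000)
        reference, truth = make_reference(cfg, audit=False)
        seq = reference[truth.chrom]
        for positions in truth.snp_positions.values():
            assert positions
            for p in positions:
                assert seq[p] in "AT"

    def test_calls_follow_read_strand(self, sim_memory):
        reference, truth, reads, calls = sim_memory
        seq = reference[truth.chrom]
        strand_of = {r.read_id: r.strand for r in reads}
        for c in calls[::997]:
            assert c.ref_strand == strand_of[c.read_id]
            assert seq[c.ref_pos] == ("C" if c.ref_strand == "+" else "G")


class TestEnrichmentTruth:
    def test_truth_enrichment_consistent_with_definition(self, sim_memory):
        _, truth, _, _ = sim_memory
        for name, enr in truth.true_enrichment.items():
            assert enr == pytest.approx(
                truth.realized_depth[name] / truth.genome_coverage, rel=1e-12
            )

    def test_sam_fastq_roundtrip_preserves_yield(self, sim_files):
        paths, truth = sim_files
        n_bases = 0
        with pysam.FastxFile(str(paths["fastq"])) as fh:
            for entry in fh:
                n_bases += len(entry.sequence)
        assert n_bases == truth.total_bases
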