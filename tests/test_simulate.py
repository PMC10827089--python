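"""Simulator determinism, read semantics, multi-mapper exactness."""

import numpy as np
import pytest
from scipy import stats as sps

from centrotx import (
    MultiMapper,
    build_cen_domains,
    simulate_nascent_reads,
    simulate_peaks,
    simulate_repeat_genome,
    small_config,
    twin_config,
)


class TestGenomeGenerator:
    def test_seed_determinism_and_seed_sensitivity(self):
        a1, e1, t1 = simulate_repeat_genome(small_config(seed=1))
        a2, e2, t2 = simulate_repeat_genome(small_config(seed=1))
        a3, _, _ = simulate_repeat_genome(small_config(seed=2))
        assert a1.contigs == a2.contigs
        assert e1 == e2
        assert t1.active_ids == t2.active_ids
        assert a1.contigs != a3.contigs

    def test_divergence_zero_copies_identical(self):
        asm, elements, _ = simulate_repeat_genome(twin_config(seed=3))
        (e1, e2) = elements
        s1 = asm.contigs[e1.contig][e1.start:e1.end]
        s2 = asm.contigs[e2.contig][e2.start:e2.end]
        from centrotx import revcomp

        if e1.strand != e2.strand:
            s2 = revcomp(s2)
        assert s1 == s2

    def test_truncated_copies_are_three_prime_suffixes(self):
        cfg = small_config(seed=4)
        _, elements, _ = simulate_repeat_genome(cfg)
        for el in elements:
            assert el.consensus_end == cfg.consensus_length  # 3'-anchored
            assert 0 <= el.consensus_start < el.consensus_end

    def test_unique_kmer_density_inside_diverged_fl_copy(self):
        # a position of a copy is covered by a single-copy 21-mer when one of
        # the ~2k-1 surrounding windows carries a private mutation; at
        # divergence d the expected coverage is ~ 1 - (1-d)^(2k-1)
        # (0.88 at d=0.05), rising with d
        from centrotx import kmer_coverage_per_interval, single_copy_kmer_track

        means = {}
        for d in (0.03, 0.05, 0.10):
            fracs = []
            for seed in range(3):
                cfg = small_config(seed=seed, divergence=d)
                asm, elements, _ = simulate_repeat_genome(cfg)
                track = single_copy_kmer_track(asm, 21)
                fl = [e for e in elements if e.consensus_start == 0]
                cov = kmer_coverage_per_interval(track, fl)
                fracs.append(cov["fraction"].mean())
            means[d] = np.mean(fracs)
            expected = 1 - (1 - d) ** 41
            assert abs(means[d] - expected) < 0.1, (d, means[d], expected)
        assert means[0.03] < means[0.05] < means[0.10]

    def test_copies_do_not_fit_is_hard_error(self):
        cfg = small_config(seed=1, island_length=100)
        with pytest.raises(ValueError, match="do not fit"):
            simulate_repeat_genome(cfg)


class TestReadSimulator:
    def test_depth_reads_per_active_copy_all_inside(self):
        cfg = small_config(seed=6, depth=50)
        asm, _, truth = simulate_repeat_genome(cfg)
        reads = simulate_nascent_reads(asm, truth, cfg)
        assert len(reads) == 50 * len(truth.active_ids)
        for r in reads:
            el = truth.element(r.copy_id)
            assert el.start <= r.start and r.end <= el.end

    def test_reads_match_genome_at_true_placement(self):
        from centrotx import revcomp

        cfg = small_config(seed=6)
        asm, _, truth = simulate_repeat_genome(cfg)
        for r in simulate_nascent_reads(asm, truth, cfg):
            g = asm.contigs[r.contig][r.start:r.end]
            assert r.seq == (g if r.strand == "+" else revcomp(g))

    def test_antisense_flag_flips_strands(self):
        cfg = small_config(seed=6)
        asm, _, truth = simulate_repeat_genome(cfg)
        sense = {r.read_id: r.strand for r in simulate_nascent_reads(asm, truth, cfg)}
        cfg_a = small_config(seed=6, antisense=True)
        asm_a, _, truth_a = simulate_repeat_genome(cfg_a)
        anti = {r.read_id: r.strand for r in simulate_nascent_reads(asm_a, truth_a, cfg_a)}
        assert set(sense) == set(anti)
        assert all(sense[k] != anti[k] for k in sense)

    def test_short_copy_skipped_with_warning(self):
        cfg = small_config(seed=8, read_length=100, truncation_frac=(0.01, 0.015))
        asm, _, truth = simulate_repeat_genome(cfg)
        short_ids = [e.element_id for e in truth.elements if e.length < cfg.read_length]
        long_ids = [e.element_id for e in truth.elements if e.length >= cfg.read_length]
        assert short_ids and long_ids
        truth.active_ids = [short_ids[0], long_ids[0]]  # force the skip path
        with pytest.warns(UserWarning, match="skipped"):
            reads = simulate_nascent_reads(asm, truth, cfg)
        assert {r.copy_id for r in reads} == {long_ids[0]}

    def test_three_prime_positions_roughly_uniform(self):
        cfg = twin_config(seed=10, depth=2000)
        asm, _, truth = simulate_repeat_genome(cfg)
        reads = simulate_nascent_reads(asm, truth, cfg)
        el = truth.element(truth.active_ids[0])
        pos = np.array([r.three_prime_pos for r in reads if r.copy_id == el.element_id])
        lo = el.start + cfg.read_length - 1 if el.strand == "+" else el.start
        hi = el.end if el.strand == "+" else el.end - cfg.read_length + 1
        u = (pos - lo) / (hi - lo)
        _, p = sps.kstest(u, "uniform")
        assert p > 0.01


class TestMultiMapper:
    def test_exhaustive_against_naive_scan(self, rng):
        # tiny genome: verify the pigeonhole index finds exactly the naive placements
        from centrotx import GenomeAssembly, revcomp

        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=600))
        seq = seq + seq[100:160] + seq[-50:]  # engineered duplications
        asm = GenomeAssembly({"c": seq})
        mapper = MultiMapper(asm, max_mismatch=1)
        for _ in range(20):
            start = int(rng.integers(0, len(seq) - 30))
            read = seq[start : start + 30]
            got = sorted(mapper.placements(read))
            naive = []
            for strand, q in (("+", read), ("-", revcomp(read))):
                for i in range(len(seq) - 29):
                    mm = sum(1 for x, y in zip(seq[i : i + 30], q) if x != y)
                    if mm <= 1:
                        naive.append(("c", i, strand, mm))
            assert got == sorted(naive)

    def test_tie_rule_and_k100_reports_both_loci(self):
        cfg = twin_config(seed=12, depth=30)
        asm, _, truth = simulate_repeat_genome(cfg)
        reads = simulate_nascent_reads(asm, truth, cfg)
        from centrotx import toy_multimapper

        best, k100 = toy_multimapper(reads, asm, cfg)
        per_read_k100 = {}
        for a in k100.alignments:
            per_read_k100.setdefault(a.read_id, []).append(a)
        assert all(len(v) == 2 for v in per_read_k100.values())
        assert len(best.alignments) == len(reads)

    def test_best_match_prefers_fewer_mismatches(self):
        from centrotx import GenomeAssembly

        base = "ACGTTGCAACGGATCGGATTACAGGCATGAGCCA"
        mut = base[:5] + ("A" if base[5] != "A" else "C") + base[6:]
        filler1 = "TTTTTGGGGGCCCCCAAAAA" * 3
        filler2 = "GATCGATCGATCGATCGATC" * 3
        asm = GenomeAssembly({"c": filler1 + base + filler2 + mut + filler1[::-1]})
        cfg = twin_config(seed=1, max_mismatch=1)
        from centrotx import SimRead, toy_multimapper

        reads = [SimRead("r0", base, "x", "c", 0, len(base), "+", 0)]
        best, k100 = toy_multimapper(reads, asm, cfg)
        assert len(k100.alignments) == 2  # 0-mm locus and 1-mm locus
        (b,) = best.alignments
        assert b.mismatches == 0
        assert b.start == len(filler1)

    def test_best_subset_of_k100(self, small_run):
        k100_keys = {
            (a.read_id, a.contig, a.start, a.strand)
            for a in small_run["alignment_sets"]["k100"].alignments
        }
        for a in small_run["alignment_sets"]["best_match"].alignments:
            assert (a.read_id, a.contig, a.start, a.strand) in k100_keys


class TestSimulatedPeaks:
    def test_peak_count_and_domain_composition(self):
        cfg = small_config(seed=14)
        _, _, truth = simulate_repeat_genome(cfg)
        peaks = simulate_peaks(truth, cfg, peaks_per_island=3)
        n_islands = sum(1 for r in truth.cenpa_regions if r[3] == "CEN")
        n_noncen = sum(1 for r in truth.cenpa_regions if r[3] == "nonCEN")
        assert len(peaks) == 3 * n_islands + n_noncen
        domains = build_cen_domains(peaks, cfg.centromeric_contigs)
        assert len(domains) == n_islands

    def test_zero_regions_empty(self):
        cfg = small_config(seed=14)
        _, _, truth = simulate_repeat_genome(cfg)
        truth.cenpa_regions = []
        assert simulate_peaks(truth, cfg) == []

    def test_deterministic_under_seed(self):
        cfg = small_config(seed=15)
        _, _, truth = simulate_repeat_genome(cfg)
        p1 = simulate_peaks(truth, cfg)
        p2 = simulate_peaks(truth, cfg)
        assert [(p.contig, p.start, p.end, p.signal) for p in p1] == [
            (p.contig, p.start, p.end, p.signal) for p in p2
        ]
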