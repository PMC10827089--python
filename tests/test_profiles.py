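"""Alignment modes, 3'-end extraction, counting, density matrices, coverage."""

import numpy as np
import pytest

from centrotx import (
    AlignmentSet,
    GenomeAssembly,
    ReadAlignment,
    RepeatElement,
    ThreePrimeSignal,
    count_over_intervals,
    extract_three_prime_ends,
    load_alignments,
    repeat_density_matrix,
    revcomp,
    simulate_nascent_reads,
    simulate_repeat_genome,
    small_config,
    toy_multimapper,
    write_alignments,
    write_coverage,
)

from _oracles import overlap_counts


def _write_table(path, rows):
    path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))


class TestLoadAlignments:
    def test_best_match_duplicate_read_is_error(self, tmp_path):
        p = tmp_path / "a.tsv"
        _write_table(p, [("c", 0, 50, "r1", 0, "+", "."), ("c", 100, 150, "r1", 0, "+", ".")])
        with pytest.raises(ValueError, match="r1"):
            load_alignments(p, mode="best_match")

    def test_k100_cap_accepts_100_rejects_101(self, tmp_path):
        p = tmp_path / "a.tsv"
        _write_table(p, [("c", i, i + 50, "r1", 0, "+", ".") for i in range(100)])
        aset = load_alignments(p, mode="k100")
        assert len(aset.alignments) == 100
        _write_table(p, [("c", i, i + 50, "r1", 0, "+", ".") for i in range(101)])
        with pytest.raises(ValueError, match="at most 100"):
            load_alignments(p, mode="k100")

    def test_round_trip_on_simulator_output(self, tmp_path, small_run):
        aset = small_run["alignment_sets"]["k100"]
        p = tmp_path / "k100.tsv"
        write_alignments(aset, p, small_run["assembly"])
        loaded = load_alignments(p, mode="k100", library=aset.library,
                                 orientation=aset.orientation)
        assert sorted(
            (a.read_id, a.contig, a.start, a.end, a.strand, a.mismatches)
            for a in loaded.alignments
        ) == sorted(
            (a.read_id, a.contig, a.start, a.end, a.strand, a.mismatches)
            for a in aset.alignments
        )


class TestThreePrimeExtraction:
    def _set(self, alignments, orientation="reads_are_sense", library="proseq"):
        return AlignmentSet(mode="best_match", alignments=alignments,
                            library=library, orientation=orientation)

    def test_sense_rules(self):
        sig = extract_three_prime_ends(
            self._set([ReadAlignment("r1", "c", 100, 150, "+"), ReadAlignment("r2", "c", 100, 150, "-")])
        )
        assert sig.records == [("c", 149, "+"), ("c", 100, "-")]

    def test_read1_revcomp_flips_then_applies_rule(self):
        sig = extract_three_prime_ends(
            self._set([ReadAlignment("r1", "c", 100, 150, "+")], orientation="read1_revcomp")
        )
        assert sig.records == [("c", 100, "-")]

    def test_rnaseq_rejected(self):
        with pytest.raises(ValueError, match="PRO-seq"):
            extract_three_prime_ends(self._set([], library="rnaseq"))

    def test_one_record_per_alignment_conservation(self, small_run):
        for mode, aset in small_run["alignment_sets"].items():
            sig = extract_three_prime_ends(aset)
            assert len(sig) == len(aset.alignments), mode

    def test_strand_flip_symmetry(self):
        # reverse-complementing genome and reads maps position p -> L-1-p
        cfg = small_config(seed=31, centromeric_contigs=("cenA",), arm_contigs=(),
                          copies_per_contig={"cenA": 4}, fl_per_contig={"cenA": 2})
        asm, _, truth = simulate_repeat_genome(cfg)
        reads = simulate_nascent_reads(asm, truth, cfg)
        best, _ = toy_multimapper(reads, asm, cfg)
        flipped = GenomeAssembly(
            {c: revcomp(s) for c, s in asm.contigs.items()},
            centromeric_ids=asm.centromeric_ids,
        )
        best_f, _ = toy_multimapper(reads, flipped, cfg)
        sig = {(c, p, s) for c, p, s in extract_three_prime_ends(best).records}
        sig_f = extract_three_prime_ends(best_f).records
        L = {c: len(s) for c, s in asm.contigs.items()}
        mapped_back = {(c, L[c] - 1 - p, "-" if s == "+" else "+") for c, p, s in sig_f}
        assert mapped_back == sig


class TestCounting:
    IVS = [("c", 19, 30, "iv1"), ("c", 20, 30, "iv2")]

    def test_one_bp_overlap_rule(self):
        aset = AlignmentSet(mode="best_match", alignments=[ReadAlignment("r", "c", 10, 20, "+")])
        counts = count_over_intervals(aset, self.IVS, min_overlap_bp=1)
        assert counts["iv1"] == 1  # [10,20) vs [19,30): 1 bp shared
        assert counts["iv2"] == 0  # half-open disjoint

    def test_signal_counts_position_membership(self):
        sig = ThreePrimeSignal(records=[("c", 19, "+"), ("c", 30, "-")])
        counts = count_over_intervals(sig, self.IVS)
        assert counts["iv1"] == 1 and counts["iv2"] == 0

    def test_strand_filter(self):
        sig = ThreePrimeSignal(records=[("c", 25, "+"), ("c", 26, "-")])
        assert count_over_intervals(sig, self.IVS, strand="+")["iv2"] == 1
        assert count_over_intervals(sig, self.IVS, strand="-")["iv2"] == 1

    def test_matches_quadratic_oracle_on_simulation(self, small_run):
        aset = small_run["alignment_sets"]["k100"]
        elements = small_run["elements"]
        counts = count_over_intervals(aset, elements)
        records = [(a.contig, a.start, a.end) for a in aset.alignments]
        expected = overlap_counts(records, [(e.contig, e.start, e.end) for e in elements])
        assert counts.tolist() == expected


class TestDensityMatrix:
    def _asm(self):
        return GenomeAssembly({"c1": "A" * 1000, "c2": "A" * 1000})

    def _els(self):
        return [
            RepeatElement("a1", "c1", 100, 200, "+", "famA", 0, 100),
            RepeatElement("a2", "c1", 300, 400, "+", "famA", 0, 100),
            RepeatElement("b1", "c1", 500, 600, "+", "famB", 0, 100),
        ]

    def test_density_is_count_over_contig_total(self):
        sig = ThreePrimeSignal(
            records=[("c1", p, "+") for p in (110, 120, 350, 360, 700, 800, 810, 820, 830, 900)]
        )
        m = repeat_density_matrix(sig, self._els(), self._asm())
        assert m.counts.loc["famA", "c1"] == 4
        assert m.density.loc["famA", "c1"] == pytest.approx(0.4)
        assert m.copy_number.loc["famA", "c1"] == 2

    def test_absent_family_zero_and_empty_contig_na(self):
        sig = ThreePrimeSignal(records=[("c1", 110, "+")])
        m = repeat_density_matrix(sig, self._els(), self._asm())
        assert m.counts.loc["famB", "c1"] == 0
        assert m.density.loc["famB", "c1"] == 0.0
        assert m.copy_number.loc["famA", "c2"] == 0
        assert np.isnan(m.density.loc["famA", "c2"])  # zero mapped reads: NA

    def test_record_overlapping_two_copies_counts_once(self):
        els = [
            RepeatElement("a1", "c1", 100, 200, "+", "famA", 0, 100),
            RepeatElement("a2", "c1", 150, 250, "+", "famA", 0, 100),
        ]
        aset = AlignmentSet(mode="best_match", alignments=[ReadAlignment("r", "c1", 140, 260, "+")])
        m = repeat_density_matrix(aset, els, self._asm())
        assert m.counts.loc["famA", "c1"] == 1

    def test_column_totals_match_per_contig_record_counts(self, small_run):
        sig = small_run["signals"]["best_match"]
        m = repeat_density_matrix(sig, small_run["elements"], small_run["assembly"])
        per_contig = {}
        for c, _, _ in sig.records:
            per_contig[c] = per_contig.get(c, 0) + 1
        for contig in small_run["assembly"].contig_order:
            assert m.contig_totals[contig] == per_contig.get(contig, 0)

    def test_argmax_per_contig_is_the_active_family(self, small_run):
        m = small_run["matrix"]
        dens = m.density.dropna(axis=1, how="all")
        for contig in dens.columns:
            col = dens[contig]
            if col.max() > 0:
                assert col.idxmax() == "jockey3"


class TestCoverageWriter:
    def test_two_ends_same_position_aggregate(self, tmp_path):
        sig = ThreePrimeSignal(records=[("ctg", 100, "+"), ("ctg", 100, "+")])
        out = tmp_path / "cov.bedGraph"
        write_coverage(sig, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["ctg\t100\t101\t2"]

    def test_empty_signal_writes_header_only(self, tmp_path):
        out = tmp_path / "cov.bedGraph"
        write_coverage(ThreePrimeSignal(records=[]), out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_value_sum_equals_record_count(self, tmp_path, small_run):
        sig = small_run["signals"]["k100"]
        out = tmp_path / "cov.bedGraph"
        write_coverage(sig, out)
        total = sum(int(l.split("\t")[3]) for l in out.read_text().splitlines()[1:])
        assert total == len(sig)

    def test_stranded_split_conserves_records(self, tmp_path, small_run):
        sig = small_run["signals"]["best_match"]
        out = tmp_path / "cov.bedGraph"
        files = write_coverage(sig, out, stranded=True)
        total = 0
        for f in files:
            total += sum(int(l.split("\t")[3]) for l in f.read_text().splitlines()[1:])
        assert total == len(sig)
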