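"""Column-wise SNP calling, substitution classes, variant regions, rates."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpop.snp_caller import (
    LOOSE,
    STRICT,
    TRANSITION,
    TRANSVERSION,
    SnpRateSummary,
    call_snps,
    classify_substitution,
    detect_variant_regions,
    per_kb,
    snp_rate_summary,
    write_snp_tsv,
    write_vcf,
)

from conftest import column_alignment, make_alignment, random_alignment


def brute_force_calls(aln, strict_min_frac=0.25, strict_min_cov=6,
                      loose_min_reads=2):
    """Independent per-column recount: dict column -> (loose, strict)."""
    out = {}
    for col in range(aln.padded_length):
        if aln.consensus[col] == "-":
            continue
        counts = {}
        for read in aln.reads:
            if read.start <= col < read.start + len(read.bases):
                ch = read.bases[col - read.start]
                if ch in "ACGT":
                    counts[ch] = counts.get(ch, 0) + 1
        if len(counts) < 2:
            continue
        ranked = sorted(counts.values(), reverse=True)
        cov = sum(counts.values())
        loose = ranked[0] >= loose_min_reads and ranked[1] >= loose_min_reads
        strict = cov >= strict_min_cov and ranked[1] / cov >= strict_min_frac
        if loose or strict:
            out[col] = (loose, strict)
    return out


class TestCallSnps:
    def test_strict_and_loose_pass(self):
        aln = column_alignment("c1", "AAAAACCC", consensus_base="A")
        (call,) = call_snps(aln, STRICT)
        assert call.passes_strict and call.passes_loose
        assert (call.major_allele, call.minor_allele) == ("A", "C")
        assert call.coverage == 8
        assert call.allele_counts == {"A": 5, "C": 3}

    def test_rare_minor_fails_both(self):
        aln = column_alignment("c1", "AAAAAAAAAC", consensus_base="A")
        assert call_snps(aln, LOOSE) == []
        assert call_snps(aln, STRICT) == []

    def test_monomorphic_column_not_reported(self):
        aln = column_alignment("c1", "AAAAAAAA", consensus_base="A")
        assert call_snps(aln, LOOSE) == []

    def test_pad_consensus_excluded(self):
        aln = column_alignment("c1", "AACC", consensus_base="-")
        assert call_snps(aln, LOOSE) == []

    def test_n_and_gap_excluded_from_coverage(self):
        # 4 A + 2 C + one N + one gap: coverage 6, minor 2/6 >= 0.25
        aln = column_alignment("c1", "AAAACCN-", consensus_base="A")
        (call,) = call_snps(aln, STRICT)
        assert call.coverage == 6
        assert call.allele_counts == {"A": 4, "C": 2}

    def test_triallelic_column_uses_top_two(self):
        aln = column_alignment("c1", "AAAAACCCGG", consensus_base="A")
        (call,) = call_snps(aln, STRICT)
        assert (call.major_allele, call.minor_allele) == ("A", "C")

    def test_minor_tie_broken_alphabetically(self):
        aln = column_alignment("c1", "AAAACCGG", consensus_base="A")
        (call,) = call_snps(aln, STRICT)
        assert call.minor_allele == "C"

    def test_unpadded_position_skips_consensus_pads(self):
        aln = make_alignment(
            "c1", "A-CG", [("r1", 0, "A-CG"), ("r2", 0, "A-TG"),
                           ("r3", 0, "A-CG"), ("r4", 0, "A-TG")]
        )
        (call,) = call_snps(aln, LOOSE)
        assert call.padded_column == 2
        assert call.unpadded_position == 1

    def test_matches_brute_force_on_random_alignments(self, rng):
        """Oracle equivalence against an independent per-column recount."""
        for _ in range(60):
            aln = random_alignment(rng, n_columns=50)
            expected = brute_force_calls(aln)
            loose = {c.padded_column for c in call_snps(aln, LOOSE)}
            strict = {c.padded_column for c in call_snps(aln, STRICT)}
            assert loose == {c for c, (l, s) in expected.items() if l}
            assert strict == {c for c, (l, s) in expected.items() if s}

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        counts=st.lists(
            st.tuples(st.sampled_from("ACGTN-"), st.integers(0, 30)),
            min_size=2, max_size=6,
        )
    )
    def test_strict_implies_loose_for_any_column(self, counts):
        """At the defaults a strict call is always also a loose call."""
        chars = "".join(ch * n for ch, n in counts)
        if not chars:
            return
        aln = column_alignment("c1", chars, consensus_base="A")
        for call in call_snps(aln, STRICT):
            assert call.passes_loose


class TestClassifySubstitution:
    def test_all_unordered_pairs(self):
        classes = {
            pair: classify_substitution(*pair)
            for pair in combinations("ACGT", 2)
        }
        transitions = [p for p, c in classes.items() if c == TRANSITION]
        assert sorted(transitions) == [("A", "G"), ("C", "T")]
        assert sum(1 for c in classes.values() if c == TRANSVERSION) == 4

    def test_invalid_input_raises(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("A", "N")


class TestVariantRegions:
    def _two_site_alignment(self, gap_cols):
        """Haplotypes A...C vs G...T on 3 reads each, planted sites separated
        by ``gap_cols`` monomorphic columns."""
        mid = "A" * gap_cols
        h1, h2 = "A" + mid + "C", "G" + mid + "T"
        cons = h1
        reads = [(f"a{i}", 0, h1) for i in range(3)] + [
            (f"b{i}", 0, h2) for i in range(3)
        ]
        return make_alignment("c1", cons, reads)

    def test_two_sites_within_gap_form_region(self):
        aln = self._two_site_alignment(5)
        (region,) = detect_variant_regions(aln)
        assert (region.start, region.end) == (0, 6)
        assert region.length == 7
        assert region.n_variants == 2
        assert sorted(region.support.values()) == [3, 3]

    def test_gap_beyond_limit_splits_into_excluded_singletons(self):
        aln = self._two_site_alignment(12)
        assert detect_variant_regions(aln) == []

    def test_monomorphic_contig_empty(self):
        aln = make_alignment("c1", "ACGT", [("r1", 0, "ACGT"), ("r2", 0, "ACGT")])
        assert detect_variant_regions(aln) == []

    def test_gap_allele_counts_as_state(self):
        h1, h2 = "ACTA", "A-GA"
        reads = [(f"a{i}", 0, h1) for i in range(2)] + [
            (f"b{i}", 0, h2) for i in range(2)
        ]
        aln = make_alignment("c1", h1, reads)
        (region,) = detect_variant_regions(aln)
        assert (region.start, region.end) == (1, 2)
        assert region.n_variants == 2

    def test_partial_reads_ignored_for_haplotype_support(self):
        h1, h2 = "ACA", "GCT"
        reads = [(f"a{i}", 0, h1) for i in range(2)] + [
            (f"b{i}", 0, h2) for i in range(2)
        ] + [("p1", 0, "AC"), ("p2", 0, "AC")]  # do not span the region
        aln = make_alignment("c1", h1, reads)
        (region,) = detect_variant_regions(aln)
        assert region.n_variants == 2
        assert set(region.support) == {"ACA", "GCT"}


class TestRateSummaries:
    def test_rate_from_calls(self):
        aln = column_alignment("c1", "AAAACCCC", consensus_base="A")
        calls = call_snps(aln, STRICT)
        summ = snp_rate_summary([aln], calls)
        assert summ.n_snps == 1
        assert summ.bp_in_contigs_with_snps == 1
        assert summ.transitions + summ.transversions == summ.n_snps

    def test_no_snps_rate_undefined(self):
        aln = column_alignment("c1", "AAAA", consensus_base="A")
        summ = snp_rate_summary([aln], [])
        assert summ.n_snps == 0
        assert summ.n_contigs_with_snps == 0
        assert summ.snps_per_kb is None

    def test_denominator_only_counts_contigs_with_snps(self):
        poly = column_alignment("c1", "AAAACCCC", consensus_base="A")
        mono = make_alignment("c2", "A" * 500, [("r1", 0, "A" * 500)])
        calls = call_snps(poly, STRICT)
        summ = snp_rate_summary([poly, mono], calls)
        assert summ.bp_in_contigs_with_snps == 1

    def test_per_kb_requires_positive_denominator(self):
        with pytest.raises(ValueError):
            per_kb(1, 0)


class TestOutput:
    def test_tsv_and_vcf(self, tmp_path):
        aln = column_alignment("c1", "AAAAACCC", consensus_base="A")
        calls = call_snps(aln, STRICT)
        tsv, vcf = tmp_path / "s.tsv", tmp_path / "s.vcf"
        write_snp_tsv(calls, tsv)
        write_vcf(calls, vcf)
        lines = tsv.read_text().splitlines()
        assert lines[1].split("\t")[:4] == ["c1", "0", "A", "C"]
        vcf_lines = [l for l in vcf.read_text().splitlines()
                     if not l.startswith("#")]
        chrom, pos, _, ref, alt = vcf_lines[0].split("\t")[:5]
        # 0-based internal position surfaces 1-based in VCF
        assert (chrom, pos, ref, alt) == ("c1", "1", "A", "C")
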