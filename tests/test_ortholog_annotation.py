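"""Hit parsing, best hits, ortholog hit ratios, SNP coding classification."""

import pytest

from estpop.assembly_model import FormatError
from estpop.ortholog_annotation import (
    NON_SYNONYMOUS,
    NONCODING,
    SYNONYMOUS,
    UNASSIGNED,
    CodingRegion,
    HitRecord,
    annotate_calls,
    best_hit,
    classify_snp,
    ohr_by_stratum,
    ortholog_hit_ratio,
    putative_coding_region,
    read_hits,
    species_hit_profiles,
    venn_composition,
    venn_counts,
    write_hits,
)
from estpop.snp_caller import SnpCall


def make_hit(
    query_id="q1",
    subject_id="s1",
    e_value=1e-10,
    bit_score=100.0,
    query_start=1,
    query_end=300,
    subject_start=1,
    subject_end=100,
    frame=1,
    query_length=300,
    subject_length=100,
    q_row="M" * 100,
    s_row="M" * 100,
    db="bmori",
):
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        database_label=db,
        e_value=e_value,
        bit_score=bit_score,
        query_start=query_start,
        query_end=query_end,
        subject_start=subject_start,
        subject_end=subject_end,
        frame=frame,
        query_length=query_length,
        subject_length=subject_length,
        aligned_query_string=q_row,
        aligned_subject_string=s_row,
    )


def make_snp(contig_id, position, major, minor):
    return SnpCall(
        contig_id=contig_id,
        padded_column=position,
        unpadded_position=position,
        consensus_base=major,
        allele_counts={major: 5, minor: 3},
        major_allele=major,
        minor_allele=minor,
        coverage=8,
        passes_loose=True,
        passes_strict=True,
        substitution_class="transition",
    )


class TestHitIO:
    def test_round_trip(self, tmp_path):
        hits = [make_hit(), make_hit(query_id="q2", frame=-2,
                                     query_start=305, query_end=6)]
        p = tmp_path / "hits.tsv"
        write_hits(hits, p)
        assert read_hits(p) == hits

    def test_unequal_rows_raise(self):
        with pytest.raises(FormatError, match="unequal"):
            make_hit(q_row="M" * 100, s_row="M" * 99)

    def test_column_count_mismatch_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        write_hits([make_hit()], p)
        p.write_text(p.read_text() + "q2\ts2\tonly_three\n")
        with pytest.raises(FormatError, match=":3"):
            read_hits(p)

    def test_row_residue_count_must_match_coordinates(self):
        with pytest.raises(FormatError, match="residues"):
            make_hit(q_row="M" * 99 + "-", s_row="M" * 100)


class TestBestHit:
    def test_lowest_evalue_wins(self):
        hits = [make_hit(subject_id="a", e_value=1e-10),
                make_hit(subject_id="b", e_value=1e-8)]
        assert {h.subject_id for h in best_hit(hits)} == {"a"}

    def test_cutoff_discards_everything(self):
        assert best_hit([make_hit(e_value=1e-4)]) is None

    def test_tie_broken_by_bit_score(self):
        hits = [make_hit(subject_id="a", e_value=1e-10, bit_score=50),
                make_hit(subject_id="b", e_value=1e-10, bit_score=60)]
        assert best_hit(hits)[0].subject_id == "b"

    def test_returns_all_hsps_of_best_subject(self):
        hits = [
            make_hit(subject_id="a", e_value=1e-10),
            make_hit(subject_id="a", e_value=1e-7, query_start=301,
                     query_end=600, query_length=600),
            make_hit(subject_id="b", e_value=1e-8),
        ]
        assert len(best_hit(hits)) == 2


class TestOrthologHitRatio:
    def test_full_coverage_gapless_is_exactly_one(self):
        ann = ortholog_hit_ratio([make_hit()])
        assert ann.ortholog_hit_ratio == 1.0
        assert ann.non_gap_query_residues == 100
        assert ann.hit_intervals == [(0, 300)]

    def test_query_gaps_reduce_ratio(self):
        # 90 query residues + 10 query gaps against a 100-residue subject
        q_row = "M" * 45 + "-" * 10 + "M" * 45
        ann = ortholog_hit_ratio(
            [make_hit(query_start=1, query_end=270, q_row=q_row,
                      s_row="M" * 100, query_length=270)]
        )
        assert ann.ortholog_hit_ratio == pytest.approx(0.9)

    def test_disjoint_hsps_union(self):
        h1 = make_hit(query_start=1, query_end=90, subject_start=1,
                      subject_end=30, q_row="M" * 30, s_row="M" * 30)
        h2 = make_hit(query_start=151, query_end=210, subject_start=60,
                      subject_end=79, q_row="M" * 20, s_row="M" * 20)
        ann = ortholog_hit_ratio([h1, h2])
        assert ann.ortholog_hit_ratio == pytest.approx(0.5)

    def test_duplicated_hsp_is_idempotent(self):
        h = make_hit()
        assert (
            ortholog_hit_ratio([h, h]).ortholog_hit_ratio
            == ortholog_hit_ratio([h]).ortholog_hit_ratio
        )

    def test_ratio_above_one_permitted(self):
        # insertions in the unigene: more aligned query codons than subject
        h1 = make_hit(query_start=1, query_end=300)
        h2 = make_hit(query_start=301, query_end=390, subject_start=1,
                      subject_end=30, q_row="M" * 30, s_row="M" * 30,
                      query_length=390)
        ann = ortholog_hit_ratio([h1, h2])
        assert ann.ortholog_hit_ratio == pytest.approx(1.3)

    def test_zero_subject_length_raises(self):
        h = make_hit()
        h.subject_length = 0
        with pytest.raises(ValueError):
            ortholog_hit_ratio([h])


class TestPutativeCodingRegion:
    def test_forward_frame_interval_and_length(self):
        h = make_hit(query_start=10, query_end=309, query_length=400)
        region = putative_coding_region(ortholog_hit_ratio([h]))
        assert region.intervals == [(9, 309)]
        assert region.length == 300
        assert region.frame == 1

    def test_reverse_frame_preserved(self):
        # frame -2 on a 400 nt query: alignment runs 399..100 on plus strand
        h = make_hit(query_start=399, query_end=100, frame=-2,
                     query_length=400)
        region = putative_coding_region(ortholog_hit_ratio([h]))
        assert region.frame == -2
        assert region.intervals == [(99, 399)]

    def test_conflicting_frames_keep_longest_and_flag(self):
        h1 = make_hit(query_start=1, query_end=300)
        h2 = make_hit(query_start=302, query_end=331, frame=2,
                      subject_start=1, subject_end=10, q_row="M" * 10,
                      s_row="M" * 10, query_length=400)
        region = putative_coding_region(ortholog_hit_ratio([h1, h2]))
        assert region.frame == 1 and region.frame_conflict


class TestClassifySnp:
    REGION = CodingRegion("q1", [(9, 309)], frame=1, length=300)

    def _seq(self, codons):
        return "T" * 9 + codons + "T" * (309 - 9 - len(codons))

    def test_fourfold_site_synonymous(self):
        seq = self._seq("GGA")
        snp = make_snp("q1", 11, "A", "G")  # GGA -> GGG, both Gly
        assert classify_snp(snp, self.REGION, seq) == SYNONYMOUS

    def test_met_to_ile_non_synonymous(self):
        seq = self._seq("ATG")
        snp = make_snp("q1", 11, "G", "A")  # ATG -> ATA
        assert classify_snp(snp, self.REGION, seq) == NON_SYNONYMOUS

    def test_outside_region_noncoding(self):
        snp = make_snp("q1", 3, "A", "G")
        assert classify_snp(snp, self.REGION, "T" * 309) == NONCODING

    def test_no_annotation_unassigned(self):
        snp = make_snp("q1", 3, "A", "G")
        assert classify_snp(snp, None, "T" * 309) == UNASSIGNED

    def test_reverse_frame_uses_reverse_complement(self):
        # plus-strand CAT at 9..12 reads ATG on the minus strand;
        # C->T (plus) makes TAT -> ATA on minus: Met -> Ile
        region = CodingRegion("q1", [(9, 309)], frame=-1, length=300)
        seq = self._seq("CAT")
        snp = make_snp("q1", 9, "C", "T")
        assert classify_snp(snp, region, seq) == NON_SYNONYMOUS
        # silent on the minus strand: GTA -> GTG is Val either way (plus
        # strand TAC -> CAC at codon position 3 from the region end)
        seq2 = self._seq("TAC")
        snp2 = make_snp("q1", 9, "T", "C")
        # minus codon GTA vs GTG: both Val
        assert classify_snp(snp2, region, seq2) == SYNONYMOUS

    def test_ambiguous_codon_unassigned(self):
        seq = self._seq("GNA")
        snp = make_snp("q1", 9, "G", "A")
        assert classify_snp(snp, self.REGION, seq) == UNASSIGNED

    def test_annotate_calls_fills_classes(self):
        seq = self._seq("GGA")
        calls = [make_snp("q1", 11, "A", "G"), make_snp("q2", 5, "A", "G")]
        annotate_calls(calls, {"q1": self.REGION}, {"q1": seq, "q2": "ACGT"})
        assert calls[0].coding_class == SYNONYMOUS
        assert calls[1].coding_class == UNASSIGNED


class TestSpeciesProfiles:
    def test_flags_and_venn(self):
        dbs = {
            "bmori": {"q1", "q2", "q3"},
            "herato": {"q1", "q4"},
            "dmel": {"q1"},
        }
        profiles = species_hit_profiles(
            ["q1", "q2", "q3", "q4", "q5"], dbs
        )
        by_id = {p.query_id: p for p in profiles}
        assert by_id["q1"].n_databases_hit == 3
        assert by_id["q5"].n_databases_hit == 0
        venn = venn_counts(profiles)
        assert venn[frozenset({"bmori", "herato", "dmel"})] == 1
        assert venn[frozenset({"bmori"})] == 2
        assert venn[frozenset({"herato"})] == 1
        assert sum(venn.values()) == 4  # all queries with >= 1 hit

    def test_composition_splits_by_class_and_coverage(self):
        profiles = species_hit_profiles(
            ["c_hi", "c_lo", "s1"], {"bmori": {"c_hi", "c_lo", "s1"}}
        )
        kinds = {"c_hi": "contig", "c_lo": "contig", "s1": "singleton"}
        covs = {"c_hi": 10.0, "c_lo": 2.0, "s1": 1.0}
        comp = venn_composition(profiles, kinds, covs)
        region = comp[frozenset({"bmori"})]
        assert region == {
            "high_coverage_contig": 1,
            "low_coverage_contig": 1,
            "singleton": 1,
        }


class TestOhrByStratum:
    def _ann(self, q, ratio):
        h = make_hit(query_id=q, query_start=1, query_end=3 * int(100 * ratio),
                     subject_start=1, subject_end=int(100 * ratio),
                     q_row="M" * int(100 * ratio), s_row="M" * int(100 * ratio),
                     query_length=400)
        return ortholog_hit_ratio([h])

    def test_fixture_split_by_coverage(self):
        anns = [self._ann("lo", 0.2), self._ann("hi", 0.6)]
        covs = {"lo": 2.0, "hi": 8.0, "other": 4.0}
        kinds = {"lo": "contig", "hi": "contig", "other": "contig"}
        strata = ohr_by_stratum(anns, covs, kinds)
        assert strata["below_median"] == pytest.approx(0.2)
        assert strata["above_median"] == pytest.approx(0.6)

    def test_singletons_form_own_stratum(self):
        anns = [self._ann("s1", 0.4)]
        strata = ohr_by_stratum(anns, {"s1": 1.0}, {"s1": "singleton"})
        assert strata["singleton"] == pytest.approx(0.4)
        assert strata["below_median"] is None
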