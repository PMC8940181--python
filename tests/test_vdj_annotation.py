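import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrgwas.vdj_annotation import (AnnotationConfig, UnassignableRead,
                                    annotate_read, assign_candidate_genes,
                                    build_allele_groups, allele_group_map,
                                    call_p_nucleotides, classify_productivity,
                                    parsimonious_scenario, revcomp,
                                    _palindromic_extension)
from conftest import (brute_force_min_insertions, brute_force_palindrome,
                      random_read)


class TestAssignCandidates:
    def test_exact_v_plus_j_concatenation(self, mini_germline):
        read = mini_germline["V1*01"].seq + mini_germline["J1*01"].seq
        v, j, d = assign_candidate_genes(read, mini_germline)
        assert v == ["V1*01"]
        assert j == ["J1*01"]
        assert d == []

    def test_designed_ambiguous_pair_both_returned(self, germline):
        read = germline["TRBV09*01"].seq + "ACGTA" + germline["TRBJ2-1*01"].seq
        v, _, _ = assign_candidate_genes(read, germline)
        assert v == ["TRBV09*01", "TRBV09*02"]

    def test_random_read_unassignable(self, mini_germline):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=60))
        with pytest.raises(UnassignableRead):
            assign_candidate_genes(read, mini_germline)

    def test_short_read_rejected(self, mini_germline):
        with pytest.raises(UnassignableRead):
            assign_candidate_genes("ACGT", mini_germline)


class TestParsimony:
    def test_exact_vdj_concatenation_all_zero(self, mini_germline):
        v, d, j = (mini_germline["V1*01"], mini_germline["D1*01"],
                   mini_germline["J1*01"])
        read = v.seq + d.seq + j.seq
        scen = parsimonious_scenario(read, "V1*01", "J1*01",
                                     ["D1*01", "D2*01"], mini_germline)
        assert scen.d_allele == "D1*01"
        assert (scen.v_trim, scen.d5_trim, scen.d3_trim, scen.j_trim) == (0, 0, 0, 0)
        assert scen.total_insertions == 0

    def test_d_beats_pure_insertion(self, mini_germline):
        # junction CCGGG: D1 starts GGG -> n_vd=2, n_dj=0 beats 5 insertions
        v, j = mini_germline["V1*01"], mini_germline["J1*01"]
        read = v.seq + "CCGGG" + j.seq
        scen = parsimonious_scenario(read, "V1*01", "J1*01",
                                     ["D1*01", "D2*01"], mini_germline)
        assert scen.d_allele == "D1*01"
        assert scen.total_insertions == 2
        assert (scen.n_vd, scen.n_dj) == (2, 0)
        assert scen.insert_vd == "CC"
        assert scen.d5_trim == 0 and scen.d3_trim == 9

    def test_short_d_reported_as_vj_insertion(self, mini_germline):
        v, j = mini_germline["V2*01"], mini_germline["J2*01"]
        read = v.seq + "CA" + j.seq  # no >= 3 nt D segment fits, even
        # allowing anchor retraction at the V/J boundaries
        scen = parsimonious_scenario(read, "V2*01", "J2*01",
                                     ["D1*01", "D2*01"], mini_germline)
        assert scen.d_allele is None
        assert scen.n_vj == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_batch(self, germline, seed):
        rng = np.random.default_rng(seed)
        d_seqs = [a.seq for a in germline.by_type("D")]
        d_names = [a.name for a in germline.by_type("D")]
        for _ in range(60):
            read = random_read(rng, germline)
            try:
                v, j, _ = assign_candidate_genes(read, germline)
            except UnassignableRead:
                continue
            scen = parsimonious_scenario(read, v[0], j[0], d_names, germline)
            oracle = brute_force_min_insertions(
                read, germline[v[0]].seq, germline[j[0]].seq, d_seqs)
            assert scen.total_insertions == oracle

    @pytest.mark.parametrize("seed", range(3))
    def test_reconstruction_invariant(self, germline, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(60):
            read = random_read(rng, germline)
            scen = annotate_read(read, germline)
            if scen is None:
                continue
            v = germline[scen.v_allele]
            j = germline[scen.j_allele]
            v_part = v.seq[scen.v_match_start:
                           scen.v_match_start + scen.v_match_len]
            j_part = j.seq[scen.j_match_start:
                           scen.j_match_start + scen.j_match_len]
            if scen.d_allele is None:
                middle = scen.insert_vj
            else:
                d = germline[scen.d_allele]
                middle = (scen.insert_vd
                          + d.seq[scen.d5_trim:len(d.seq) - scen.d3_trim]
                          + scen.insert_dj)
            assert v_part + middle + j_part == read
            # trims never exceed segment lengths
            assert 0 <= scen.v_trim <= len(v.seq)
            assert 0 <= scen.j_trim <= len(j.seq)


class TestPNucleotides:
    def test_worked_example_p_v_2(self, mini_germline):
        # V1 ends ...CA, untrimmed; insert begins TG = revcomp(CA)
        v, j = mini_germline["V1*01"], mini_germline["J2*01"]
        read = v.seq + "TG" + j.seq
        scen = parsimonious_scenario(read, "V1*01", "J2*01", [], mini_germline)
        scen = call_p_nucleotides(scen, mini_germline)
        assert scen.v_trim == 0
        assert scen.p_v == 2

    def test_trimmed_end_gets_zero(self, mini_germline):
        v, j = mini_germline["V1*01"], mini_germline["J2*01"]
        # insert chosen so no base coincides with the trimmed V terminus
        read = v.seq[:-3] + "GCAGC" + j.seq
        scen = parsimonious_scenario(read, "V1*01", "J2*01", [], mini_germline)
        assert scen.v_trim == 3
        scen = call_p_nucleotides(scen, mini_germline)
        assert scen.p_v == 0

    def test_cap_respected(self, mini_germline):
        v, j = mini_germline["V1*01"], mini_germline["J2*01"]
        read = v.seq + "TGA" + j.seq  # TGA extends revcomp(TCA) fully
        scen = parsimonious_scenario(read, "V1*01", "J2*01", [], mini_germline)
        full = call_p_nucleotides(scen, mini_germline)
        capped = call_p_nucleotides(scen, mini_germline, cap=2)
        assert full.p_v == 3
        assert capped.p_v == 2

    @given(gene_end=st.text("ACGT", min_size=1, max_size=12),
           insert=st.text("ACGT", min_size=0, max_size=8),
           side=st.sampled_from(["after", "before"]))
    @settings(max_examples=150, deadline=None)
    def test_palindrome_oracle(self, gene_end, insert, side):
        assert (_palindromic_extension(gene_end, insert, side, None)
                == brute_force_palindrome(gene_end, insert, side))

    def test_p_implies_untrimmed(self, annotated_tables):
        for t in annotated_tables[:5]:
            df = t.df
            assert (df.loc[df["p_v"] > 0, "v_trim"] == 0).all()
            assert (df.loc[df["p_j"] > 0, "j_trim"] == 0).all()
            assert (df.loc[df["p_d5"] > 0, "d5_trim"] == 0).all()
            assert (df.loc[df["p_d3"] > 0, "d3_trim"] == 0).all()


class TestProductivity:
    def _scen(self, read, germline, v="V1*01", j="J1*01"):
        return parsimonious_scenario(read, v, j, [], germline)

    def test_in_frame_no_stop_productive(self, mini_germline):
        v, j = mini_germline["V1*01"], mini_germline["J1*01"]
        read = v.seq + "GCT" + j.seq  # junction of 3 keeps frame
        scen = self._scen(read, mini_germline)
        assert classify_productivity(read, scen, mini_germline) == "productive"

    def test_frame_shift_non_productive(self, mini_germline):
        v, j = mini_germline["V1*01"], mini_germline["J1*01"]
        read = v.seq + "GCTA" + j.seq  # +1 shift
        scen = self._scen(read, mini_germline)
        assert classify_productivity(read, scen, mini_germline) == "non_productive"

    def test_in_frame_stop_non_productive(self, mini_germline):
        v, j = mini_germline["V1*01"], mini_germline["J1*01"]
        read = v.seq + "TAA" + j.seq  # in frame, stop codon in junction
        scen = self._scen(read, mini_germline)
        assert classify_productivity(read, scen, mini_germline) == "non_productive"


class TestAlleleGroups:
    def test_identical_span_same_gene_merges(self, germline):
        groups = build_allele_groups(germline)
        by_type = {}
        for g in groups:
            by_type.setdefault(g.gene_type, []).append(g)
        # 12 V alleles but TRBV09*01/*02 share a sequence: 11 groups
        assert len(by_type["V"]) == 11
        assert len(by_type["D"]) == 3
        assert len(by_type["J"]) == 6
        v9 = [g for g in by_type["V"] if g.gene == "TRBV09"]
        assert len(v9) == 1 and v9[0].members == ("TRBV09*01", "TRBV09*02")

    def test_identical_span_different_genes_stay_apart(self):
        from tcrgwas.io_formats import GermlineAllele, GermlineReference
        seq = "ATGGCTGGTCATCTGGAACGTATTACTTCA"
        ref = GermlineReference([
            GermlineAllele("VA*01", "VA", "V", seq, 0),
            GermlineAllele("VB*01", "VB", "V", seq, 0),
        ])
        assert len(build_allele_groups(ref)) == 2

    def test_partition(self, germline):
        groups = build_allele_groups(germline)
        members = [m for g in groups for m in g.members]
        assert sorted(members) == sorted(a.name for a in germline)

    def test_observed_span_restriction_merges_more(self):
        from tcrgwas.io_formats import GermlineAllele, GermlineReference
        # differ only in the first 6 nt (upstream of a 24 nt observed span)
        a = "ATGGCTGGTCATCTGGAACGTATTACTTCA"
        b = "GGTTCC" + a[6:]
        ref = GermlineReference([
            GermlineAllele("VX*01", "VX", "V", a, 0),
            GermlineAllele("VX*02", "VX", "V", b, 0),
        ])
        assert len(build_allele_groups(ref)) == 2
        assert len(build_allele_groups(ref, observed_span=24)) == 1


class TestZeroNoiseRecovery:
    def test_exact_concatenations_recovered(self, germline):
        gmap = allele_group_map(build_allele_groups(germline))
        for v in germline.by_type("V")[:4]:
            for d in germline.by_type("D"):
                for j in germline.by_type("J")[:3]:
                    read = v.seq + d.seq + j.seq
                    scen = annotate_read(read, germline, group_of=gmap)
                    assert scen is not None
                    assert gmap[scen.v_allele] == gmap[v.name]
                    assert scen.j_allele == j.name
                    assert scen.d_allele == d.name
                    assert scen.total_insertions == 0
                    assert scen.total_trims == 0

    def test_zero_noise_cohort_round_trip(self, germline):
        from tcrgwas.synthetic import CohortConfig, simulate_cohort
        cfg = CohortConfig(n_subjects=4, n_snps=20, n_reads=60, planted=(),
                           zero_noise=True, target_productive_fraction=None)
        cohort = simulate_cohort(cfg, seed=5)
        from tcrgwas.vdj_annotation import annotate_repertoire
        for rep in cohort.repertoires:
            ann = annotate_repertoire(rep, germline)
            # zero noise: no read dropped, order preserved
            assert len(ann.df) == len(rep.df)
            assert (ann.df["sequence"].values == rep.df["sequence"].values).all()
            for col in ("v_trim", "j_trim", "n_vd", "n_dj",
                        "d5_trim", "d3_trim"):
                np.testing.assert_array_equal(ann.df[col].values,
                                              rep.df[col].values)
            assert (ann.df["v_group"].values == rep.df["v_group"].values).all()
            assert (ann.df["productive"].values
                    == rep.df["productive"].values).all()


def test_revcomp():
    assert revcomp("CA") == "TG"
    assert revcomp("ACGT") == "ACGT"
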