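"""Similarity metrics, haplotype construction, and match assignment."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svcompare.editdist import edit_distance
from svcompare.matching import (MatchParams, SequenceComparisonError,
                                assign_multi, assign_single_best, build_haplotypes,
                                build_match, match_matrix, reciprocal_overlap,
                                reference_distance_ok, sequence_similarity,
                                size_similarity)
from svcompare.variants import make_record

from _oracles import best_matching_enum, levenshtein_dp
from conftest import simple_record

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


def del_at(start0, end0, contig="ctg1", source="base"):
    """DEL whose internal span is [start0, end0) (anchor at start0-1)."""
    size = end0 - start0
    return simple_record(contig=contig, pos=start0 - 1, svtype="DEL",
                         size=size, source=source)


class TestReferenceDistance:
    def test_within(self):
        assert reference_distance_ok(del_at(100, 200), del_at(650, 750), 500)

    def test_just_outside_strict(self):
        assert not reference_distance_ok(del_at(100, 200), del_at(701, 800), 500)

    def test_identical_zero_refdist(self):
        a = del_at(100, 200)
        assert reference_distance_ok(a, del_at(100, 200), 0)

    def test_different_contigs_false(self):
        assert not reference_distance_ok(
            del_at(100, 200), del_at(100, 200, contig="ctg2"), 500)

    def test_ins_anchor_span_never_degenerate(self):
        # anchor-base convention gives INS a 1-bp span, so two insertions at
        # the same position pass the strict inequality even at refdist=0
        a = simple_record(pos=100, svtype="INS", size=50)
        b = simple_record(pos=100, svtype="INS", size=60)
        assert reference_distance_ok(a, b, 0)


class TestReciprocalOverlap:
    def test_identical(self):
        assert reciprocal_overlap(del_at(100, 200), del_at(100, 200)) == 1.0

    def test_half(self):
        assert reciprocal_overlap(del_at(100, 200), del_at(150, 250)) == 0.5

    def test_disjoint(self):
        assert reciprocal_overlap(del_at(100, 200), del_at(300, 400)) == 0.0

    def test_ins_expansion_by_half_length(self):
        # two 200-bp INS 150 bp apart: expanded spans [pos-100, pos+101)
        a = simple_record(pos=1000, svtype="INS", size=200)
        b = simple_record(pos=1150, svtype="INS", size=200)
        got = reciprocal_overlap(a, b)
        # spans [900,1101) and [1050,1251): overlap 51 / span 201
        assert got == pytest.approx(51 / 201)
        # without expansion the 1-bp anchors would not overlap at all
        assert reciprocal_overlap(del_at(1000, 1001), del_at(1150, 1151)) == 0.0


class TestSizeSimilarity:
    @pytest.mark.parametrize("l1,l2,expected", [
        (500, 500, 1.0),
        (538, 580, 538 / 580),   # ~0.9276
        (50, 100, 0.5),
    ])
    def test_values(self, l1, l2, expected):
        a = simple_record(svtype="INS", size=l1)
        b = simple_record(svtype="INS", size=l2)
        assert size_similarity(a, b) == pytest.approx(expected)


class TestHaplotypes:
    REF = {"ctg1": "ACGTACGTACGTACGTACGTACGTACGTACGT"}

    def test_identical_records(self):
        a = make_record("ctg1", 4, "A", "ATTTT")
        b = make_record("ctg1", 4, "A", "ATTTT")
        h1, h2 = build_haplotypes(a, b, self.REF)
        assert h1 == h2

    def test_same_anchor_substitution(self):
        a = make_record("ctg1", 4, "A", "AAAC")
        b = make_record("ctg1", 4, "A", "AAAG")
        h1, h2 = build_haplotypes(a, b, self.REF)
        assert len(h1) == len(h2)
        assert sum(x != y for x, y in zip(h1, h2)) == 1

    def test_window_construction(self):
        # S1 < S2: H1 begins with A1, H2 begins with ref[S1:S2]
        a = make_record("ctg1", 4, "A", "ATTT")    # span [4,5)
        b = make_record("ctg1", 8, "A", "AGGG")    # span [8,9)
        h1, h2 = build_haplotypes(a, b, self.REF)
        assert h1.startswith("ATTT")
        assert h2.startswith(self.REF["ctg1"][4:8])

    def test_symbolic_raises(self):
        sym = make_record("ctg1", 4, "A", "<INS>", info_svlen=100)
        res = make_record("ctg1", 4, "A", "ATTT")
        with pytest.raises(SequenceComparisonError):
            build_haplotypes(sym, res, self.REF)


class TestSequenceSimilarity:
    def test_printed_examples(self):
        # seqsim = 1 - ed/(|H1|+|H2|) on fixed haplotype pairs
        assert 1 - levenshtein_dp("AAAA", "AAAT") / 8 == 0.875
        assert 1 - levenshtein_dp("ACGT", "TGCA") / 8 == 0.5

    def test_identical_deletions_score_one(self):
        ref = {"ctg1": "A" * 10 + "CGTGACGTTA" * 20 + "A" * 10}
        a = make_record("ctg1", 20, "G" + ref["ctg1"][21:101], "G")
        b = make_record("ctg1", 20, "G" + ref["ctg1"][21:101], "G")
        assert sequence_similarity(a, b, ref) == 1.0

    def test_matches_dp_oracle_on_random_insertions(self, rng):
        ref = {"ctg1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])}
        for _ in range(50):
            p1, p2 = sorted(rng.integers(50, 450, size=2))
            s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 80))])
            s2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 80))])
            a = make_record("ctg1", int(p1), ref["ctg1"][p1], ref["ctg1"][p1] + s1)
            b = make_record("ctg1", int(p2), ref["ctg1"][p2], ref["ctg1"][p2] + s2)
            h1, h2 = build_haplotypes(a, b, ref)
            expected = max(0.0, 1 - levenshtein_dp(h1, h2) / (len(h1) + len(h2)))
            assert sequence_similarity(a, b, ref) == pytest.approx(expected)

    @given(DNA, DNA)
    def test_edit_distance_equals_dp(self, s1, s2):
        assert edit_distance(s1, s2) == levenshtein_dp(s1, s2)


def ins_pair(ref, pos1, pos2, seq1, seq2):
    a = make_record("ctg1", pos1, ref["ctg1"][pos1], ref["ctg1"][pos1] + seq1,
                    source="base")
    b = make_record("ctg1", pos2, ref["ctg1"][pos2], ref["ctg1"][pos2] + seq2,
                    source="comp")
    return a, b


class TestBuildMatch:
    REF = {"ctg1": "ACGT" * 300}

    def test_identical_strictest_thresholds(self):
        a, b = ins_pair(self.REF, 100, 100, "TTTGGG" * 20, "TTTGGG" * 20)
        m = build_match(a, b, MatchParams(pctseq=1.0, pctsize=1.0, pctovl=1.0,
                                          refdist=0), self.REF)
        assert m.state
        assert m.truscore == 100.0
        assert (m.start_distance, m.end_distance) == (0, 0)

    def test_typematch_veto(self):
        ins = simple_record(pos=100, svtype="INS", size=100, source="base")
        del_ = simple_record(pos=100, svtype="DEL", size=100, source="comp")
        m = build_match(ins, del_, MatchParams(pctseq=0), None)
        assert not m.state and not m.type_match

    def test_truscore_is_mean_of_fractions(self):
        a, b = ins_pair(self.REF, 100, 110, "A" * 100, "A" * 90)
        m = build_match(a, b, MatchParams(), self.REF)
        assert m.truscore == pytest.approx(
            100 * (m.recovl + m.sizesim + m.seqsim) / 3)

    def test_pctseq_zero_skips_sequence(self):
        sym = make_record("ctg1", 100, "A", "<INS>", info_svlen=100, source="base")
        sym2 = make_record("ctg1", 105, "A", "<INS>", info_svlen=100, source="comp")
        m = build_match(sym, sym2, MatchParams(pctseq=0), None)
        assert m.state and m.seqsim is None
        assert m.truscore == pytest.approx(100 * (m.recovl + m.sizesim) / 2)

    def test_symbolic_with_pctseq_raises(self):
        sym = make_record("ctg1", 100, "A", "<INS>", info_svlen=100)
        res = make_record("ctg1", 100, "A", "A" + "T" * 100)
        with pytest.raises(SequenceComparisonError):
            build_match(sym, res, MatchParams(), self.REF)

    def test_signed_breakpoint_distances(self):
        a, b = ins_pair(self.REF, 120, 100, "T" * 50, "T" * 50)
        m = build_match(a, b, MatchParams(pctseq=0), None)
        assert m.start_distance == 20 and m.end_distance == 20

    @given(st.integers(0, 1000), st.integers(0, 1000),
           st.integers(50, 400), st.integers(50, 400))
    def test_metric_symmetry_and_bounds(self, p1, p2, l1, l2):
        a = simple_record(pos=p1, svtype="INS", size=l1, source="base")
        b = simple_record(pos=p2, svtype="INS", size=l2, source="comp")
        assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)
        assert size_similarity(a, b) == size_similarity(b, a)
        assert 0 <= reciprocal_overlap(a, b) <= 1
        assert 0 <= size_similarity(a, b) <= 1

    def test_seqsim_symmetry(self, rng):
        for _ in range(20):
            p1, p2 = rng.integers(100, 1000, size=2)
            s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            s2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            a, b = ins_pair(self.REF, int(p1), int(p2), s1, s2)
            assert sequence_similarity(a, b, self.REF) == pytest.approx(
                sequence_similarity(b, a, self.REF))

    def test_threshold_monotonicity(self, rng):
        # lowering any threshold never decreases the number of passing pairs
        bases = [simple_record(pos=int(p), svtype="INS", size=int(s), source="base")
                 for p, s in zip(rng.integers(0, 3000, 6), rng.integers(50, 500, 6))]
        comps = [simple_record(pos=int(p), svtype="INS", size=int(s), source="comp")
                 for p, s in zip(rng.integers(0, 3000, 6), rng.integers(50, 500, 6))]
        count = lambda params: sum(
            m.state for m in match_matrix(bases, comps, params, None))
        strict = MatchParams(pctseq=0, pctsize=0.9, pctovl=0.3, refdist=200)
        for loose in (MatchParams(pctseq=0, pctsize=0.5, pctovl=0.3, refdist=200),
                      MatchParams(pctseq=0, pctsize=0.9, pctovl=0.0, refdist=200),
                      MatchParams(pctseq=0, pctsize=0.9, pctovl=0.3, refdist=500)):
            assert count(loose) >= count(strict)


def scored_matrix(scores):
    """Build records plus MatchResults with prescribed TruScores."""
    n = max(r for r, _ in scores) + 1
    m = max(c for _, c in scores) + 1
    bases = [simple_record(pos=100 * (i + 1), svtype="INS", size=100,
                           source="base") for i in range(n)]
    comps = [simple_record(pos=100 * (j + 1), svtype="INS", size=100,
                           source="comp") for j in range(m)]
    results = []
    for i in range(n):
        for j in range(m):
            passing = (i, j) in scores
            res = build_match(bases[i], comps[j], MatchParams(pctseq=0), None,
                              base_idx=i, comp_idx=j)
            res = dataclasses.replace(
                res, state=passing,
                truscore=scores.get((i, j), 0.0))
            results.append(res)
    return results, bases, comps


class TestAssignment:
    def test_single_best_consumes_each_record_once(self):
        matches, bases, comps = scored_matrix({(0, 0): 95.0, (0, 1): 80.0})
        out = assign_single_best(matches, bases, comps)
        assert [(m.base_idx, m.comp_idx) for m in out.tp_pairs] == [(0, 0)]
        assert out.fp_comps == [comps[1]]
        assert not out.fn_bases

    def test_empty_side_all_fn(self):
        matches, bases, comps = scored_matrix({(0, 0): 50.0})
        out = assign_single_best([], bases, [])
        assert out.fn_bases == bases and not out.tp_pairs

    def test_cross_pairs_matched_descending(self):
        matches, bases, comps = scored_matrix({(0, 1): 90.0, (1, 0): 85.0})
        out = assign_single_best(matches, bases, comps)
        assert sorted((m.base_idx, m.comp_idx) for m in out.tp_pairs) == \
            [(0, 1), (1, 0)]

    def test_every_record_classified_once(self, rng):
        for _ in range(30):
            n, m = rng.integers(1, 5, size=2)
            scores = {}
            for i in range(n):
                for j in range(m):
                    if rng.random() < 0.5:
                        scores[(i, j)] = float(rng.random() * 100)
            matches, bases, comps = scored_matrix(
                scores if scores else {(0, 0): 1.0})
            if not scores:
                matches = [dataclasses.replace(matches[0], state=False)] + matches[1:]
            out = assign_single_best(matches, bases, comps)
            assert len(out.tp_pairs) + len(out.fn_bases) == len(bases)
            assert len(out.tp_pairs) + len(out.fp_comps) == len(comps)

    def test_greedy_equals_enumeration_oracle(self, rng):
        # distinct scores => greedy == lexicographically best matching
        for _ in range(100):
            n, m = rng.integers(1, 5, size=2)
            cells = [(i, j) for i in range(n) for j in range(m)
                     if rng.random() < 0.6]
            scores = dict(zip(cells, rng.permutation(len(cells) * 2)[:len(cells)].astype(float)))
            if not scores:
                continue
            matches, bases, comps = scored_matrix(scores)
            got = sorted((p.base_idx, p.comp_idx)
                         for p in assign_single_best(matches, bases, comps).tp_pairs)
            assert got == best_matching_enum(scores)

    def test_multi_one_base_three_comps(self):
        matches, bases, comps = scored_matrix(
            {(0, 0): 90.0, (0, 1): 80.0, (0, 2): 70.0})
        out = assign_multi(matches, bases, comps)
        assert len({p.comp_idx for p in out.tp_pairs}) == 3
        assert len({p.base_idx for p in out.tp_pairs}) == 1
        assert not out.fn_bases and not out.fp_comps

    def test_multi_no_passing_equals_single(self):
        matches, bases, comps = scored_matrix({(0, 0): 90.0})
        matches = [dataclasses.replace(m, state=False) for m in matches]
        single = assign_single_best(matches, bases, comps)
        multi = assign_multi(matches, bases, comps)
        assert single.fn_bases == multi.fn_bases
        assert single.fp_comps == multi.fp_comps

    def test_multi_symmetric_all_passing(self):
        matches, bases, comps = scored_matrix(
            {(0, 0): 90.0, (0, 1): 80.0, (1, 0): 70.0, (1, 1): 60.0})
        out = assign_multi(matches, bases, comps)
        assert not out.fn_bases and not out.fp_comps
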