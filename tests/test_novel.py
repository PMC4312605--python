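"""Genome mapping, hairpin folding and the novel miRNA annotation criteria."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtmir._seq import revcomp
from droughtmir.novel import (GenomeLocus, call_novel,
                              evaluate_hairpin, excise_candidates, fold,
                              map_exact)
from .oracles import best_fold_by_enumeration

SEQ = st.text(alphabet="ACGT", min_size=6, max_size=16)


class TestMapExact:
    GENOME = {"chr1": "T" * 50 + "ACGTGCATGCTAGCTAGCAGT" + "T" * 50}
    TAG = "ACGTGCATGCTAGCTAGCAGT"

    def test_single_plus_strand_locus(self):
        loci = map_exact(self.TAG, self.GENOME)
        assert loci == [GenomeLocus("chr1", 50, 71, "+")]

    def test_reverse_complement_maps_minus(self):
        loci = map_exact(revcomp(self.TAG), self.GENOME)
        assert loci == [GenomeLocus("chr1", 50, 71, "-")]

    def test_single_substitution_maps_nowhere(self):
        assert map_exact("ACGTGCATGCTAGCTAGCAGA", self.GENOME) == []

    @given(st.text(alphabet="ACGT", min_size=200, max_size=400),
           st.text(alphabet="ACGT", min_size=16, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_naive_scan(self, genome, tag):
        expected = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            for i in range(len(genome) - len(tag) + 1):
                if genome[i:i + len(tag)] == query:
                    expected.append((i, strand))
        got = [(l.start, l.strand) for l in map_exact(tag, {"g": genome})]
        assert sorted(got) == sorted(expected)


class TestExcise:
    def test_window_lengths(self):
        genome = {"c": "A" * 100_000}
        locus = GenomeLocus("c", 5000, 5021, "+")
        w1, w2 = excise_candidates(locus, genome)
        assert len(w1.sequence) == 20 + 21 + 200
        assert len(w2.sequence) == 200 + 21 + 20
        assert w1.mature_offset == 20
        assert w2.mature_offset == 200

    def test_clipped_at_contig_start(self):
        genome = {"c": "A" * 1000}
        w1, w2 = excise_candidates(GenomeLocus("c", 5, 26, "+"), genome)
        assert w1.start == 0 and w1.mature_offset == 5
        assert w2.start == 0 and w2.mature_offset == 5

    def test_minus_strand_orientation(self):
        mature = "ACGTGCATGCTAGCTAGCAG"
        genome = {"c": "G" * 300 + revcomp(mature) + "C" * 300}
        locus = map_exact(mature, genome)[0]
        assert locus.strand == "-"
        for cand in excise_candidates(locus, genome):
            assert cand.sequence[cand.mature_offset:
                                 cand.mature_offset + 20] == mature


class TestFold:
    def test_no_complementarity_no_pairs(self):
        s = fold("AAAAAA")
        assert s.pairs == [] and s.dot_bracket == "......"

    def test_gc_stem_with_minimal_loop(self):
        # expected structure computed by exhaustive enumeration: three GC
        # pairs enclosing the four A's
        s = fold("GGGAAAACCC")
        assert s.pairs == [(0, 9), (1, 8), (2, 7)]
        assert s.score == 9 == best_fold_by_enumeration("GGGAAAACCC")

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fold("ACG")

    @given(SEQ)
    @settings(max_examples=150, deadline=None)
    def test_score_equals_enumeration_optimum(self, seq):
        assert fold(seq).score == best_fold_by_enumeration(seq)

    @given(SEQ)
    @settings(max_examples=100, deadline=None)
    def test_structure_validity_invariants(self, seq):
        s = fold(seq)
        seen = set()
        for i, j in s.pairs:
            assert j - i > 3                       # loop constraint
            assert not {i, j} & seen               # each base in <= 1 pair
            seen |= {i, j}
        for (i, j), (k, l) in zip(s.pairs, s.pairs[1:]):
            # sorted pair list: nesting means no partial overlap
            assert k > j or l < j
        assert s.dot_bracket.count("(") == len(s.pairs)

    def test_score_is_structure_score(self):
        s = fold("GGGAAAACCCAAAGGGTTTACCC")
        w = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
             ("G", "T"): 1, ("T", "G"): 1}
        assert s.score == sum(w[(s.sequence[i], s.sequence[j])]
                              for i, j in s.pairs)


def _perfect_precursor(mature_len=22, arm=34, loop=5, seed=0):
    rng = random.Random(seed)
    arm5 = "".join(rng.choice("ACGT") for _ in range(arm))
    prec = arm5 + "".join(rng.choice("ACGT") for _ in range(loop)) + revcomp(arm5)
    return prec, arm5[3:3 + mature_len]


class TestEvaluateHairpin:
    def test_planted_perfect_stem_passes(self):
        prec, mature = _perfect_precursor()
        call = evaluate_hairpin(prec, mature)
        assert call.passed
        assert call.duplex_mismatches == 0
        assert revcomp(call.star[2:])[2:] in prec

    def test_homopolymer_fails_stem_pairing(self):
        call = evaluate_hairpin("A" * 40 + "ACGTGCATGCTAGCTAGCAG" + "A" * 40,
                                "ACGTGCATGCTAGCTAGCAG")
        assert not call.passed

    def test_mature_straddling_loop_fails(self):
        prec, _ = _perfect_precursor(arm=30, loop=6)
        mature = prec[20:42]          # spans the 30..35 loop
        call = evaluate_hairpin(prec, mature)
        assert not call.flags["in_one_arm"]
        assert not call.passed

    def test_mature_length_bounds_enforced(self):
        prec, _ = _perfect_precursor()
        call = evaluate_hairpin(prec, prec[3:22])       # 19 nt
        assert not call.flags["mature_length_ok"]

    def test_missing_mature_errors(self):
        prec, _ = _perfect_precursor()
        with pytest.raises(ValueError):
            evaluate_hairpin(prec, "TTTTTTTTTTTTTTTTTTTT")


class TestCallNovel:
    def test_no_tags_no_calls(self):
        assert call_novel([], {"c": "ACGT" * 100}) == []

    def test_unmappable_tag_no_call(self):
        genome = {"c": "A" * 2000}
        assert call_novel(["ACGTGCATGCTAGCTAGCAG"], genome) == []

    def test_recovers_planted_precursors(self, small_dataset):
        bundle = small_dataset["bundle"]
        novel = bundle.manifest[bundle.manifest["kind"] == "novel"]
        calls = call_novel(list(novel["mature_sequence"]), bundle.genome)
        called = {c.mature for c in calls}
        recovered = sum(seq in called for seq in novel["mature_sequence"])
        assert recovered >= 0.8 * len(novel)

    def test_one_call_per_distinct_mature(self):
        rng = random.Random(5)
        arm5 = "".join(rng.choice("ACGT") for _ in range(34))
        prec = arm5 + "".join(rng.choice("ACGT") for _ in range(5)) \
            + revcomp(arm5)
        mature = arm5[3:25]
        flanks = ["".join(rng.choice("ACGT") for _ in range(300))
                  for _ in range(2)]
        genome = {"c": flanks[0] + prec + flanks[1]}
        calls = call_novel([mature, mature.lower()], genome)
        assert len(calls) == 1
        assert calls[0].passed and calls[0].mature == mature
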