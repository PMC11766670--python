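import pytest

from rnaevo.folding import (FoldParams, basepair_f1, curate, fold_consensus,
                            fold_mfe, project_consensus, select_structure)
from rnaevo.seqio import Alignment, RnaSequence
from rnaevo.structure import SecondaryStructure, parse_dotbracket_string

from _oracles import (bruteforce_fold_optimum, enumerate_nested_structures,
                      random_nested_structure, random_rna)


def _seq(residues, sid="x"):
    return RnaSequence(id=sid, residues=residues)


class TestFoldMfe:
    def test_no_complementary_residues(self):
        s = fold_mfe(_seq("AAAAAA"))
        assert s.pairs == frozenset() and s.score == 0

    def test_canonical_hairpin(self):
        s = fold_mfe(_seq("GGGAAACCC"))
        assert s.pairs == frozenset({(0, 8), (1, 7), (2, 6)})
        assert s.score == 9
        # brute force confirms this is the optimum for the 9-mer
        assert bruteforce_fold_optimum("GGGAAACCC") == 9

    def test_too_short_returns_empty(self):
        s = fold_mfe(_seq("GAAC"))
        assert s.pairs == frozenset() and s.score == 0

    def test_n_never_pairs(self):
        s = fold_mfe(_seq("NNNAAANNN"))
        assert s.pairs == frozenset()

    def test_dp_equals_bruteforce_on_random_short_sequences(self, rng):
        for _ in range(60):
            seq = random_rna(rng, int(rng.integers(12, 17)))
            assert fold_mfe(_seq(seq)).score == bruteforce_fold_optimum(seq)

    def test_min_hairpin_respected(self, rng):
        for _ in range(50):
            seq = random_rna(rng, 30)
            s = fold_mfe(_seq(seq))
            assert all(j - i > 3 for i, j in s.pairs)

    def test_deterministic_dotbracket(self, rng):
        seq = _seq(random_rna(rng, 60))
        assert fold_mfe(seq).dot_bracket() == fold_mfe(seq).dot_bracket()


class TestFoldConsensus:
    def test_single_row_reduces_to_mfe(self):
        row = "GGGAAACCCAAAGGGAAACCC"
        cons, _ = fold_consensus(Alignment(rows=[("a", row)]))
        assert cons.pairs == fold_mfe(_seq(row)).pairs

    def test_covariance_bonus_counts_pair_types(self):
        aln = Alignment(rows=[("a", "GGGAAACCC"), ("b", "CCCAAAGGG")])
        cons, stats = fold_consensus(aln, FoldParams(covariance_bonus=1.0))
        assert cons.pairs == frozenset({(0, 8), (1, 7), (2, 6)})
        # each column pair: 3 (G:C) + 3 (C:G) + bonus * (2 types - 1) = 7
        assert set(stats["score"]) == {7.0}
        assert set(stats["n_pair_types"]) == {2}

    def test_empty_alignment_is_error(self):
        with pytest.raises(ValueError):
            fold_consensus(Alignment(rows=[]))

    def test_gap_rows_penalized(self):
        params = FoldParams(inconsistency_penalty=10.0)
        aln = Alignment(rows=[("a", "GGGAAACCC"), ("b", "---AAACCC")])
        cons, _ = fold_consensus(aln, params)
        assert cons.pairs == frozenset()  # penalty kills every column pair


class TestProjectConsensus:
    def test_gapless_row_isomorphic(self):
        aln = Alignment(rows=[("a", "GGGAAACCC"), ("b", "GGGAAACCC")])
        cons, _ = fold_consensus(aln)
        proj = project_consensus(cons, aln, "a")
        assert proj.pairs == cons.pairs

    def test_gapped_stem_side_dropped(self):
        aln = Alignment(rows=[("a", "GGGAAACCC"), ("b", "---AAACCC")])
        cons = SecondaryStructure(seq_id="c", length=9,
                                  pairs=frozenset({(0, 8), (1, 7), (2, 6)}))
        proj = project_consensus(cons, aln, "b")
        assert proj.pairs == frozenset()
        assert proj.length == 6

    def test_projection_always_valid(self, rng):
        # random gap patterns over a paired consensus never yield crossing
        # pairs (constructor validates nesting)
        base = "GGGGGAAAAACCCCC"
        cons = SecondaryStructure(
            seq_id="c", length=15,
            pairs=frozenset((i, 14 - i) for i in range(5)))
        for _ in range(100):
            chars = [("-" if rng.random() < 0.3 else c) for c in base]
            aln = Alignment(rows=[("r", "".join(chars))])
            project_consensus(cons, aln, "r")  # must not raise


class TestCurate:
    def test_rule1_closes_gc_internal_loop(self):
        #  GG G GG AAA CC C CC : 1x1 loop at (2, 10) with G and C
        seq = _seq("GGGGGAAACCCCC")
        struct = parse_dotbracket_string("((.((...)).))", seq_id="x")
        out = curate(struct, seq)
        assert (2, 10) in out.pairs
        assert out.pairs == struct.pairs | {(2, 10)}

    def test_rule1_ignores_non_gc_loop(self):
        seq = _seq("GGAGGAAACCACC")
        struct = parse_dotbracket_string("((.((...)).))", seq_id="x")
        assert curate(struct, seq).pairs == struct.pairs

    def test_rule2_drops_helix_with_two_noncanonical_pairs(self):
        # helix pairs: (0,8)=G:C, (1,7)=A:A, (2,6)=C:U -> 2 non-canonical
        seq = _seq("GACAAAUAC")
        struct = parse_dotbracket_string("(((...)))", seq_id="x")
        assert curate(struct, seq).pairs == frozenset()

    def test_rule2_keeps_helix_with_one_noncanonical_pair(self):
        # (0,8)=G:C, (1,7)=A:A non-canonical, (2,6)=G:C
        seq = _seq("GAGAAACAC")
        struct = parse_dotbracket_string("(((...)))", seq_id="x")
        assert curate(struct, seq).pairs == struct.pairs

    def test_idempotence_on_random_structures(self, rng):
        for _ in range(100):
            n = int(rng.integers(15, 60))
            seq = _seq(random_rna(rng, n))
            struct = SecondaryStructure(
                seq_id="x", length=n,
                pairs=frozenset(random_nested_structure(rng, n)))
            once = curate(struct, seq)
            twice = curate(once, seq)
            assert once.pairs == twice.pairs


class TestSelectStructure:
    def test_single_candidate(self):
        s = fold_mfe(_seq("GGGAAACCC"))
        assert select_structure([s], None) is s

    def test_reference_compatibility_breaks_score_ties(self):
        ref = SecondaryStructure(seq_id="x", length=10,
                                 pairs=frozenset({(0, 9)}), score=0)
        a = SecondaryStructure(seq_id="x", length=10,
                               pairs=frozenset({(0, 9)}), score=3)
        b = SecondaryStructure(seq_id="x", length=10,
                               pairs=frozenset({(1, 8)}), score=3)
        assert select_structure([b, a], ref) is a

    def test_matches_bruteforce_argmax_on_full_candidate_set(self):
        seq = "GGCAAAAGCC"
        ref = fold_mfe(_seq(seq))
        candidates = []
        for pairs in enumerate_nested_structures(seq):
            score = sum({"GC": 3, "CG": 3, "AU": 2, "UA": 2,
                         "GU": 1, "UG": 1}[seq[i] + seq[j]] for i, j in pairs)
            candidates.append(SecondaryStructure(
                seq_id="x", length=len(seq), pairs=frozenset(pairs),
                score=score))
        chosen = select_structure(candidates, ref)
        best = max(c.score for c in candidates)
        assert chosen.score == best
        best_f1 = max(basepair_f1(c, ref) for c in candidates
                      if c.score == best)
        assert basepair_f1(chosen, ref) == best_f1
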