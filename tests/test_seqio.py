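import pytest

from rnaevo import seqio
from rnaevo.seqio import (Alignment, RnaSequence, SeqIOError, parse_dotbracket,
                          read_fasta, read_newick, read_vienna, render_dotbracket,
                          write_fasta, write_vienna)
from rnaevo.structure import StructureError, parse_dotbracket_string
from rnaevo.synthetic_data import random_yule_tree

from _oracles import random_nested_structure, random_rna


class TestFasta:
    def test_normalization_dna_lowercase(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">x\nacgt\n")
        (seq,) = read_fasta(p)
        assert seq.residues == "ACGU"

    def test_degenerate_codes_collapse_to_n(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">x\nACGRYWU\n")
        (seq,) = read_fasta(p)
        assert seq.residues == "ACGNNNU"

    def test_duplicate_id_is_hard_error(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">x\nACGU\n>x\nGGGG\n")
        with pytest.raises(SeqIOError, match="x"):
            read_fasta(p)

    def test_roundtrip_identity_on_normalized_records(self, tmp_path, rng):
        seqs = [RnaSequence(id=f"s{i}", residues=random_rna(rng, int(rng.integers(1, 300))))
                for i in range(100)]
        p = tmp_path / "out.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == \
               [(s.id, s.residues) for s in seqs]

    def test_write_empty_and_single_residue(self, tmp_path):
        p = tmp_path / "empty.fasta"
        write_fasta([], p)
        assert p.read_text() == ""
        q = tmp_path / "one.fasta"
        write_fasta([RnaSequence(id="a", residues="G")], q)
        assert q.read_text().splitlines() == [">a", "G"]


class TestNewick:
    def test_small_tree_counts(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,b),c);\n")
        tree = read_newick(p)
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 2

    def test_root_trifurcation_preserved(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(a,b,c);\n")
        tree = read_newick(p)
        assert len(tree.seed_node.child_nodes()) == 3

    def test_parse_error_on_unbalanced(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a,b),c;\n")
        with pytest.raises(SeqIOError):
            read_newick(p)

    def test_roundtrip_on_simulated_trees(self, tmp_path):
        for seed in range(50):
            tree = random_yule_tree(n_taxa=int(5 + seed % 10), seed=seed)
            p = tmp_path / f"t{seed}.nwk"
            seqio.write_newick(tree, p)
            back = read_newick(p)
            # identical topology: same tip sets at every internal node
            def clades(t):
                return {frozenset(l.taxon.label for l in n.leaf_iter())
                        for n in t.preorder_node_iter()}
            assert clades(back) == clades(tree)


class TestDotBracket:
    def test_bracket_matching(self):
        seq = RnaSequence(id="x", residues="GGGAAACCC")
        s = parse_dotbracket("(((...)))", seq)
        assert s.pairs == frozenset({(0, 8), (1, 7), (2, 6)})

    def test_all_dots_empty(self):
        seq = RnaSequence(id="x", residues="GGGAAACCC")
        assert parse_dotbracket(".........", seq).pairs == frozenset()

    @pytest.mark.parametrize("db,col", [("())", 2), ("((.", 0)])
    def test_unbalanced_reports_column(self, db, col):
        with pytest.raises(StructureError, match=f"column {col}"):
            parse_dotbracket_string(db)

    def test_length_mismatch(self):
        with pytest.raises(StructureError):
            parse_dotbracket("...", RnaSequence(id="x", residues="ACGU"))

    def test_parse_render_identity_on_random_structures(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 80))
            pairs = random_nested_structure(rng, n)
            seq = RnaSequence(id="r", residues=random_rna(rng, n))
            from rnaevo.structure import SecondaryStructure
            s = SecondaryStructure(seq_id="r", length=n, pairs=frozenset(pairs))
            db = render_dotbracket(s)
            assert parse_dotbracket(db, seq).pairs == s.pairs


class TestViennaAndAlignment:
    def test_vienna_roundtrip(self, tmp_path, rng):
        from rnaevo.structure import SecondaryStructure
        entries = []
        for i in range(5):
            n = int(rng.integers(15, 60))
            seq = RnaSequence(id=f"v{i}", residues=random_rna(rng, n))
            pairs = random_nested_structure(rng, n)
            entries.append((seq, SecondaryStructure(seq_id=seq.id, length=n,
                                                    pairs=frozenset(pairs))))
        p = tmp_path / "s.vienna"
        write_vienna(entries, p)
        back = read_vienna(p)
        assert [(s.id, st.pairs) for s, st in back] == \
               [(s.id, st.pairs) for s, st in entries]

    def test_alignment_invariants(self):
        with pytest.raises(SeqIOError):
            Alignment(rows=[("a", "ACGU"), ("b", "ACG")])
        aln = Alignment(rows=[("a", "AC-U"), ("b", "ACGU")])
        assert aln.ungapped("a").residues == "ACU"
        assert aln.column(2) == ["-", "G"]

    def test_ct_read(self, tmp_path):
        ct = ("9 toy\n"
              "1 G 0 2 9 1\n2 G 1 3 8 2\n3 G 2 4 7 3\n"
              "4 A 3 5 0 4\n5 A 4 6 0 5\n6 A 5 7 0 6\n"
              "7 C 6 8 3 7\n8 C 7 9 2 8\n9 C 8 0 1 9\n")
        p = tmp_path / "toy.ct"
        p.write_text(ct)
        seq, struct = seqio.read_ct(p)
        assert seq.residues == "GGGAAACCC"
        assert struct.pairs == frozenset({(0, 8), (1, 7), (2, 6)})
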