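import numpy as np
import pytest

from phylomask import parsimony_engine as pe
from phylomask.seq_io import SequenceSet, read_newick


def matrix(rows, gap_mode=pe.FIFTH_STATE):
    return pe.encode_matrix(SequenceSet(rows, aligned=True), gap_mode=gap_mode)


QUARTET = read_newick("((a,b),(c,d));")


class TestEncode:
    def test_n_is_any_nucleotide(self):
        m = matrix([("a", "N")])
        assert int(m.masks[0, 0]) == 0b1111

    def test_question_fifth_state_includes_gap(self):
        m = matrix([("a", "?")], gap_mode=pe.FIFTH_STATE)
        assert int(m.masks[0, 0]) == 0b11111
        m2 = matrix([("a", "?")], gap_mode=pe.MISSING)
        assert int(m2.masks[0, 0]) == 0b1111

    def test_iupac_subsets(self):
        m = matrix([("a", "RYSWKM")])
        expected = [0b0101, 0b1010, 0b0110, 0b1001, 0b1100, 0b0011]
        assert list(m.masks[0]) == expected

    def test_unknown_character_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            matrix([("a", "AJ")])


class TestFitchLength:
    def test_single_split_pattern(self):
        assert pe.fitch_length(QUARTET, matrix(
            [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])) == 1

    def test_four_distinct_states(self):
        assert pe.fitch_length(QUARTET, matrix(
            [("a", "A"), ("b", "C"), ("c", "G"), ("d", "T")])) == 3

    def test_ambiguity_resolves(self):
        assert pe.fitch_length(QUARTET, matrix(
            [("a", "A"), ("b", "N"), ("c", "C"), ("d", "C")])) == 1

    def test_gap_as_fifth_state_costs(self):
        rows = [("a", "-"), ("b", "-"), ("c", "A"), ("d", "A")]
        assert pe.fitch_length(QUARTET, matrix(rows, pe.FIFTH_STATE)) == 1
        assert pe.fitch_length(QUARTET, matrix(rows, pe.MISSING)) == 0

    def test_polytomy_refused(self):
        star = read_newick("(a,b,c,d);")
        with pytest.raises(ValueError, match="binary"):
            pe.fitch_length(star, matrix(
                [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")]))

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pe.fitch_length(QUARTET, matrix([("a", "A"), ("b", "A"),
                                             ("c", "C"), ("x", "C")]))

    def test_rooting_invariance(self, random_seqset):
        seqs = random_seqset(11, n_taxa=7, n_sites=20)
        m = pe.encode_matrix(seqs)
        t = pe.wagner_build(m, seed=2)
        base = pe.fitch_length(t, m)
        for leaf in t.leaf_names():
            assert pe.fitch_length(t.rooted_at({leaf}), m) == base

    def test_site_additivity(self, random_seqset):
        s1 = random_seqset(21, n_taxa=6, n_sites=15)
        s2 = random_seqset(22, n_taxa=6, n_sites=11)
        combined = SequenceSet(
            [(n, a + s2.sequence(n)) for n, a in s1], aligned=True
        )
        m1, m2, mc = (pe.encode_matrix(s) for s in (s1, s2, combined))
        t = pe.wagner_build(mc, seed=0)
        assert pe.fitch_length(t, mc) == pe.fitch_length(t, m1) + \
            pe.fitch_length(t, m2)

    @pytest.mark.parametrize("filler", ["N", "?"])
    def test_all_ambiguous_column_is_free(self, random_seqset, filler):
        s1 = random_seqset(31, n_taxa=6, n_sites=10)
        padded = SequenceSet([(n, s + filler) for n, s in s1], aligned=True)
        m1, m2 = pe.encode_matrix(s1), pe.encode_matrix(padded)
        t = pe.wagner_build(m1, seed=5)
        assert pe.fitch_length(t, m1) == pe.fitch_length(t, m2)

    def test_per_site_bounds(self, random_seqset):
        seqs = random_seqset(41, n_taxa=6, n_sites=25)
        m = pe.encode_matrix(seqs)
        t = pe.wagner_build(m, seed=1)
        total = pe.fitch_length(t, m)
        assert 0 <= total <= m.n_sites * (m.n_taxa - 1)

    def test_missing_mode_never_longer(self, random_seqset):
        for seed in range(5):
            seqs = random_seqset(50 + seed, n_taxa=6, n_sites=20)
            mf = pe.encode_matrix(seqs, gap_mode=pe.FIFTH_STATE)
            mm = pe.encode_matrix(seqs, gap_mode=pe.MISSING)
            t = pe.wagner_build(mf, seed=seed)
            assert pe.fitch_length(t, mm) <= pe.fitch_length(t, mf)

    def test_weights_multiply(self):
        rows = [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")]
        m = matrix(rows).with_weights(np.array([7]))
        assert pe.fitch_length(QUARTET, m) == 7


class TestSankoffAgreement:
    def test_matches_fitch_on_random_binary_trees(self, random_seqset):
        for seed in range(20):
            seqs = random_seqset(seed, n_taxa=7, n_sites=12)
            for gm in (pe.FIFTH_STATE, pe.MISSING):
                m = pe.encode_matrix(seqs, gap_mode=gm)
                t = pe.wagner_build(m, seed=seed)
                assert pe.fitch_length(t, m) == pe.sankoff_length(t, m)

    def test_consensus_polytomy_scored(self):
        # on the star the single internal node must be A or C: two changes
        star = read_newick("(a,b,c,d);")
        m = matrix([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        assert pe.sankoff_length(star, m) == 2


class TestWagnerBuild:
    def test_three_taxa_unique_topology(self):
        m = matrix([("a", "ACGT"), ("b", "AGGT"), ("c", "TCGT")])
        t1, t2 = pe.wagner_build(m, seed=0), pe.wagner_build(m, seed=99)
        assert t1.splits(nontrivial_only=False) == t2.splits(
            nontrivial_only=False)

    def test_identical_sequences_zero_length(self):
        m = matrix([(f"t{i}", "ACGT") for i in range(5)])
        t = pe.wagner_build(m, seed=3)
        assert pe.fitch_length(t, m) == 0

    def test_seed_determinism(self, random_seqset):
        m = pe.encode_matrix(random_seqset(8, n_taxa=8))
        assert pe.wagner_build(m, seed=4).newick() == \
            pe.wagner_build(m, seed=4).newick()


class TestSearch:
    def test_heuristic_matches_exhaustive(self, random_seqset):
        for seed in range(8):
            m = pe.encode_matrix(random_seqset(seed, n_taxa=6, n_sites=25))
            ex = pe.exhaustive_search(m)
            hs = pe.heuristic_search(m, builds=3, seed=seed, max_trees=30)
            assert hs.best_length == ex.best_length

    def test_spr_swap_also_reaches_optimum(self, random_seqset):
        for seed in range(4):
            m = pe.encode_matrix(random_seqset(80 + seed, n_taxa=6,
                                               n_sites=25))
            ex = pe.exhaustive_search(m)
            hs = pe.heuristic_search(m, builds=5, swap="SPR", seed=seed)
            assert hs.best_length == ex.best_length

    def test_identical_sequences_collapse_to_star(self):
        m = matrix([(f"t{i}", "ACGT") for i in range(5)])
        res = pe.heuristic_search(m, builds=2, seed=0)
        assert res.best_length == 0
        assert len(res.best_trees) == 1
        assert res.best_trees[0].splits() == set()

    def test_search_determinism(self, random_seqset):
        m = pe.encode_matrix(random_seqset(9, n_taxa=7))
        r1 = pe.heuristic_search(m, builds=4, seed=11)
        r2 = pe.heuristic_search(m, builds=4, seed=11)
        assert r1.best_length == r2.best_length
        assert {t.newick() for t in r1.best_trees} == \
            {t.newick() for t in r2.best_trees}

    def test_exhaustive_counts_all_topologies_for_identical_taxa(self):
        m = matrix([(f"t{i}", "AAAA") for i in range(5)])
        res = pe.exhaustive_search(m, collapse=False)
        assert res.best_length == 0
        assert len(res.best_trees) == 15  # (2*5-5)!!

    def test_exhaustive_refuses_large(self, random_seqset):
        m = pe.encode_matrix(random_seqset(0, n_taxa=10))
        with pytest.raises(ValueError):
            pe.exhaustive_search(m)

    def test_all_reported_trees_have_best_length(self, random_seqset):
        m = pe.encode_matrix(random_seqset(13, n_taxa=6, n_sites=20))
        res = pe.heuristic_search(m, builds=3, seed=7)
        for t in res.best_trees:
            assert pe.sankoff_length(t, m) == res.best_length


class TestStrictConsensus:
    def test_identical_trees(self):
        t = read_newick("((a,b),(c,(d,e)),f);")
        cons = pe.strict_consensus([t, t.copy()])
        assert cons.splits() == t.splits()

    def test_conflicting_quartets_give_star(self):
        cons = pe.strict_consensus(
            [read_newick("((a,b),(c,d));"), read_newick("((a,c),(b,d));")]
        )
        assert cons.splits() == set()

    def test_shared_split_retained(self):
        trees = [read_newick("((x,y),(a,(b,c)));"),
                 read_newick("((x,y),(b,(a,c)));"),
                 read_newick("((x,y),(c,(a,b)));")]
        cons = pe.strict_consensus(trees)
        assert frozenset({"x", "y"}) in cons.splits()
        assert len(cons.splits()) == 1

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pe.strict_consensus([read_newick("((a,b),(c,d));"),
                                 read_newick("((a,b),(c,e));")])

    def test_matches_dendropy(self, random_seqset):
        import dendropy

        m = pe.encode_matrix(random_seqset(17, n_taxa=7, n_sites=12))
        res = pe.heuristic_search(m, builds=3, seed=1, max_trees=20)
        if len(res.best_trees) < 2:
            res = pe.exhaustive_search(m)
        mine = pe.strict_consensus(res.best_trees)
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(
            [dendropy.Tree.get(data=t.newick(), schema="newick",
                               taxon_namespace=tns)
             for t in res.best_trees], taxon_namespace=tns)
        dcons = tl.consensus(min_freq=1.0)
        theirs = read_newick(dcons.as_string(schema="newick"))
        assert mine.splits() == theirs.splits()


class TestBootstrap:
    def test_perfect_clade_full_support(self):
        rows = [("a", "A" * 20), ("b", "A" * 20), ("c", "T" * 20),
                ("d", "T" * 20), ("e", "T" * 20)]
        sup = pe.bootstrap_support(matrix(rows), replicates=20,
                                   builds_per_rep=1, seed=0)
        assert sup[frozenset({"c", "d", "e"})] == 100.0

    def test_support_bounded(self, random_seqset):
        m = pe.encode_matrix(random_seqset(23, n_taxa=6, n_sites=20))
        sup = pe.bootstrap_support(m, replicates=10, builds_per_rep=1, seed=1)
        assert all(0.0 <= v <= 100.0 for v in sup.values())

    def test_seed_determinism(self, random_seqset):
        m = pe.encode_matrix(random_seqset(24, n_taxa=6, n_sites=15))
        s1 = pe.bootstrap_support(m, replicates=8, builds_per_rep=1, seed=5)
        s2 = pe.bootstrap_support(m, replicates=8, builds_per_rep=1, seed=5)
        assert s1 == s2
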