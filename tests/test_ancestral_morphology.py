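import itertools

import numpy as np
import pandas as pd
import pytest

from phylomask import ancestral_morphology as am
from phylomask import parsimony_engine as pe
from phylomask.seq_io import SequenceSet, Tree, read_newick


def rooted_quartet():
    """Quartet with exactly two internal vertices: the root joins a, b and
    the (c,d) cherry."""
    t = read_newick("(a,b,(c,d));")
    t.rooted = True
    return t


def brute_force(tree, char):
    """Exhaustive enumeration over 5^(internal nodes) assignments."""
    am.attach_character(tree, char)
    nodes = list(tree.preorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    internal = [n for n in nodes if not n.is_leaf]
    best, count = None, 0
    sets = {idx[id(n)]: set() for n in internal}
    for combo in itertools.product(am.STATES, repeat=len(internal)):
        assign = {idx[id(n)]: s for n, s in zip(internal, combo)}
        c = am._assignment_cost(tree, idx, assign)
        if best is None or c < best:
            best, count = c, 0
            sets = {k: set() for k in sets}
        if c == best:
            count += 1
            for n, s in zip(internal, combo):
                sets[idx[id(n)]].add(s)
    return best, count, {k: frozenset(v) for k, v in sets.items()}


class TestCharacterFromTable:
    def test_scored_terminals_singleton(self):
        df = pd.DataFrame({"terminal": ["AtPIN1", "AtPIN5"], "score": [1, 2]})
        char = am.character_from_table(df)
        assert char.state_set("AtPIN1") == frozenset({1})
        assert char.state_set("AtPIN5") == frozenset({2})

    def test_missing_terminal_fully_ambiguous(self):
        char = am.character_from_table(
            pd.DataFrame({"terminal": ["x"], "score": [3]})
        )
        assert char.state_set("unlisted") == frozenset({1, 2, 3, 4, 5})

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            am.character_from_table(
                pd.DataFrame({"terminal": ["x"], "score": [6]})
            )

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "char.tsv"
        p.write_text("terminal\tscore\nAtPIN1\t1\nOsPIN1d\t4\n")
        char = am.character_from_table(str(p))
        assert char.state_set("OsPIN1d") == frozenset({4})


class TestMprReconstruct:
    def test_clean_split_single_reconstruction(self):
        char = am.MorphCharacter({"a": {1}, "b": {1}, "c": {2}, "d": {2}})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        assert rs.min_cost == 1
        assert rs.n_reconstructions == 1
        internal_sets = {
            i: s for i, s in rs.node_states.items()
            if not rs.node_ids[i].is_leaf
        }
        assert sorted(internal_sets.values(), key=sorted) == [
            frozenset({1}), frozenset({2})]

    def test_conflicting_pattern_two_reconstructions(self):
        char = am.MorphCharacter({"a": {1}, "b": {2}, "c": {1}, "d": {2}})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        assert rs.min_cost == 2
        assert rs.n_reconstructions == 2
        recs = am.enumerate_reconstructions(rs, cap=30)
        assigns = {tuple(sorted(r.items())) for r in recs}
        # both internal nodes 1, or both 2
        assert {tuple(v for _, v in a) for a in assigns} == {(1, 1), (2, 2)}

    def test_constant_character_zero_cost(self):
        char = am.MorphCharacter({n: {1} for n in "abcd"})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        assert rs.min_cost == 0
        assert rs.n_reconstructions == 1
        assert all(s == frozenset({1}) for s in rs.node_states.values())

    def test_unrooted_without_outgroup_refused(self):
        t = read_newick("((a,b),(c,d),e);")
        char = am.MorphCharacter({n: {1} for n in "abcde"})
        with pytest.raises(ValueError, match="root"):
            am.mpr_reconstruct(t, char)

    def test_outgroup_rooting(self):
        t = read_newick("((a,b),(c,d),e);")
        char = am.MorphCharacter(
            {"a": {2}, "b": {2}, "c": {2}, "d": {2}, "e": {1}})
        rs = am.mpr_reconstruct(t, char, root_taxa={"e"})
        assert rs.min_cost == 1

    def test_agrees_with_brute_force(self, random_rooted_tree):
        rng = np.random.default_rng(0)
        for seed in range(25):
            n = int(rng.integers(4, 8))  # at most 7 internal incl. root
            tree = random_rooted_tree(seed, n)
            states = {
                name: {int(rng.integers(1, 6))}
                for name in tree.leaf_names()
                if rng.random() > 0.15
            }
            char = am.MorphCharacter(states)
            rs = am.mpr_reconstruct(tree, char)
            cost, count, sets = brute_force(tree, char)
            assert rs.min_cost == cost
            assert rs.n_reconstructions == count
            for k, v in sets.items():
                assert rs.node_states[k] == v

    def test_min_cost_equals_fitch_length(self, random_rooted_tree):
        """The unordered 5-state minimum matches the engine's unit-cost
        parsimony score (encoding states 1..5 as A,C,G,T,gap)."""
        code = {1: "A", 2: "C", 3: "G", 4: "T", 5: "-"}
        rng = np.random.default_rng(1)
        for seed in range(10):
            tree = random_rooted_tree(100 + seed, 6)
            states = {name: int(rng.integers(1, 6))
                      for name in tree.leaf_names()}
            char = am.MorphCharacter({k: {v} for k, v in states.items()})
            rs = am.mpr_reconstruct(tree, char)
            rows = [(name, code[states[name]]) for name in tree.leaf_names()]
            m = pe.encode_matrix(SequenceSet(rows, aligned=True),
                                 gap_mode=pe.FIFTH_STATE)
            assert rs.min_cost == pe.fitch_length(tree, m)

    def test_missing_data_monotonicity(self, random_rooted_tree):
        rng = np.random.default_rng(2)
        tree = random_rooted_tree(7, 6)
        states = {name: {int(rng.integers(1, 6))}
                  for name in tree.leaf_names()}
        base = am.mpr_reconstruct(tree, am.MorphCharacter(dict(states)))
        for name in tree.leaf_names():
            relaxed = dict(states)
            relaxed[name] = {1, 2, 3, 4, 5}
            rs = am.mpr_reconstruct(tree, am.MorphCharacter(relaxed))
            assert rs.min_cost <= base.min_cost

    def test_root_placement_cost_invariance(self):
        t = read_newick("((a,b),(c,d),(e,f));")
        char = am.MorphCharacter(
            {"a": {1}, "b": {2}, "c": {2}, "d": {3}, "e": {1}, "f": {3}})
        costs = {
            am.mpr_reconstruct(t, char, root_taxa={leaf}).min_cost
            for leaf in "abcdef"
        }
        assert len(costs) == 1

    def test_polytomous_consensus_tree(self):
        t = read_newick("(a,b,(c,d),(e,f));")
        t.rooted = True
        char = am.MorphCharacter(
            {"a": {1}, "b": {1}, "c": {2}, "d": {2}, "e": {1}, "f": {1}})
        rs = am.mpr_reconstruct(t, char)
        cost, count, sets = brute_force(t, char)
        assert rs.min_cost == cost
        assert rs.n_reconstructions == count


class TestEnumerate:
    def test_cap_refusal_names_count(self):
        char = am.MorphCharacter({"a": {1}, "b": {2}, "c": {1}, "d": {2}})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        with pytest.raises(ValueError, match="2"):
            am.enumerate_reconstructions(rs, cap=1)

    def test_zero_cost_single_map(self):
        char = am.MorphCharacter({n: {4} for n in "abcd"})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        recs = am.enumerate_reconstructions(rs, cap=10)
        assert len(recs) == 1
        assert set(recs[0].values()) == {4}


class TestPaintTree:
    def test_annotations_and_round_trip(self):
        char = am.MorphCharacter({"a": {1}, "b": {2}, "c": {1}, "d": {2}})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        newick, table = am.paint_tree(rs.tree, rs)
        assert "mpr=1|2" in newick
        assert table[~table.is_leaf]["ambiguous"].all()
        back = am.annotations_from_table(table)
        assert back == {i: s for i, s in rs.node_states.items()}

    def test_unambiguous_single_labels(self):
        char = am.MorphCharacter({"a": {3}, "b": {3}, "c": {3}, "d": {3}})
        rs = am.mpr_reconstruct(rooted_quartet(), char)
        _, table = am.paint_tree(rs.tree, rs)
        assert not table["ambiguous"].any()
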