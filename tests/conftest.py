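import numpy as np
import pytest

from phylomask.seq_io import SequenceSet


@pytest.fixture
def random_seqset():
    """Factory: aligned nucleotide SequenceSet with ambiguity characters."""

    def make(seed: int, n_taxa: int = 7, n_sites: int = 30,
             chars: str = "ACGTN?-", probs=None):
        rng = np.random.default_rng(seed)
        pool = list(chars)
        if probs is None:
            probs = [0.2, 0.2, 0.2, 0.2, 0.08, 0.06, 0.06][: len(pool)]
            probs = [p / sum(probs) for p in probs]
        rows = [
            (f"t{i}", "".join(rng.choice(pool, size=n_sites, p=probs)))
            for i in range(n_taxa)
        ]
        return SequenceSet(rows, alphabet="nucleotide", aligned=True)

    return make


@pytest.fixture
def random_rooted_tree():
    """Factory: random rooted binary tree on labelled leaves."""

    def make(seed: int, n_leaves: int):
        from phylomask.seq_io import Node, Tree

        rng = np.random.default_rng(seed)
        leaves = [f"L{i}" for i in range(n_leaves)]
        root = Node()
        a, b = Node(label=leaves[0]), Node(label=leaves[1])
        root.add(a)
        root.add(b)
        attachable = [a, b]
        for name in leaves[2:]:
            target = attachable[int(rng.integers(len(attachable)))]
            parent = target.parent
            joint = Node()
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            joint.add(target)
            leaf = Node(label=name)
            joint.add(leaf)
            attachable.extend([leaf, joint])
        return Tree(root, rooted=True)

    return make
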