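"""Parsimony ancestral reconstruction of the 5-state PIN morphology character.

PIN proteins are coded 1-5 by their structure (1 long, 2 short, 3 reduced
central hydrophilic loop, 4 C-terminal-TMD-only, 5 N-terminal-TMD-only); the
character is unordered, so any state-to-state change costs one step.  Given a
rooted tree (possibly polytomous, e.g. a strict consensus) the Sankoff dynamic
program computes, exactly and without enumeration:

* the minimum number of changes (``min_cost``);
* for every internal node the MPR set — the states that appear in at least
  one most-parsimonious reconstruction (computed from up- and down-pass cost
  vectors);
* the exact number of equally parsimonious full reconstructions (product-sum
  over optimal backpointers).

When the count is small the reconstructions themselves can be enumerated and
painted onto the tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .seq_io import Node, Tree

STATES = (1, 2, 3, 4, 5)
STATE_LABELS = {
    1: "long",
    2: "short",
    3: "reduced",
    4: "C-terminal TMD only",
    5: "N-terminal TMD only",
}
_INF = float("inf")


@dataclass
class MorphCharacter:
    """Taxon -> subset of {1..5}; missing taxa are fully ambiguous."""

    states: dict[str, frozenset]
    state_labels: Mapping[int, str] = field(default_factory=lambda: dict(STATE_LABELS))

    def __post_init__(self) -> None:
        for taxon, ss in self.states.items():
            ss = frozenset(int(s) for s in ss)
            if not ss or not ss <= set(STATES):
                raise ValueError(f"{taxon}: state set {set(ss)} invalid")
            self.states[taxon] = ss

    def state_set(self, taxon: str) -> frozenset:
        return self.states.get(taxon, frozenset(STATES))


def character_from_table(tsv) -> MorphCharacter:
    """Read a two-column TSV (``terminal``, ``score``) into a character.

    Terminals absent from the table are treated as fully ambiguous
    (missing data)."""
    df = tsv if isinstance(tsv, pd.DataFrame) else pd.read_csv(tsv, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "terminal" not in cols or "score" not in cols:
        raise ValueError("table must have columns 'terminal' and 'score'")
    states = {}
    for _, row in df.iterrows():
        score = int(row[cols["score"]])
        if score not in STATES:
            raise ValueError(
                f"{row[cols['terminal']]}: score {score} outside 1-5"
            )
        states[str(row[cols["terminal"]])] = frozenset([score])
    return MorphCharacter(states)


@dataclass
class ReconstructionSet:
    """MPR summary for one (tree, character) pair."""

    tree: Tree
    node_states: dict[int, frozenset]  # preorder node index -> MPR state set
    min_cost: int
    n_reconstructions: int
    node_ids: dict[int, Node] = field(default_factory=dict, repr=False)

    def states_at(self, node_id: int) -> frozenset:
        return self.node_states[node_id]


def _node_index(tree: Tree) -> tuple[list[Node], dict[int, int]]:
    """Stable preorder ids for every node."""
    nodes = list(tree.preorder())
    return nodes, {id(n): i for i, n in enumerate(nodes)}


def mpr_reconstruct(
    tree: Tree,
    char: MorphCharacter,
    root_taxa: Optional[Iterable[str]] = None,
) -> ReconstructionSet:
    """Sankoff reconstruction of the unordered character over a rooted tree.

    ``tree`` must be rooted, or ``root_taxa`` (an outgroup forming one side of
    a bipartition, e.g. the moss copies) must be given to place the root.
    Polytomies are handled by the generalised Sankoff recursion (sum over all
    children), so strict consensus trees can be used directly.
    """
    if not tree.rooted:
        if root_taxa is None:
            raise ValueError(
                "tree is unrooted: supply root_taxa (outgroup) to place the root"
            )
        tree = tree.rooted_at(root_taxa)
    attach_character(tree, char)  # leaves absent from the table are ambiguous
    nodes, idx = _node_index(tree)

    down: dict[int, list[float]] = {}
    ways: dict[int, list[int]] = {}  # ways to realise down-cost, internals only
    for node in tree.postorder():
        i = idx[id(node)]
        if node.is_leaf:
            allowed = char.state_set(node.label)
            down[i] = [0.0 if s in allowed else _INF for s in STATES]
            continue
        cost = [0.0] * len(STATES)
        nways = [1] * len(STATES)
        for c in node.children:
            j = idx[id(c)]
            cmin = min(down[j])
            folded = [min(down[j][k], cmin + 1) for k in range(len(STATES))]
            if c.is_leaf:
                for k in range(len(STATES)):
                    cost[k] += folded[k]
            else:
                for k in range(len(STATES)):
                    cost[k] += folded[k]
                    w = 0
                    for t in range(len(STATES)):
                        if down[j][t] + (0 if t == k else 1) == folded[k]:
                            w += ways[j][t]
                    nways[k] = nways[k] * w
        down[i] = cost
        ways[i] = nways

    root_i = idx[id(tree.root)]
    min_cost = min(down[root_i])
    n_rec = sum(w for c, w in zip(down[root_i], ways[root_i]) if c == min_cost)

    # up-pass: cost of the rest of the tree as a function of each node's state
    up: dict[int, list[float]] = {root_i: [0.0] * len(STATES)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        i = idx[id(node)]
        folded_children = {}
        for c in node.children:
            j = idx[id(c)]
            cmin = min(down[j])
            folded_children[j] = [
                min(down[j][k], cmin + 1) for k in range(len(STATES))
            ]
        tot = [up[i][k] + sum(f[k] for f in folded_children.values())
               for k in range(len(STATES))]
        for c in node.children:
            j = idx[id(c)]
            rest = [tot[k] - folded_children[j][k] for k in range(len(STATES))]
            # child's up vector, as a function of the *child's* state
            rmin = min(rest)
            up[j] = [min(rest[k], rmin + 1) for k in range(len(STATES))]

    node_states: dict[int, frozenset] = {}
    for node in tree.preorder():
        i = idx[id(node)]
        if node.is_leaf:
            total = [down[i][k] + up[i][k] for k in range(len(STATES))]
        else:
            total = [down[i][k] + up[i][k] for k in range(len(STATES))]
        node_states[i] = frozenset(
            STATES[k] for k in range(len(STATES)) if total[k] == min_cost
        )
    return ReconstructionSet(
        tree=tree,
        node_states=node_states,
        min_cost=int(min_cost),
        n_reconstructions=int(n_rec),
        node_ids={i: n for i, n in enumerate(nodes)},
    )


def enumerate_reconstructions(
    rs: ReconstructionSet, cap: int = 1000
) -> list[dict[int, int]]:
    """Explicit list of all most-parsimonious internal-state assignments.

    Each map sends internal-node preorder id -> state.  Refuses (with the
    exact count) when there are more than ``cap`` reconstructions.
    """
    if rs.n_reconstructions > cap:
        raise ValueError(
            f"{rs.n_reconstructions} reconstructions exceed cap {cap}"
        )
    tree = rs.tree
    nodes, idx = _node_index(tree)
    internal = [i for i, n in rs.node_ids.items() if not n.is_leaf]
    out = []
    for combo in itertools.product(STATES, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        if _assignment_cost(tree, idx, assign) == rs.min_cost:
            out.append(assign)
    assert len(out) == rs.n_reconstructions
    return out


def _assignment_cost(tree: Tree, idx: dict[int, int],
                     assign: dict[int, int],
                     char: Optional[MorphCharacter] = None) -> float:
    """Cost of a full internal-node assignment (leaves resolve freely)."""
    cost = 0.0
    for node in tree.preorder():
        if node is tree.root:
            continue
        p_state = assign[idx[id(node.parent)]]
        if node.is_leaf:
            allowed = _leaf_allowed(tree, node)
            cost += 0 if p_state in allowed else 1
        else:
            cost += 0 if assign[idx[id(node)]] == p_state else 1
    return cost


_LEAF_CHAR_ATTR = "_phylomask_leaf_states"


def _leaf_allowed(tree: Tree, leaf: Node) -> frozenset:
    table = getattr(tree, _LEAF_CHAR_ATTR, None)
    if table is None:
        raise RuntimeError("leaf states not attached to tree")
    return table[leaf.label]


def attach_character(tree: Tree, char: MorphCharacter) -> None:
    """Cache each leaf's allowed state set on the tree (for enumeration)."""
    setattr(
        tree,
        _LEAF_CHAR_ATTR,
        {name: char.state_set(name) for name in tree.leaf_names()},
    )


def paint_tree(tree: Tree, rs: ReconstructionSet) -> tuple[str, pd.DataFrame]:
    """Annotated Newick plus a node table of MPR state sets.

    Internal nodes are labelled ``mpr=1|2`` in the Newick string; the table
    has columns node_id, is_leaf, label, states, ambiguous."""
    nodes, idx = _node_index(rs.tree)
    rows = []
    for i, node in enumerate(nodes):
        states = sorted(rs.node_states[i])
        rows.append(
            {
                "node_id": i,
                "is_leaf": node.is_leaf,
                "label": node.label or "",
                "states": "|".join(str(s) for s in states),
                "ambiguous": len(states) > 1,
            }
        )
    table = pd.DataFrame(rows)

    def fmt(node: Node) -> str:
        i = idx[id(node)]
        states = "|".join(str(s) for s in sorted(rs.node_states[i]))
        if node.is_leaf:
            return f"{node.label}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner})mpr={states}"

    return fmt(rs.tree.root) + ";", table


def annotations_from_table(table: pd.DataFrame) -> dict[int, frozenset]:
    """Inverse of the paint_tree table: node_id -> MPR state set."""
    return {
        int(row["node_id"]): frozenset(
            int(s) for s in str(row["states"]).split("|") if s
        )
        for _, row in table.iterrows()
    }
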