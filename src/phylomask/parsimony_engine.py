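"""Maximum-parsimony scoring and tree search with explicit ambiguity semantics.

The ambiguity semantics are the point of this engine and mirror how TNT reads
the masked alignments:

* ``N`` is *any nucleotide* — the cell is {A,C,G,T}, so the information that
  the site is **not** a gap survives;
* ``?`` is *any nucleotide or a gap*;
* ``-`` is a gap, which can be treated either as a fifth character state
  (``gap_mode="fifth_state"``, the default, matching the TNT analyses) or as
  missing data (``gap_mode="missing"``, mimicking how RAxML handles gaps).

Scoring uses the Fitch set intersection/union pass over bitmask-encoded
state sets, vectorised across sites with numpy.  A unit-cost Sankoff dynamic
program over the same encoding provides per-edge minimum lengths (used to
collapse zero-length branches) and an independent length computation that also
accepts polytomous trees.

Search is TNT-flavoured: random-addition Wagner builds followed by SPR or TBR
branch swapping, keeping every shortest tree found (plateau search), then
collapsing zero-minimum-length branches and deduplicating by unrooted
topology.  A brute-force :func:`exhaustive_search` over all unrooted
topologies (feasible to nine taxa) serves as the oracle the heuristic is
validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .seq_io import Node, SequenceSet, Tree

FIFTH_STATE = "fifth_state"
MISSING = "missing"

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_GAP_BIT = 16
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_ALL_NUC = 15


def _char_to_mask(ch: str, gap_mode: str) -> int:
    ch = ch.upper()
    if ch in _BIT:
        return _BIT[ch]
    if ch in _IUPAC:
        return sum(_BIT[c] for c in _IUPAC[ch])
    if ch in ("N", "X"):
        return _ALL_NUC
    if ch == "?":
        return _ALL_NUC | _GAP_BIT if gap_mode == FIFTH_STATE else _ALL_NUC
    if ch == "-":
        return _GAP_BIT if gap_mode == FIFTH_STATE else _ALL_NUC
    raise ValueError(f"unknown character {ch!r}")


def _mask_to_char(mask: int, gap_mode: str) -> str:
    if gap_mode == FIFTH_STATE:
        if mask == _ALL_NUC | _GAP_BIT:
            return "?"
        if mask == _GAP_BIT:
            return "-"
    if mask == _ALL_NUC:
        return "N"
    for ch, bit in _BIT.items():
        if mask == bit:
            return ch
    for ch, chars in _IUPAC.items():
        if mask == sum(_BIT[c] for c in chars):
            return ch
    return "?"


@dataclass
class CharacterMatrix:
    """Taxa x sites of state sets encoded as bitmasks (A=1,C=2,G=4,T=8,gap=16)."""

    taxa: list[str]
    masks: np.ndarray  # (ntaxa, nsites) uint8
    gap_mode: str = FIFTH_STATE
    weights: Optional[np.ndarray] = None  # (nsites,) non-negative ints

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.masks.ndim != 2 or self.masks.shape[0] != len(self.taxa):
            raise ValueError("masks must be a (n_taxa, n_sites) array")
        if self.gap_mode not in (FIFTH_STATE, MISSING):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if (self.masks == 0).any():
            raise ValueError("empty state set in matrix")
        if self.weights is None:
            self.weights = np.ones(self.masks.shape[1], dtype=np.int64)
        else:
            self.weights = np.asarray(self.weights, dtype=np.int64)
            if self.weights.shape != (self.masks.shape[1],) or (self.weights < 0).any():
                raise ValueError("weights must be non-negative, one per site")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.masks.shape[1]

    @property
    def n_states(self) -> int:
        return 5 if self.gap_mode == FIFTH_STATE else 4

    def with_weights(self, weights: np.ndarray) -> "CharacterMatrix":
        return CharacterMatrix(self.taxa, self.masks, self.gap_mode, weights)

    def cell_chars(self) -> list[str]:
        """Decode each row back to a character string (for TNT export)."""
        return [
            "".join(_mask_to_char(int(m), self.gap_mode) for m in row)
            for row in self.masks
        ]


def encode_matrix(seqs: SequenceSet, gap_mode: str = FIFTH_STATE) -> CharacterMatrix:
    """Encode an aligned nucleotide SequenceSet into bitmask state sets."""
    if not seqs.records:
        raise ValueError("empty sequence set")
    if not seqs.aligned and len({len(s) for _, s in seqs}) > 1:
        raise ValueError("matrix encoding requires aligned sequences")
    n_sites = len(seqs.records[0][1])
    masks = np.zeros((len(seqs), n_sites), dtype=np.uint8)
    for i, (name, seq) in enumerate(seqs):
        for j, ch in enumerate(seq):
            try:
                masks[i, j] = _char_to_mask(ch, gap_mode)
            except ValueError as exc:
                raise ValueError(f"taxon {name!r}, site {j + 1}: {exc}") from exc
    return CharacterMatrix(list(seqs.names), masks, gap_mode=gap_mode)


@dataclass
class SearchResult:
    """Outcome of a parsimony search: shortest length and all shortest trees."""

    best_length: int
    best_trees: list[Tree]
    replicates_run: int = 0
    seed: Optional[int] = None

    def strict_consensus(self) -> Tree:
        return strict_consensus(self.best_trees)


# ---------------------------------------------------------------------------
# internal unrooted-tree representation: adjacency dict, leaves 0..L-1
# ---------------------------------------------------------------------------

def _rooted_order(adj: dict[int, list[int]], root: int = 0):
    """BFS order and parent map, rooted at ``root`` (normally leaf 0)."""
    parent = {root: -1}
    order = [root]
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
    return order, parent


def _fitch_adj(adj: dict[int, list[int]], L: int, masks: np.ndarray,
               weights: np.ndarray) -> int:
    """Fitch length of the unrooted tree given by ``adj`` (leaves 0..L-1).

    Children at a vertex are folded pairwise with the intersection/union rule,
    which is exact for binary trees (every internal vertex of degree three).
    """
    root = 0 if 0 in adj else min(u for u in adj if len(adj[u]) == 1)
    order, parent = _rooted_order(adj, root=root)
    state: dict[int, np.ndarray] = {}
    cost = 0
    for u in reversed(order):
        if u < L:
            state[u] = masks[u]
            continue
        kids = [v for v in adj[u] if v != parent[u]]
        cur = state[kids[0]]
        for k in kids[1:]:
            inter = cur & state[k]
            empty = inter == 0
            if empty.any():
                cost += int(weights[empty].sum())
                cur = np.where(empty, cur | state[k], inter)
            else:
                cur = inter
        state[u] = cur
    # close the circuit at the rooting leaf
    child = adj[root][0]
    empty = (masks[root] & state[child]) == 0
    cost += int(weights[empty].sum())
    return cost


_BIG = np.int32(1 << 20)


def _leaf_cost(mask_row: np.ndarray, n_states: int) -> np.ndarray:
    """(n_states, n_sites) unit-cost Sankoff leaf vector from bitmasks."""
    out = np.empty((n_states, mask_row.shape[0]), dtype=np.int32)
    for s in range(n_states):
        out[s] = np.where(mask_row & (1 << s), 0, _BIG)
    return out


def _fold(x: np.ndarray) -> np.ndarray:
    """min(cost, min+1): a child's contribution to its parent (unit cost)."""
    return np.minimum(x, x.min(axis=0) + 1)


def _sankoff_down(adj, L, masks, n_states):
    """Postorder cost vectors for every node, rooted at leaf 0."""
    order, parent = _rooted_order(adj)
    down: dict[int, np.ndarray] = {}
    for u in reversed(order):
        if u < L:
            down[u] = _leaf_cost(masks[u], n_states)
        else:
            kids = [v for v in adj[u] if v != parent[u]]
            down[u] = sum(_fold(down[k]) for k in kids)
    return order, parent, down


def _sankoff_adj(adj, L, masks, weights, n_states) -> int:
    """Unit-cost Sankoff length; accepts polytomies (exact everywhere)."""
    order, parent, down = _sankoff_down(adj, L, masks, n_states)
    c0 = adj[0][0]
    total = _fold(down[c0]) + _leaf_cost(masks[0], n_states)
    return int((weights * total.min(axis=0)).sum())


def _collapsible_edges(adj, L, masks, weights, n_states) -> set[frozenset]:
    """Internal edges whose minimum length over all MPRs is zero."""
    order, parent, down = _sankoff_down(adj, L, masks, n_states)
    up: dict[int, np.ndarray] = {}
    for u in order:
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            continue
        if parent[u] == -1:  # rooting leaf
            up[kids[0]] = _leaf_cost(masks[u], n_states)
            continue
        folded = {c: _fold(down[c]) for c in kids}
        tot = _fold(up[u]) + sum(folded.values())
        for c in kids:
            up[c] = tot - folded[c]
    out: set[frozenset] = set()
    w_pos = weights > 0
    for v in order[1:]:
        p = parent[v]
        if v < L or p < L:
            continue  # terminal edges are never collapsed
        joint = (down[v] + up[v]).min(axis=0)
        separate = down[v].min(axis=0) + up[v].min(axis=0) + 1
        if np.all(joint[w_pos] <= separate[w_pos]):
            out.add(frozenset((p, v)))
    return out


def _collapse_edges(adj, edges: set[frozenset]) -> dict[int, list[int]]:
    """Contract the given edges (union-find merge of their endpoints)."""
    if not edges:
        return {u: list(vs) for u, vs in adj.items()}
    rep = {u: u for u in adj}

    def find(u):
        while rep[u] != u:
            rep[u] = rep[rep[u]]
            u = rep[u]
        return u

    for e in edges:
        a, b = tuple(e)
        ra, rb = find(a), find(b)
        if ra != rb:
            rep[max(ra, rb)] = min(ra, rb)
    new: dict[int, set[int]] = {}
    for u, vs in adj.items():
        ru = find(u)
        for v in vs:
            rv = find(v)
            if ru != rv:
                new.setdefault(ru, set()).add(rv)
                new.setdefault(rv, set()).add(ru)
    return {u: sorted(vs) for u, vs in new.items()}


def _split_key(adj, L) -> frozenset:
    """Canonical topology key: the set of nontrivial splits as leaf bitsets
    (side not containing leaf 0)."""
    order, parent = _rooted_order(adj)
    below: dict[int, int] = {}
    full = (1 << L) - 1
    keys = set()
    for u in reversed(order):
        if u < L:
            below[u] = 1 << u
        else:
            below[u] = 0
            for v in adj[u]:
                if v != parent[u]:
                    below[u] |= below[v]
        if parent[u] == -1:
            continue
        m = below[u]
        if m & 1:
            m = full ^ m
        if 2 <= m.bit_count() <= L - 2:
            keys.add(m)
    return frozenset(keys)


def _tree_to_adj(tree: Tree, taxa: list[str]) -> dict[int, list[int]]:
    """Convert a Tree to adjacency form with leaf ids = matrix row order."""
    index = {t: i for i, t in enumerate(taxa)}
    if set(tree.leaf_names()) != set(taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    adj: dict[int, list[int]] = {}
    next_id = [len(taxa)]

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def visit(node: Node) -> int:
        if node.is_leaf:
            return index[node.label]
        nid = next_id[0]
        next_id[0] += 1
        adj.setdefault(nid, [])
        for c in node.children:
            add_edge(nid, visit(c))
        return nid

    root_id = visit(tree.root)
    # splice a bifurcating root so the structure is a proper unrooted tree
    if len(adj[root_id]) == 2:
        a, b = adj.pop(root_id)
        adj[a].remove(root_id)
        adj[b].remove(root_id)
        add_edge(a, b)
    return adj


def _adj_to_tree(adj, L, taxa: list[str]) -> Tree:
    """Convert adjacency form back to an (unrooted) Tree."""
    internals = [u for u in adj if u >= L]
    if internals:
        root_id = min(internals, key=lambda u: -len(adj[u]))
        # prefer an internal node adjacent to leaf 0 for determinism
        for v in adj[0]:
            if v >= L:
                root_id = v
                break
    else:  # two-leaf degenerate tree
        root_id = 0
    order, parent = _rooted_order(adj, root=root_id)
    nodes = {
        u: Node(label=taxa[u] if u < L else None) for u in order
    }
    for u in order[1:]:
        nodes[parent[u]].add(nodes[u])
    return Tree(nodes[root_id], rooted=False)


# ---------------------------------------------------------------------------
# public scoring
# ---------------------------------------------------------------------------

def fitch_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Parsimony length of a binary tree (unordered states, unit cost).

    Rooting is irrelevant: a bifurcating root is spliced before scoring.
    Polytomous trees are refused — resolve them, or score a consensus with
    :func:`sankoff_length`.
    """
    adj = _tree_to_adj(tree, matrix.taxa)
    for u, vs in adj.items():
        if u >= matrix.n_taxa and len(vs) != 3:
            raise ValueError(
                "fitch_length requires a binary tree; use sankoff_length "
                "for polytomies"
            )
    return _fitch_adj(adj, matrix.n_taxa, matrix.masks, matrix.weights)


def sankoff_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Unit-cost Sankoff parsimony length; polytomies are allowed."""
    adj = _tree_to_adj(tree, matrix.taxa)
    return _sankoff_adj(adj, matrix.n_taxa, matrix.masks, matrix.weights,
                        matrix.n_states)


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------

def _wagner_adj(matrix: CharacterMatrix, rng: np.random.Generator):
    """Random-addition-order stepwise (Wagner) tree, adjacency form."""
    L = matrix.n_taxa
    if L < 3:
        raise ValueError("Wagner build needs at least three taxa")
    order = list(rng.permutation(L))
    a, b, c = order[:3]
    hub = L
    adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_id = L + 1
    for t in order[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        best = None
        best_edges = []
        for (u, v) in edges:
            w = next_id
            adj[u][adj[u].index(v)] = w
            adj[v][adj[v].index(u)] = w
            adj[w] = [u, v, t]
            adj[t] = [w]
            score = _fitch_adj(adj, L, matrix.masks, matrix.weights)
            del adj[w], adj[t]
            adj[u][adj[u].index(w)] = v
            adj[v][adj[v].index(w)] = u
            if best is None or score < best:
                best, best_edges = score, [(u, v)]
            elif score == best:
                best_edges.append((u, v))
        u, v = best_edges[int(rng.integers(len(best_edges)))]
        w = next_id
        next_id += 1
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, t]
        adj[t] = [w]
    return adj


def wagner_build(matrix: CharacterMatrix, seed: int = 0) -> Tree:
    """One random-addition Wagner tree (ties broken by the seeded RNG)."""
    rng = np.random.default_rng(seed)
    return _adj_to_tree(_wagner_adj(matrix, rng), matrix.n_taxa, matrix.taxa)


def _prep_side(adj, x, other):
    """Edges and attachment specs for the component containing ``x`` after
    removing edge (x, other).  Attachment specs are ('node', x) or
    ('edge', u, v)."""
    # collect component nodes
    comp = {x}
    stack = [x]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == x and v == other:
                continue
            if v not in comp:
                comp.add(v)
                stack.append(v)
    nbrs_x = [v for v in adj[x] if v != other]
    edges = []
    for u in comp:
        for v in adj[u]:
            if v in comp and u < v and not (frozenset((u, v)) == frozenset((x, other))):
                edges.append((u, v))
    if not nbrs_x:  # x is a bare leaf
        return [], [("node", x)], None
    if len(nbrs_x) == 2:  # suppress the degree-2 vertex x
        n1, n2 = nbrs_x
        edges = [e for e in edges if x not in e]
        edges.append((n1, n2))
        attach = [("edge", u, v) for (u, v) in edges]
        return edges, attach, x
    # vertex keeps degree >= 3: attach at any edge or at x itself
    attach = [("edge", u, v) for (u, v) in edges] + [("node", x)]
    return edges, attach, None


def _reconnect(edges_a, attach1, edges_b, attach2, next_id):
    """Build adjacency for edges_a + edges_b joined at the two attachments."""
    new_edges = list(edges_a) + list(edges_b)
    nid = next_id

    def resolve(spec, edges_side):
        nonlocal nid, new_edges
        if spec[0] == "node":
            return spec[1]
        _, u, v = spec
        w = nid
        nid += 1
        new_edges.remove((u, v))
        new_edges.append((u, w))
        new_edges.append((w, v))
        return w

    p = resolve(attach1, edges_a)
    q = resolve(attach2, edges_b)
    new_edges.append((p, q))
    adj: dict[int, list[int]] = {}
    for u, v in new_edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _neighbors(adj, L, swap: str) -> Iterator[dict[int, list[int]]]:
    """SPR or TBR neighbourhood of a binary unrooted tree."""
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    next_id = max(adj) + 2
    for (a, b) in edges:
        edges_a, attach_a, supp_a = _prep_side(adj, a, b)
        edges_b, attach_b, supp_b = _prep_side(adj, b, a)
        if swap == "SPR":
            # keep one side's original attachment point: the suppressed
            # vertex's edge (or the bare node itself)
            fixed_a = [s for s in attach_a
                       if s[0] == "node" or supp_a is None or
                       set(s[1:]) == {v for v in adj[a] if v != b}]
            fixed_b = [s for s in attach_b
                       if s[0] == "node" or supp_b is None or
                       set(s[1:]) == {v for v in adj[b] if v != a}]
            pairs = [(s1, s2) for s1 in attach_a for s2 in fixed_b]
            pairs += [(s1, s2) for s1 in fixed_a for s2 in attach_b]
        else:
            pairs = [(s1, s2) for s1 in attach_a for s2 in attach_b]
        for s1, s2 in pairs:
            yield _reconnect(edges_a, s1, edges_b, s2, next_id)


def _hill_climb(adj, matrix, rng, swap):
    L = matrix.n_taxa
    cur, cur_len = adj, _fitch_adj(adj, L, matrix.masks, matrix.weights)
    while True:
        best_len, best = cur_len, []
        for nb in _neighbors(cur, L, swap):
            ln = _fitch_adj(nb, L, matrix.masks, matrix.weights)
            if ln < best_len:
                best_len, best = ln, [nb]
            elif ln == best_len and ln < cur_len:
                best.append(nb)
        if best_len >= cur_len:
            return cur, cur_len
        cur = best[int(rng.integers(len(best)))]
        cur_len = best_len


def heuristic_search(
    matrix: CharacterMatrix,
    builds: int = 100,
    swap: str = "TBR",
    keep_all_shortest: bool = True,
    seed: int = 0,
    max_trees: int = 200,
) -> SearchResult:
    """Random-addition builds + branch swapping, keeping all shortest trees.

    Each build swaps (SPR or TBR) to a local optimum; the pool of trees at the
    global minimum is then closed under equal-length swaps (bounded by
    ``max_trees``).  Zero-minimum-length branches are collapsed before
    deduplication, so the returned trees may be polytomous.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least four taxa")
    if swap not in ("SPR", "TBR"):
        raise ValueError("swap must be 'SPR' or 'TBR'")
    rng = np.random.default_rng(seed)
    L = matrix.n_taxa
    best_len = None
    pool: dict[frozenset, dict] = {}
    for _ in range(builds):
        adj = _wagner_adj(matrix, rng)
        adj, ln = _hill_climb(adj, matrix, rng, swap)
        if best_len is None or ln < best_len:
            best_len = ln
            pool = {}
        if ln == best_len:
            pool.setdefault(_split_key(adj, L), adj)
    if keep_all_shortest:
        # close the shortest-tree pool under equal-length swaps; restart if a
        # shorter tree is stumbled upon
        restart = True
        while restart:
            restart = False
            queue = list(pool.values())
            while queue and len(pool) < max_trees:
                t = queue.pop()
                for nb in _neighbors(t, L, swap):
                    ln = _fitch_adj(nb, L, matrix.masks, matrix.weights)
                    if ln < best_len:
                        nb, ln = _hill_climb(nb, matrix, rng, swap)
                        best_len = ln
                        pool = {_split_key(nb, L): nb}
                        restart = True
                        queue = []
                        break
                    if ln == best_len and len(pool) < max_trees:
                        key = _split_key(nb, L)
                        if key not in pool:
                            pool[key] = nb
                            queue.append(nb)
    trees = _finalise_pool(pool.values(), matrix)
    return SearchResult(
        best_length=int(best_len),
        best_trees=trees,
        replicates_run=builds,
        seed=seed,
    )


def _finalise_pool(adjs, matrix) -> list[Tree]:
    """Collapse zero-length branches, deduplicate, convert to Trees."""
    L = matrix.n_taxa
    out: dict[frozenset, Tree] = {}
    for adj in adjs:
        coll = _collapse_edges(
            adj,
            _collapsible_edges(adj, L, matrix.masks, matrix.weights,
                               matrix.n_states),
        )
        key = _split_key(coll, L)
        if key not in out:
            out[key] = _adj_to_tree(coll, L, matrix.taxa)
    return list(out.values())


def _all_topologies(n: int) -> Iterator[dict[int, list[int]]]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1."""
    hub = n
    base = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}

    def expand(adj, next_leaf, next_id):
        if next_leaf == n:
            yield adj
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for (u, v) in edges:
            new = {k: list(vs) for k, vs in adj.items()}
            w = next_id
            new[u][new[u].index(v)] = w
            new[v][new[v].index(u)] = w
            new[w] = [u, v, next_leaf]
            new[next_leaf] = [w]
            yield from expand(new, next_leaf + 1, next_id + 1)

    yield from expand(base, 3, n + 1)


def exhaustive_search(matrix: CharacterMatrix, collapse: bool = True) -> SearchResult:
    """Brute-force global optimum over all unrooted topologies (<= 9 taxa)."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least three taxa")
    if n > 9:
        raise ValueError(
            f"exhaustive search refuses {n} taxa "
            f"((2n-5)!! topologies would be enumerated)"
        )
    best_len = None
    best: list[dict] = []
    for adj in _all_topologies(n):
        ln = _fitch_adj(adj, n, matrix.masks, matrix.weights)
        if best_len is None or ln < best_len:
            best_len, best = ln, [adj]
        elif ln == best_len:
            best.append(adj)
    trees = (
        _finalise_pool(best, matrix)
        if collapse
        else [_adj_to_tree(a, n, matrix.taxa) for a in best]
    )
    return SearchResult(best_length=int(best_len), best_trees=trees,
                        replicates_run=1, seed=None)


# ---------------------------------------------------------------------------
# consensus and bootstrap
# ---------------------------------------------------------------------------

def strict_consensus(trees: list[Tree]) -> Tree:
    """The tree containing exactly the bipartitions shared by every input."""
    if not trees:
        raise ValueError("no trees given")
    leafset = frozenset(trees[0].leaf_names())
    for t in trees[1:]:
        if frozenset(t.leaf_names()) != leafset:
            raise ValueError("trees are on different leaf sets")
    common = set.intersection(*(set(t.splits()) for t in trees))
    return tree_from_splits(common, leafset)


def tree_from_splits(splits: Iterable[frozenset], leafset: frozenset) -> Tree:
    """Build the (unrooted) tree realising a compatible, laminar split set.

    Splits must be canonicalised as the side not containing the smallest
    leaf, which makes them a laminar family ordered by containment.
    """
    ref = min(leafset)
    clusters = sorted(set(splits), key=len, reverse=True)
    root = Node()
    cluster_nodes: list[tuple[frozenset, Node]] = []
    for cl in clusters:
        node = Node()
        # parent = smallest strict superset already placed (laminar family)
        parent, parent_size = root, None
        for other, onode in cluster_nodes:
            if cl < other and (parent_size is None or len(other) < parent_size):
                parent, parent_size = onode, len(other)
        parent.add(node)
        cluster_nodes.append((cl, node))
    for leaf in sorted(leafset):
        node = Node(label=leaf)
        parent, parent_size = root, None
        if leaf != ref:
            for cl, cnode in cluster_nodes:
                if leaf in cl and (parent_size is None or len(cl) < parent_size):
                    parent, parent_size = cnode, len(cl)
        parent.add(node)
    return Tree(root, rooted=False)


def bootstrap_support(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    builds_per_rep: int = 2,
    seed: int = 0,
    swap: str = "TBR",
) -> dict[frozenset, float]:
    """Site-resampling bootstrap: percentage of pseudoreplicates whose strict
    consensus contains each bipartition (keys are leaf-name frozensets,
    canonicalised as the side without the smallest leaf)."""
    rng = np.random.default_rng(seed)
    n_sites = matrix.n_sites
    total = int(matrix.weights.sum())
    p = matrix.weights / total
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        w = rng.multinomial(total, p).astype(np.int64)
        rep_seed = int(rng.integers(2**31))
        res = heuristic_search(
            matrix.with_weights(w),
            builds=builds_per_rep,
            swap=swap,
            seed=rep_seed,
        )
        for split in res.strict_consensus().splits():
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / replicates for s, c in counts.items()}
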