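"""Sequence and tree containers plus the file formats the pipeline touches.

The two core types are deliberately small:

* :class:`SequenceSet` — an ordered collection of named residue strings over a
  declared alphabet (nucleotide or amino acid), optionally aligned.
* :class:`Tree` — a leaf-labelled topology, rooted or unrooted, with optional
  branch lengths.  Unrooted trees are stored with a trifurcating (or higher)
  root vertex, the usual Newick convention.

FASTA is read through Biopython and validated afterwards; Newick is parsed by
dendropy and converted into the package's own node structure.  The TNT/Hennig86
``xread`` writer is local because no installed library emits that dialect, and
because it must preserve the N-versus-? distinction that motivates the whole
toolkit: ``N`` means "any nucleotide" (the gap information survives) while
``?`` means "any nucleotide or a gap".

Coordinates shown to users (reports, tables) are 1-based inclusive; internal
storage is 0-based half-open.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
from Bio import SeqIO

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

_NUC_CHARS = set("ACGTRYSWKMBDHV")          # IUPAC nucleotides
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY*")
_SHARED = set("-N?X")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Ordered, uniquely named residue strings over a declared alphabet."""

    records: list[tuple[str, str]]
    alphabet: str = NUCLEOTIDE
    aligned: bool = False

    def __post_init__(self) -> None:
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise FormatError(f"duplicate identifier: {dup!r}")
        if self.aligned and self.records:
            L = len(self.records[0][1])
            for name, seq in self.records:
                if len(seq) != L:
                    raise FormatError(
                        f"aligned set has unequal lengths: {name!r} "
                        f"has {len(seq)}, expected {L}"
                    )
        allowed = (_NUC_CHARS if self.alphabet == NUCLEOTIDE else _AA_CHARS) | _SHARED
        for name, seq in self.records:
            for i, ch in enumerate(seq):
                if ch not in allowed:
                    raise FormatError(
                        f"record {name!r}, position {i + 1}: character {ch!r} "
                        f"outside {self.alphabet} alphabet"
                    )

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    def sequence(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def n_sites(self) -> int:
        if not self.aligned:
            raise ValueError("n_sites is only defined for aligned sets")
        return len(self.records[0][1]) if self.records else 0

    def map_sequences(self, fn, aligned: Optional[bool] = None) -> "SequenceSet":
        """New SequenceSet with ``fn`` applied to every residue string."""
        return SequenceSet(
            [(n, fn(s)) for n, s in self.records],
            alphabet=self.alphabet,
            aligned=self.aligned if aligned is None else aligned,
        )


def read_fasta(path_or_handle, alphabet: str = NUCLEOTIDE) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Lowercase is normalised to uppercase and, for nucleotide data, U to T
    (RNA-style CDS deposits are common).  Records keep file order.  Aligned
    status is inferred: equal lengths over >=2 records mark the set aligned.
    """
    if isinstance(path_or_handle, str) and path_or_handle.lstrip().startswith(">"):
        handle = io.StringIO(path_or_handle)
    elif hasattr(path_or_handle, "read"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if alphabet == NUCLEOTIDE:
                seq = seq.replace("U", "T")
            records.append((rec.id, seq))
    finally:
        if handle is not path_or_handle:
            handle.close()
    lengths = {len(s) for _, s in records}
    aligned = len(records) >= 2 and len(lengths) == 1
    return SequenceSet(records, alphabet=alphabet, aligned=aligned)


def write_fasta(seqs: SequenceSet, path_or_handle, wrap: int = 60) -> None:
    """Write FASTA with lines wrapped at ``wrap`` residues."""
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        for name, seq in seqs:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

class Node:
    """A tree vertex; leaves carry a label, edges an optional length."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Leaf-labelled topology; unrooted trees have a root of degree >= 3."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise FormatError("duplicate leaf labels in tree")
        if any(not n for n in names):
            raise FormatError("empty leaf label")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise FormatError("negative branch length")
            if (
                not self.rooted
                and node is not self.root
                and not node.is_leaf
                and len(node.children) == 1
            ):
                raise FormatError("unrooted tree has a degree-2 internal vertex")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.postorder() if n is not self.root
        )

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add(clone(c))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    def is_binary(self) -> bool:
        """Fully resolved: rooted => 2 children everywhere; unrooted => root
        degree 3 and all other internals with 2 children."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                want = 2 if self.rooted else 3
                if len(self.leaves()) <= 2:
                    continue
                if k != want:
                    return False
            elif k != 2:
                return False
        return True

    # -- bipartitions ------------------------------------------------------
    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Unrooted bipartitions, each canonicalised as the side *not*
        containing the lexicographically smallest leaf."""
        names = self.leaf_names()
        all_leaves = frozenset(names)
        ref = min(names)
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if nontrivial_only and not (2 <= len(side) <= len(all_leaves) - 2):
                continue
            out.add(side)
        return out

    def robinson_foulds(self, other: "Tree") -> int:
        """Unweighted RF distance (symmetric difference of nontrivial splits)."""
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees are on different leaf sets")
        return len(self.splits() ^ other.splits())

    def rooted_at(self, outgroup: Iterable[str]) -> "Tree":
        """Root on the edge separating ``outgroup`` from the rest.

        The outgroup must form one side of an existing bipartition (or be a
        single leaf).  Returns a new rooted Tree whose root has two children:
        the outgroup side and the ingroup side.
        """
        og = frozenset(outgroup)
        names = set(self.leaf_names())
        if not og or not og <= names:
            raise ValueError("outgroup must be a non-empty subset of the leaves")
        work = self.copy()
        # locate a node whose leaf set below equals og or its complement
        # (either way the edge above it is the rooting edge).
        below: dict[int, frozenset] = {}
        target = None
        for node in work.postorder():
            below[id(node)] = (
                frozenset([node.label])
                if node.is_leaf
                else frozenset().union(*(below[id(c)] for c in node.children))
            )
            if node is not work.root and below[id(node)] in (og, names - og):
                target = node
        if target is None:
            raise ValueError(
                "outgroup does not correspond to an edge of the tree; "
                "cannot place the root"
            )
        # reverse the path from target's parent up to the old root.
        path = []
        node = target.parent
        while node is not None:
            path.append(node)
            node = node.parent
        original_lengths = [n.length for n in path]
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
        path[0].children.remove(target)
        for i in range(len(path) - 1):
            path[i].add(path[i + 1])
            path[i + 1].length = original_lengths[i]
        half = None if target.length is None else target.length / 2.0
        target.parent = None
        target.length = half
        path[0].length = half
        new_root = Node()
        new_root.add(target)
        new_root.add(path[0])
        _suppress_unifurcations(new_root)
        return Tree(new_root, rooted=True)

    # -- serialization -----------------------------------------------------
    def newick(self, precision: int = 6) -> str:
        return write_newick(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<Tree {kind} {len(self.leaves())} leaves>"


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        changed = True
        while changed:
            changed = False
            for c in list(node.children):
                if not c.is_leaf and len(c.children) == 1:
                    g = c.children[0]
                    if g.length is not None or c.length is not None:
                        g.length = (g.length or 0.0) + (c.length or 0.0)
                    node.children[node.children.index(c)] = g
                    g.parent = node
                    changed = True
        stack.extend(node.children)


_LABEL_SPECIALS = re.compile(r"[\s()\[\]{}:;,'\"]")


def _quote_label(label: str) -> str:
    if _LABEL_SPECIALS.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize to Newick; labels with special characters are quoted."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            core = _quote_label(node.label or "")
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                core += _quote_label(node.label)
        if node.length is not None and node is not tree.root:
            core += f":{node.length:.{precision}g}"
        return core

    return fmt(tree.root) + ";"


def read_newick(path_or_string) -> Tree:
    """Parse Newick (path, handle or literal string) into a :class:`Tree`.

    Rootedness is inferred from the root degree: a bifurcating root is taken
    as rooted, a trifurcation (or higher) as unrooted, unless the string
    carries an explicit ``[&R]``/``[&U]`` hint, which dendropy honours.
    """
    if hasattr(path_or_string, "read"):
        text = path_or_string.read()
    elif isinstance(path_or_string, str) and (
        "(" in path_or_string or path_or_string.strip().endswith(";")
    ):
        text = path_or_string
    else:
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.is_leaf():
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        if not dnode.is_leaf() and dnode.label:
            node.label = dnode.label
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    if "[&R]" in text:
        rooted = True
    elif "[&U]" in text:
        rooted = False
    else:
        rooted = len(root.children) == 2 and not root.is_leaf
    _suppress_unifurcations(root)
    if root.children and len(root.children) == 1 and not root.is_leaf:
        only = root.children[0]
        if not only.is_leaf:
            only.parent = None
            root = only
    return Tree(root, rooted=rooted)


# ---------------------------------------------------------------------------
# TNT / Hennig86 xread
# ---------------------------------------------------------------------------

def _sanitize_taxon(name: str) -> str:
    return re.sub(r"\s+", "_", name.strip())


def write_tnt_matrix(matrix, path_or_handle, title: str = "phylomask export") -> None:
    """Write a character matrix as a TNT ``xread`` block.

    ``matrix`` may be a nucleotide :class:`SequenceSet` or a
    ``parsimony_engine.CharacterMatrix`` (anything exposing ``taxa`` and
    ``cell_chars()``).  ``N`` cells are written as ``N`` — TNT reads N as
    "any nucleotide", which preserves gap information — and only true
    any-nucleotide-or-gap cells are written as ``?``.
    """
    if isinstance(matrix, SequenceSet):
        taxa = matrix.names
        rows = [seq for _, seq in matrix]
        if not matrix.aligned and len({len(r) for r in rows}) > 1:
            raise ValueError("TNT export requires an aligned matrix")
    else:
        taxa = list(matrix.taxa)
        rows = matrix.cell_chars()
    if not taxa or not rows or len(rows[0]) == 0:
        raise ValueError("cannot write an empty matrix (0 taxa or 0 sites)")
    clean = [_sanitize_taxon(t) for t in taxa]
    if len(set(clean)) != len(clean):
        dup = next(c for i, c in enumerate(clean) if c in clean[:i])
        raise FormatError(f"taxon name collision after sanitization: {dup!r}")
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        handle.write("xread\n")
        handle.write(f"'{title}'\n")
        handle.write(f"{len(rows[0])} {len(taxa)}\n")
        for name, row in zip(clean, rows):
            handle.write(f"{name} {row}\n")
        handle.write(";\n")
    finally:
        if own:
            handle.close()
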