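"""Codon-aware alignment transformations that strip GC-mutational-bias signal.

Grass (monocot) genes carry a strong G+C substitution bias, concentrated at
third codon positions, which creates convergent compositional signal that can
mislead tree inference.  The transformations here remove that signal while
keeping as much genuine historical information as possible:

* :func:`back_translate`      — thread original codons through a protein
  alignment, so the nucleotide alignment inherits the amino-acid gaps.
* :func:`strip_third_positions` — drop every third codon position.
* :func:`mask_gc_to_n`        — replace G and C with N ("any nucleotide"),
  leaving only A<->T transformations informative.
* :func:`serine_mask`         — keep only first and second positions of serine
  codons: the first can only be T or A and the second only C or G, so those
  columns are immune to a GC bias by construction.
* :func:`to_question_marks`   — recode N and gaps as '?' ("any nucleotide or
  gap"), emulating analyses that treat both as missing.
* :func:`trim_gappy_blocks`   — Gblocks-style removal of gap-rich columns
  (gaps allowed in up to half of the rows by default) and of short surviving
  column runs, with remaining gaps rewritten to N.
* :func:`flag_suspect_sequences` — pseudogene screen: flags sequences that are
  about half the typical length, or sit on a terminal branch about twice as
  long as their sister's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .seq_io import NUCLEOTIDE, SequenceSet, Tree

logger = logging.getLogger(__name__)

SERINE_CODONS = frozenset({"TCT", "TCC", "TCA", "TCG", "AGT", "AGC"})
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)


@dataclass
class CodonAlignment:
    """A frame-aware nucleotide alignment (length divisible by 3)."""

    seqs: SequenceSet
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.seqs.alphabet != NUCLEOTIDE:
            raise ValueError("CodonAlignment requires nucleotide sequences")
        if self.seqs.records and not self.seqs.aligned:
            if len({len(s) for _, s in self.seqs.records}) == 1:
                self.seqs = SequenceSet(
                    self.seqs.records, alphabet=NUCLEOTIDE, aligned=True
                )
            else:
                raise ValueError("CodonAlignment requires aligned sequences")
        if self.seqs.records and self.seqs.n_sites % 3 != 0:
            raise ValueError(
                f"aligned length {self.seqs.n_sites} is not a multiple of 3"
            )

    @property
    def taxa(self) -> list[str]:
        return self.seqs.names

    @property
    def n_codons(self) -> int:
        return self.seqs.n_sites // 3 if self.seqs.records else 0

    def codons(self, taxon: str) -> list[str]:
        s = self.seqs.sequence(taxon)
        return [s[i : i + 3] for i in range(0, len(s), 3)]


def translate_codon(codon: str) -> str:
    """Standard-code translation; gaps give '-', ambiguity gives 'X'."""
    codon = codon.upper()
    if codon == "---":
        return "-"
    if codon in _CODON_TO_AA:
        return _CODON_TO_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"


def back_translate(aa_alignment: SequenceSet, cds: SequenceSet) -> CodonAlignment:
    """Replace each aligned amino acid by its original codon.

    Every amino-acid gap becomes ``---`` so gaps remain whole codons.  A
    terminal stop codon on the CDS is trimmed with a warning; any codon whose
    translation disagrees with the aligned residue raises (this is the frame
    shift / wrong-CDS guard).
    """
    if set(aa_alignment.names) != set(cds.names):
        missing = set(aa_alignment.names) ^ set(cds.names)
        raise ValueError(f"taxon sets differ between protein and CDS: {missing}")
    out = []
    for name, aa in aa_alignment:
        nt = cds.sequence(name)
        aa_res = aa.replace("-", "")
        if len(nt) == 3 * len(aa_res) + 3 and nt[-3:].upper() in STOP_CODONS:
            warnings.warn(
                f"{name}: trimming terminal stop codon {nt[-3:]}", stacklevel=2
            )
            nt = nt[:-3]
        if len(nt) != 3 * len(aa_res):
            raise ValueError(
                f"{name}: CDS length {len(nt)} does not match "
                f"3 x {len(aa_res)} ungapped residues"
            )
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        pieces, k = [], 0
        for col, res in enumerate(aa):
            if res == "-":
                pieces.append("---")
                continue
            codon = codons[k]
            k += 1
            trans = translate_codon(codon)
            if res.upper() not in (trans, "X") and trans != "X":
                raise ValueError(
                    f"{name}: codon {codon} at alignment column {col + 1} "
                    f"translates to {trans}, aligned residue is {res} "
                    "(frame shift or wrong CDS?)"
                )
            pieces.append(codon)
        out.append((name, "".join(pieces)))
    return CodonAlignment(
        SequenceSet(out, alphabet=NUCLEOTIDE, aligned=True),
        provenance="back_translate",
    )


def strip_third_positions(aln: CodonAlignment) -> SequenceSet:
    """Keep only first and second codon positions (output length 2/3)."""

    def strip(s: str) -> str:
        return "".join(ch for i, ch in enumerate(s) if i % 3 != 2)

    return aln.seqs.map_sequences(strip)


def mask_gc_to_n(seqs: SequenceSet) -> SequenceSet:
    """Replace every G and C with N; only A<->T changes stay informative."""
    if seqs.alphabet != NUCLEOTIDE:
        raise ValueError("mask_gc_to_n expects nucleotide sequences")
    table = str.maketrans("GC", "NN")
    return seqs.map_sequences(lambda s: s.translate(table))


def serine_mask(aln: CodonAlignment) -> SequenceSet:
    """Keep first/second positions of serine codons only, then drop thirds.

    Non-serine codons contribute ``NN``; all-gap codons contribute ``--``.
    Codons containing N/?/partial gaps are conservatively masked (logged),
    never guessed to be serine.  Every retained informative first position is
    T or A and every second position is C or G, which is what makes this
    encoding immune to a GC bias.
    """
    out = []
    for name, seq in aln.seqs:
        pieces = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3].upper()
            if all(c == "-" for c in codon):
                pieces.append("--")
            elif codon in SERINE_CODONS:
                pieces.append(codon[:2])
            else:
                if any(c in "N?-" for c in codon):
                    logger.debug(
                        "%s codon %d (%s) ambiguous; masked", name, i // 3 + 1, codon
                    )
                pieces.append("NN")
        out.append((name, "".join(pieces)))
    return SequenceSet(out, alphabet=NUCLEOTIDE, aligned=True)


def to_question_marks(seqs: SequenceSet) -> SequenceSet:
    """Recode every N and gap as '?' (any nucleotide *or* gap)."""
    if seqs.alphabet != NUCLEOTIDE:
        raise ValueError("to_question_marks expects nucleotide sequences")
    table = str.maketrans("N-", "??")
    return seqs.map_sequences(lambda s: s.translate(table))


def trim_gappy_blocks(
    seqs: SequenceSet,
    max_gap_fraction: float = 0.5,
    min_block: int = 5,
    replace_remaining_gaps_with: str = "N",
) -> tuple[SequenceSet, list[int]]:
    """Drop gap-rich columns and short surviving blocks (Gblocks-style).

    Columns whose gap fraction exceeds ``max_gap_fraction`` are removed; runs
    of surviving columns shorter than ``min_block`` (in original coordinates)
    are removed too.  Remaining gaps are rewritten to
    ``replace_remaining_gaps_with``.  Returns the trimmed set and the kept
    column indices, 1-based in the original alignment.
    """
    if not seqs.aligned:
        raise ValueError("trim_gappy_blocks requires an aligned input")
    n_taxa = len(seqs)
    n_sites = seqs.n_sites
    rows = [s for _, s in seqs]
    kept: list[int] = []
    for j in range(n_sites):
        gaps = sum(1 for r in rows if r[j] == "-")
        if gaps / n_taxa <= max_gap_fraction:
            kept.append(j)
    # prune runs of contiguous kept columns shorter than min_block
    runs: list[list[int]] = []
    for j in kept:
        if runs and j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])
    kept = [j for run in runs if len(run) >= min_block for j in run]
    if not kept:
        warnings.warn("trim_gappy_blocks removed every column", stacklevel=2)
    out = []
    for name, s in seqs:
        trimmed = "".join(s[j] for j in kept)
        trimmed = trimmed.replace("-", replace_remaining_gaps_with)
        out.append((name, trimmed))
    trimmed_set = SequenceSet(out, alphabet=seqs.alphabet, aligned=True)
    return trimmed_set, [j + 1 for j in kept]


def flag_suspect_sequences(
    seqs: SequenceSet,
    tree: Optional[Tree] = None,
    length_ratio: float = 0.5,
    branch_ratio: float = 2.0,
) -> list[tuple[str, list[str]]]:
    """Pseudogene screen: short sequences and long terminal branches.

    A sequence is flagged when its ungapped length is at most
    ``length_ratio`` times the median ungapped length of the *other*
    sequences (leave-one-out, so a very short suspect cannot drag the
    reference down) — the "about half the number of nucleotides" symptom —
    and, when a tree with branch lengths is supplied, when its terminal
    branch is at least ``branch_ratio`` times the mean of its sister
    branches at the same vertex (the "twice as long as its sister" symptom).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to screen")
    reasons: dict[str, list[str]] = {}
    lengths = {name: len(s.replace("-", "")) for name, s in seqs}
    for name, L in lengths.items():
        med = median(v for k, v in lengths.items() if k != name)
        if L <= length_ratio * med:
            reasons.setdefault(name, []).append(
                f"ungapped length {L} <= {length_ratio:g} x median {med:g} "
                "of the remaining sequences"
            )
    if tree is not None:
        unknown = set(tree.leaf_names()) - set(seqs.names)
        if unknown:
            raise ValueError(f"tree leaves not in sequence set: {sorted(unknown)}")
        if not tree.has_branch_lengths():
            warnings.warn(
                "tree lacks branch lengths; applying length criterion only",
                stacklevel=2,
            )
        else:
            for leaf in tree.leaves():
                sibs = [
                    c.length
                    for c in leaf.parent.children
                    if c is not leaf and c.length is not None
                ]
                if not sibs:
                    continue
                sister = sum(sibs) / len(sibs)
                if sister > 0 and leaf.length >= branch_ratio * sister:
                    reasons.setdefault(leaf.label, []).append(
                        f"terminal branch {leaf.length:g} >= {branch_ratio:g} x "
                        f"sister branch {sister:g}"
                    )
    return sorted((name, why) for name, why in reasons.items())
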