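# Methods

## The masking transforms

All transforms operate on characters, never on alignment coordinates, so
column provenance survives composition.  The canonical chain mirrors how a
GC-biased nucleotide alignment is prepared for parsimony analysis:

1. **Back-translation.**  Each aligned amino acid is replaced by its original
   codon; amino-acid gaps become whole `---` codons, so the nucleotide
   alignment inherits the protein alignment's gap structure and the reading
   frame is exact.  Every codon is checked against its aligned residue under
   the standard genetic code; a disagreement aborts with the position (it
   almost always means a frame shift or the wrong CDS).  A terminal stop on
   the CDS is trimmed with a warning; internal stops fail the residue check.
2. **Third-position removal** keeps positions 1–2 of every codon (output
   length exactly 2/3 of input).
3. **G/C → N.**  `N` is "any nucleotide": the cell still excludes the gap, so
   gap information survives while every G/C difference becomes invisible.
   Only A↔T transformations remain informative.
4. **Serine coding.**  Codons translating to serine (TCT, TCC, TCA, TCG, AGT,
   AGC) keep their first two positions; all other codons contribute `NN`;
   all-gap codons contribute `--`; third positions are dropped.  The retained
   first position can only be T or A, the second only C or G, so these
   characters cannot carry a GC compositional signal at all.  Codons
   containing N, ? or partial gaps are conservatively masked (logged, never
   guessed to be serine).
5. **N/gap → ?** emulates treating gaps and Ns as plain missing data.
6. **Gappy-block trimming** removes columns whose gap fraction exceeds 0.5
   (gaps allowed in half of the rows), then surviving runs shorter than 5
   columns, and rewrites remaining gaps to N.  This deliberately implements
   only the gap-occupancy part of the Gblocks heuristic — the conservation
   scoring stages are not part of this pipeline's contract — with both
   parameters exposed.

The pseudogene screen flags a sequence when its ungapped length is at most
half the leave-one-out median of the others (a plain median is dragged down
by the suspect itself in small families), and, when a tree with branch
lengths is given, when its terminal branch is at least twice the mean of its
sister branches.

## Parsimony with explicit ambiguity semantics

State sets are bitmasks over A, C, G, T and optionally the gap:

* `N` (and `X`) ⇒ {A,C,G,T} — any nucleotide, **not** a gap;
* `?` ⇒ {A,C,G,T,gap} under `gap_mode="fifth_state"`, {A,C,G,T} under
  `"missing"`;
* `-` ⇒ {gap} under `fifth_state`, full nucleotide ambiguity under
  `missing`;
* IUPAC codes map to their standard subsets.

The distinction matters because the masked alignments are mostly N: an engine
that silently turns N into ? throws away the information that a position is
not a gap.  The TNT export therefore writes N as `N`, never `?`.

**Scoring.**  `fitch_length` runs the set intersection/union pass over the
bitmask rows, vectorised across sites, rooted at an arbitrary leaf
(rooting-invariant; a bifurcating root is spliced first).  It requires binary
trees.  `sankoff_length` is the unit-cost dynamic program over per-state cost
vectors (`min(child, child_min + 1)` folding); it accepts polytomies and is
the engine used to score consensus trees.  The two agree exactly on binary
trees, including fully ambiguous cells — this is checked, not assumed.

**Zero-length-branch collapse.**  For each internal edge, down- and up-pass
cost vectors give the per-site minimum when both endpoints share a state
versus differ; an edge whose minimum possible length over all most
parsimonious reconstructions is zero at every weighted site is contracted.
Collapse happens before deduplication, so searches return polytomous trees
when the data do not separate resolutions.

**Search.**  Random-addition Wagner builds (ties between insertion edges
broken by the seeded generator) followed by SPR or TBR hill climbing
(best-improvement steps, seeded tie-breaks).  After the builds, the pool of
trees at the global minimum is closed under equal-length swaps (plateau
search, bounded by `max_trees`, default 200; an improvement found during
closure restarts it).  This approximates a multi-strategy heuristic search
with a transparent, fully seeded mechanism; the exhaustive enumerator
(feasible to nine taxa, (2n−5)!! topologies) is kept in the package as the
oracle the heuristic is validated against.

**Consensus and bootstrap.**  Bipartitions are canonicalised as the leaf set
not containing the lexicographically smallest leaf, which makes the strict
consensus a laminar-family construction; the result is cross-checked against
an independent tree library in the tests.  The bootstrap resamples site
weights multinomially (same total), runs a reduced-effort search per
pseudoreplicate (default 2 builds — the per-replicate effort is a tunable
the full analysis protocol leaves open), and reports the percentage of
replicates whose strict consensus contains each bipartition.

## Ancestral reconstruction of the morphology character

The five PIN morphology states (1 long, 2 short, 3 reduced, 4
C-terminal-TMD-only, 5 N-terminal-TMD-only) form an unordered character:
every change costs one step.  On a rooted tree (polytomies allowed, so a
strict consensus can be traced directly; generalised Sankoff sums over all
children) the dynamic program computes:

* `min_cost` — equal to the unit-cost parsimony length, independent of root
  placement;
* per-node **MPR sets** from down- plus up-pass vectors: a state belongs to a
  node's set iff fixing it there still achieves `min_cost`;
* the exact **number of equally parsimonious reconstructions** by a
  product-sum over optimal backpointers — no enumeration needed.  The count
  ranges over assignments to internal nodes; ambiguous leaves resolve freely
  and do not multiply the count.

No ACCTRAN/DELTRAN resolution is imposed: the full MPR set is reported, and
the reconstructions themselves can be enumerated below a cap.  Unrooted
input trees are rooted on the edge to a stated outgroup (in the motivating
analyses, the moss copies); the outgroup must correspond to an edge of the
tree.

## PIN classification

A protein is summarised by its length and its predicted TMD intervals
(1-based inclusive).  The central hydrophilic loop is the largest gap between
consecutive TMDs; TMDs before/after it form the N- and C-terminal blocks.
Terminal-only types are tested first: type 5 when the C block is empty or
every TMD ends within the first half of the protein, type 4 symmetrically
for the last half; otherwise the loop length decides — ≥ 200 aa long
(type 1), 100–199 reduced (type 3), shorter short (type 2).  The criteria
are structural; the cutoffs (200/100 aa, terminal fraction 0.5) are package
configuration chosen so that layouts consistent with the packaged 151-gene
reference table classify to their printed scores, and are exposed in
`ClassifierConfig`.  Interval input is mandatory: a TMD count alone cannot
separate the types (five TMDs occur in types 1, 2, 4 and 5 of the reference
table).  Two documented overrides (OsPIN3a, Aco018694) are genes predicted
N-terminal-TMD-only whose sequences are otherwise indistinguishable from
long forms; they are forced to type 1 after structural classification, and
the output records both the forced and the structural type.  TMD intervals
are predictions, and the output carries that disclaimer.

Because the reference table prints lengths, TMD counts and types but not the
intervals themselves, the packaged regression reconstructs a synthetic
layout per row (`simulate_tmd_protein`) satisfying the printed geometry; the
test is therefore a consistency check between the generator's geometry and
the classifier's criteria over all 151 printed rows, not a re-prediction of
real TMD coordinates.

## The simulator and what it does (not) show

Sites evolve independently down a tree under an F81-style model: on a branch
of length *t* a site keeps its state with probability exp(−t/β) and
otherwise draws from the branch's stationary distribution (β normalises *t*
to expected substitutions/site).  Third positions evolve `pos3_rate` times
faster and take a GC-shifted stationary distribution on biased branches; a
branch is biased when every leaf below it carries the same explicit GC3
target, so a target shared by two non-sister leaves biases exactly their
terminal branches — convergence without shared history.  First/second
positions use a symmetric composition (`gc12`).  Optional indels delete
whole codons (deletion-only, inherited down the tree), so the frame always
survives.  Every generator is deterministic in its seed.

The packaged convergence scenario is an eight-taxon balanced tree with
internal branches of 0.025 and terminals of 0.3 substitutions/site at
first/second positions, 1200 codons, `pos3_rate` 35 (terminal third
positions are then saturated: pure composition, no history), GC3 targets 0.8
on the two non-sister leaves `b` and `g` versus 0.5 elsewhere, and GC12 0.35
(mildly AT-rich, as plant coding positions tend to be; this is the signal
that survives G/C→N masking).  These sizes were chosen so that a desk-scale
run (20 replicates, 2 search builds per treatment) exhibits the phenomenon
of interest: the unmasked analysis repeatedly groups the biased pair while
the masked analysis does not, and masking lowers the Robinson–Foulds
distance to the true tree (assessed by a one-sided sign test over
replicates).

What the simulator does **not** emulate: codon structure beyond
position-specific rates (no selection, no dN/dS), among-site rate variation,
alignment error (sequences are generated aligned), insertions, or
nonstationarity beyond the per-branch composition switch.  Passing tests
show that the masking rescues trees from *this* minimal compositional
artifact; they do not show that real PIN/ACO alignments contain no other
confounders.

## Numerical and design choices

* Confidence intervals in the composition summary are normal-approximation
  (mean ± 1.96·sd/√n) with genes as the sampling units; a single-gene group
  reports the mean with CI marked unavailable.  The group comparison of GC
  percentages uses Welch's *t*-test (no variance homogeneity assumed).
* Degenerate *t*-test input (zero variance in both groups, equal means)
  returns t = 0, p = 1 rather than NaN.
* Ties in Wagner insertion, hill-climbing steps and bootstrap resampling are
  all driven by explicit seeds recorded in the results.
* Topology identity is decided by canonical bipartition sets (leaf bitsets
  on the side excluding leaf 0), which is also how duplicate trees are
  removed after collapse.
* Coordinates in user-facing tables are 1-based inclusive; internal storage
  is 0-based half-open.  Lowercase and U are normalised on FASTA input.
* `fitch_length` refuses polytomies rather than silently folding them
  (pairwise folding is only exact on binary trees); polytomous trees are
  scored by `sankoff_length`.

## Problem sizes used in the packaged checks

Heuristic-versus-exhaustive agreement uses 50 seeded 7-taxon × 30-site
matrices in both gap modes (3 builds per search); Fitch-versus-Sankoff uses
200 seeded single-site instances; the masking invariants run over 100
simulated 6-taxon × 30-codon alignments (half with indels); the ancestral
check enumerates 5^k assignments on 100 seeded trees with at most six
internal nodes; the convergence experiment runs 20 replicates of the
packaged scenario.  These sizes keep every check exact (the oracles are
exhaustive) while remaining desk-scale.

## Known limitations

* The search heuristic is plateau-TBR from random-addition starts; it has no
  ratchet/fusing stages, so on large, flat landscapes it may need more
  builds (`builds`, `max_trees`) than a specialised program would.
* `exhaustive_search` hard-refuses above nine taxa.
* The bootstrap's per-replicate effort trades thoroughness for replicate
  count; supports on difficult matrices are conservative.
* The classifier's cutoffs are calibrated to one reference table; proteins
  from families with genuinely different loop geometries need their own
  `ClassifierConfig`.
* Cost-matrix (non-unit) ancestral reconstruction is not exposed.
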