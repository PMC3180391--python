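# Methods

This note documents the models, algorithms and design choices behind
`vdga`, in the order data flows through a run.

## Distances

Two pairwise distance measures feed guide-tree construction.

**DP distance.** Sequences are globally aligned by affine-gap
Needleman–Wunsch (see *Alignment kernel* below) and the distance is the
mismatch fraction `mismatch / alignment length`, in [0, 1]. A "mismatch"
is any column that is not an exact residue–residue match; residue-vs-gap
columns count as mismatches. This keeps the measure within [0, 1], since
the denominator includes gap columns.

**Kimura protein distance.** For two *aligned* rows, columns with a gap in
either row are ignored; `S` is the fraction of exactly matching columns
among the scored ones, `D = 1 − S`, and the distance is
`−ln(1 − D − 0.2·D²)`. Ambiguity codes (B, Z, X) count as matches only
when the characters are identical — partial-match scoring is deliberately
not implemented (exact matching is the operational rule; fractional
schemes vary between implementations and change no downstream decision
here). The correction diverges as `D → 0.8541…` (the positive root of
`1 − D − 0.2D²`); when the log argument falls below 1e−9 the distance is
capped at 10.0 with a `RuntimeWarning`, mirroring common practice in
distance-correction code so that neighbour-joining always receives finite
inputs.

## Alignment kernel

One affine-gap dynamic program (Gotoh three-state recursion) serves both
pairwise and profile–profile alignment; a pairwise alignment is the
1×1-profile case. Gap-cost convention: a run of `n` gap positions costs
`G = g + n·x` in total (so at the defaults `g = −10`, `x = −0.2`, a
length-1 run costs −10.2). Terminal gaps are penalised exactly like
internal ones — the formula admits no end-gap exception, and making one
would change the fitness surface. Traceback ties are broken
diagonal > up > left, making every alignment deterministic.

Profile columns are scored as the unweighted mean of cross-pair
substitution scores, with any pair involving an existing gap scoring 0;
a new gap run inserted into a profile is charged `g + n·x` once per run,
not multiplied by profile size. The mean (rather than the sum) keeps the
match term on a scale independent of profile sizes, so one gap model fits
all merge steps. No position-specific or residue-specific gap-penalty
modulation is applied. The kernel is numba-jitted; the test suite checks
it against pure-Python exhaustive enumeration of all alignments on short
sequences and small profiles.

## Guide trees and weights

Trees are built by neighbour-joining. Ties in the Q criterion are broken
toward the smallest index pair in the current agglomeration order;
negative branch-length estimates are clamped to 0. The final join becomes
the root with the last edge split equally — rooting is otherwise
arbitrary for this package because progressive merge order depends only
on topology. Sequence weights follow the CLUSTAL W idea: each leaf
accumulates, over the edges on its root-to-leaf path, the edge length
divided by the number of leaves sharing that edge; weights are rescaled
to mean 1 (a zero-length or star tree falls back to uniform weights).
Weights are computed once from the initial DP-distance tree (TR1) and
frozen for the whole run, so WSPM values are comparable across
individuals and generations.

Two perturbation mechanisms seed the population. The *split* mechanism
selects each leaf independently with probability 1/2 (redrawing empty or
complete sets), prunes the selected set and its complement into two
subtrees that preserve the base tree's relative branching order, and
joins them under a new root whose two branches get the mean root-child
length of the base tree (perturbed-tree branch lengths are never reused
for weights, so any finite choice is safe). The *shuffle* mechanism
exchanges the labels of two uniformly chosen leaves.

## Fitness

WSPM scores every unordered row pair on its gap–gap-deleted projection:
residue–residue columns contribute `W_ij · PAM250(a, b)` to their original
column's score, and each maximal residue-vs-gap run of length `n` in the
projection contributes `W_ij · (g + n·x)`. Gap–gap columns cost nothing
and neither open nor interrupt a run (projection first, then run
counting — the convention that makes the brute-force oracle unambiguous).
Column-range scores (used by the multiple-point crossover to compare
leading/trailing quarters) treat the slice as a standalone sub-alignment:
all-gap columns inside the slice are dropped and runs truncate at the
slice boundaries, so a run straddling a boundary is charged one opening
per side. Whether such quarter scores should include gap penalties at all
is a genuinely open choice; standalone-slice scoring is the simplest
self-consistent reading and is what ships.

## The genetic algorithm

* **Seeding.** TR1 (DP distances) gives MSA1; the Kimura distances of
  MSA1 give TR2 and MSA2. The remaining `pop_size − 2` individuals come
  from the two mechanisms applied to TR1/TR2, split evenly over the four
  mechanism×tree combinations (remainder to shuffle×TR1). Duplicate trees
  or alignments are redrawn a bounded number of times, then admitted with
  a warning.
* **Selection.** One parent uniform from the top half by fitness, one
  from the bottom half.
* **Single-point crossover.** A cut column is drawn uniformly on the
  interior of the better-scoring parent; the other parent is cut row-wise
  so each row's left piece carries the same residue count (shortest such
  prefix); pieces are exchanged, padded to rectangles (left pieces
  right-padded, right pieces left-padded), all-gap columns removed, and
  the better recombinant kept.
* **Multiple-point crossover.** The leading `ceil(L/4)` columns of each
  parent are scored; the better parent is cut there, the other tailored
  by residue counts; the procedure repeats on the trailing quarter of the
  right pieces; the middle pieces are swapped and the better reassembly
  kept. Fractional quarter boundaries round up (2.5 → 3 columns). If
  tailoring empties a middle piece the better parent is returned
  unchanged with a warning. Parents shorter than 8 columns fall back to
  single-point crossover inside the main loop.
* **Mutation.** One individual is drawn uniformly from the whole
  population; a tree is rebuilt from the Kimura distances of its
  alignment and hill-climbed by leaf-label shuffles (re-aligning after
  each), accepting strict improvements of the loop's best WSPM and
  stopping after `mutation_patience` consecutive failures. The result
  becomes a child only if it strictly beats the source individual.
* **Vertical decomposition.** Columns are split into `k` contiguous
  blocks of near-equal width (the first `L mod k` blocks one column
  wider); each block is gap-stripped per row and re-aligned from scratch
  by the one-stage guide-tree method (DP distances → NJ → progressive);
  rows emptied by stripping re-enter as all-gap rows; the reassembly
  replaces the individual only on strict WSPM improvement. Applied to
  every individual of the initial generation and to every child.
* **Replacement.** Parents and children are pooled, exact duplicates (by
  canonical alignment text) dropped first-seen-kept, and the best
  `pop_size` retained — elitism holds by construction, so the best
  fitness trace is non-decreasing.
* **Termination.** The run stops once the best fitness has not improved
  for `termination_patience` consecutive generations, or at
  `max_generations` (default 1000, a safety cap).

Per 100-individual generation the child budget is 25 single-point + 25
multiple-point crossovers and 50 mutation attempts; failed mutations
simply produce fewer children that generation. A single RNG stream seeded
from the config drives every stochastic choice in a fixed order, so runs
are reproducible byte-for-byte.

## Reference accuracy (SPS / CS)

Residues are identified by (sequence, residue ordinal). SPS is the
fraction of reference residue pairs — two residues of different sequences
sharing a reference column — that also share a column in the test
alignment. CS is the fraction of reference columns whose full residue
content (gaps included) appears as a test column. Both accept an optional
core-column list (a plain list of 0-based reference column indices) to
restrict scoring to annotated regions. Note that CS is not monotone under
arbitrary re-gapping of a test alignment (vacating a column can re-match
a reference column that holds a gap there); the test suite asserts
monotonicity only where it actually holds (SPS under single-row
staggering).

## Synthetic families

`generate_family` draws a random ancestor (uniform over the 20 amino
acids), a random binary topology by successive joins with Uniform(0.5,
1.5) edge lengths rescaled so the mean root-to-leaf depth equals
`tree_depth`, then evolves the sequence down each edge: per-site
substitution probability `1 − exp(−rate·t)` with replacement uniform over
the other 19 residues, and Poisson-many indel events of geometric length
(mean 3), insertions and deletions equally likely. Insertion coordinates
are threaded through a global column registry, so the true alignment of
the leaves is known exactly. Defaults — 8 sequences, ancestor length 150,
substitution rate 0.2, indel rate 0.03, depth 1.0 — produce families at
roughly 50–80% pairwise identity with occasional short indels, the regime
of the curated protein-family benchmarks this class of aligner is usually
evaluated on (small equidistant families, and more divergent ones as the
depth/rate is raised).

What the generator does *not* emulate: sequence-composition bias,
rate heterogeneity across sites, conserved motifs/core blocks, long
terminal extensions, repeated or inverted domains, and orphan sequences
with no close relative. Passing the accuracy tests on these families
therefore shows the machinery optimises its objective and recovers
simulated homology under idealised evolution; it does not certify
benchmark-grade accuracy on real protein families.

## Problem sizes used in tests and the acceptance script

The full-scale operating point (population 100, patience 100) is the
package default but is deliberately not what the test suite runs: the
suite exercises the identical code paths at reduced scale so the whole
run stays inside a desktop-CI budget. The accuracy study
(tests and `scripts/acceptance.py`) uses 10–20 seeded families at the
default family conditions with population 20, three divisions,
termination patience 20 and a mutation hill-climb budget of 10
(a pilot showed budgets of 10 and 50 give indistinguishable SPS here,
at a ~5× runtime difference). The determinism check uses a 6-sequence,
length-80 family. Exhaustive DP verification covers all sequence pairs of
length ≤ 4 over a three-letter alphabet plus a seeded sample of longer
pairs.

## Known limitations

* The progressive kernel is a generic profile aligner: no
  position-specific gap penalties, no iterative refinement, no
  consistency transformation. Absolute WSPM values are therefore not
  comparable to those of other programs, only across individuals of one
  run (which is all the GA needs).
* WSPM optimisation and reference accuracy are correlated but not
  aligned: a strictly better WSPM can have slightly lower SPS (observed
  occasionally in the tests); median accuracy over families is the
  meaningful summary.
* Kimura distances saturate near 85% divergence; beyond that pairs hit
  the cap and tree resolution among them is lost.
* MSF support targets the common GCG dialect (one block header, `.` or
  `~` gaps, standard checksums); exotic variants are out of scope.
* Runs are single-threaded by design (determinism first); population
  evaluation is embarrassingly parallel in principle but not implemented.
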