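"""The vertical-decomposition genetic algorithm (VDGA).

The GA maintains a population of multiple alignments of the same input
sequences, scored by the weighted sum-of-pairs fitness under weights frozen
from the initial guide tree.  Each generation produces children by
single-point and multiple-point column crossovers and by a tree-shuffling
mutation; every individual (initial and child) passes through the vertical
decomposition step — split into k contiguous column blocks, gap-strip and
re-align each block with the guide-tree method, and keep the reassembly
only if the fitness improves.  The best 50% of parents plus children forms
the next generation (duplicates removed), so the best fitness never
decreases; the run stops once it has not improved for a configured number
of consecutive generations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    GAP_BYTE,
    Alignment,
    AlignmentError,
    GapModel,
    Sequence,
    SubstitutionMatrix,
    load_matrix,
)
from .distances import distance_matrix_dp, distance_matrix_kimura
from .progressive import progressive_align
from .scoring import wspm, wspm_range
from .tree import (
    GuideTree,
    WeightVector,
    build_guide_tree,
    clustalw_weights,
    mechanism1_split,
    mechanism2_swap,
)


@dataclass(frozen=True)
class Individual:
    """An alignment with its cached fitness and a lineage tag for logging."""

    alignment: Alignment
    fitness: float
    lineage: str = "init"


class Population:
    """Individuals kept sorted by fitness, best first."""

    def __init__(self, individuals: list[Individual], size: int):
        self.individuals = sorted(
            individuals, key=lambda ind: -ind.fitness
        )
        self.size = size

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, i: int) -> Individual:
        return self.individuals[i]

    @property
    def best(self) -> Individual:
        return self.individuals[0]

    def mean_fitness(self) -> float:
        return float(np.mean([ind.fitness for ind in self.individuals]))


@dataclass(frozen=True)
class GAConfig:
    """Run parameters.

    The defaults are the published operating point: population 100, an even
    crossover/mutation split with crossovers split evenly between single- and
    multiple-point, three vertical divisions, a 50-failure mutation loop and
    termination after 100 generations without improvement of the best score.
    """

    pop_size: int = 100
    crossover_fraction: float = 0.5
    mutation_fraction: float = 0.5
    decomp_k: int = 3
    mutation_patience: int = 50
    termination_patience: int = 100
    max_generations: int = 1000
    seed: int = 0
    matrix: str = "pam250"
    gaps: GapModel = field(default_factory=GapModel)

    def __post_init__(self) -> None:
        if abs(self.crossover_fraction + self.mutation_fraction - 1.0) > 1e-9:
            raise AlignmentError("crossover and mutation fractions must sum to 1")
        if self.decomp_k < 1:
            raise AlignmentError("decomp_k must be >= 1")
        if min(self.mutation_patience, self.termination_patience) < 1:
            raise AlignmentError("patience values must be >= 1")
        if self.pop_size < 2:
            raise AlignmentError("population size must be >= 2")


@dataclass(frozen=True)
class FitnessModel:
    """Frozen scoring context of one GA run: substitution matrix, gap model
    and the sequence weights computed once from the initial guide tree."""

    matrix: SubstitutionMatrix
    gaps: GapModel
    weights: WeightVector

    def score(self, aln: Alignment) -> float:
        return wspm(aln, self.weights, self.matrix, self.gaps).total

    def score_range(self, aln: Alignment, col_from: int, col_to: int) -> float:
        return wspm_range(
            aln, self.weights, self.matrix, self.gaps, col_from, col_to
        ).total


@dataclass
class GenerationStats:
    generation: int
    best_wspm: float
    mean_wspm: float
    children_produced: int
    mutations_failed: int


@dataclass(frozen=True)
class VdgaResult:
    best: Individual
    population: Population
    trace: list[GenerationStats]
    fitness_model: FitnessModel
    tr1: GuideTree
    msa1: Alignment
    config: GAConfig


# ---------------------------------------------------------------------------
# population seeding


def init_population(
    seqs: list[Sequence], cfg: GAConfig, rng: np.random.Generator
) -> tuple[Population, FitnessModel, GuideTree, Alignment]:
    """Seed the population.

    TR1 is the neighbour-joining tree of the DP distances and yields MSA1;
    the Kimura distances of MSA1 give TR2 and MSA2.  The remaining
    individuals come from the split and shuffle mechanisms applied to TR1
    and TR2 (split evenly over the four mechanism-tree combinations, the
    remainder going to shuffle x TR1).  Sequence weights are frozen from TR1
    for the whole run.
    """
    if len(seqs) < 3:
        raise AlignmentError("VDGA needs at least 3 sequences")
    matrix = load_matrix(cfg.matrix)
    dm1 = distance_matrix_dp(seqs, matrix, cfg.gaps)
    tr1 = build_guide_tree(dm1)
    fm = FitnessModel(matrix, cfg.gaps, clustalw_weights(tr1))
    msa1 = progressive_align(seqs, tr1, matrix, cfg.gaps)
    tr2 = build_guide_tree(distance_matrix_kimura(msa1))
    msa2 = progressive_align(seqs, tr2, matrix, cfg.gaps)

    individuals = [Individual(msa1, fm.score(msa1), "init")]
    seen_aln = {msa1.text}
    seen_trees = {tr1.canonical_form, tr2.canonical_form}
    if msa2.text in seen_aln:
        warnings.warn("MSA2 duplicates MSA1; admitted anyway", RuntimeWarning)
    seen_aln.add(msa2.text)
    individuals.append(Individual(msa2, fm.score(msa2), "init"))

    remainder = cfg.pop_size - 2
    q, r = divmod(remainder, 4)
    budget = {
        ("split", 0): q,
        ("split", 1): q,
        ("shuffle", 0): q + r,
        ("shuffle", 1): q,
    }
    bases = (tr1, tr2)
    for (mech, base_idx), count in budget.items():
        for _ in range(count):
            tree = aln = None
            for _attempt in range(20):
                cand = (
                    mechanism1_split(bases[base_idx], rng)
                    if mech == "split"
                    else mechanism2_swap(bases[base_idx], rng)
                )
                if cand.canonical_form in seen_trees:
                    continue
                cand_aln = progressive_align(seqs, cand, matrix, cfg.gaps)
                tree, aln = cand, cand_aln
                if cand_aln.text not in seen_aln:
                    break
            if tree is None:
                tree = mechanism2_swap(bases[base_idx], rng)
                aln = progressive_align(seqs, tree, matrix, cfg.gaps)
            if aln.text in seen_aln:
                warnings.warn(
                    "duplicate individual admitted after bounded redraws",
                    RuntimeWarning,
                )
            seen_trees.add(tree.canonical_form)
            seen_aln.add(aln.text)
            individuals.append(Individual(aln, fm.score(aln), "init"))

    return Population(individuals, cfg.pop_size), fm, tr1, msa1


# ---------------------------------------------------------------------------
# parent selection and crossovers


def select_parents(
    pop: Population, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """One parent uniform from the top half by fitness, one from the bottom
    half; the first returned parent never scores below the second."""
    n = len(pop)
    if n < 2:
        raise AlignmentError("need at least two individuals to select parents")
    split = (n + 1) // 2
    pa = pop[int(rng.integers(0, split))]
    pb = pop[int(rng.integers(split, n))]
    return pa, pb


def _cut_by_residue_counts(
    matrix: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Per-row cut positions: the shortest prefix of each row containing
    ``counts[i]`` residues (0 -> empty prefix)."""
    res = matrix != GAP_BYTE
    cum = np.cumsum(res, axis=1)
    cuts = np.empty(matrix.shape[0], dtype=np.intp)
    for i in range(matrix.shape[0]):
        k = counts[i]
        cuts[i] = 0 if k == 0 else int(np.searchsorted(cum[i], k)) + 1
    return cuts


def _pad_pieces(
    matrix: np.ndarray, cuts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split each row at its cut and pad to rectangles: left pieces are
    right-padded, right pieces left-padded with gaps."""
    n, L = matrix.shape
    lw = int(cuts.max())
    rw = int((L - cuts).max())
    left = np.full((n, lw), GAP_BYTE, dtype=np.uint8)
    right = np.full((n, rw), GAP_BYTE, dtype=np.uint8)
    for i in range(n):
        c = cuts[i]
        left[i, :c] = matrix[i, :c]
        if L - c:
            right[i, rw - (L - c):] = matrix[i, c:]
    return left, right


def _child_from_pieces(
    pieces: list[np.ndarray], ids, fm: FitnessModel
) -> tuple[Alignment, float]:
    mat = np.concatenate([p for p in pieces if p.shape[1] > 0], axis=1)
    keep = (mat != GAP_BYTE).any(axis=0)
    aln = Alignment(np.ascontiguousarray(mat[:, keep]), ids)
    return aln, fm.score(aln)


def single_point_crossover(
    pa: Individual,
    pb: Individual,
    fm: FitnessModel,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> Individual:
    """Single-point column crossover.

    A cut column is drawn on the better-scoring parent; the other parent is
    cut row-wise so each row's left piece carries the same residue count;
    pieces are exchanged, padded to rectangles, canonicalised and scored,
    and the better recombinant becomes the child.
    """
    better, other = (pa, pb) if pa.fitness >= pb.fitness else (pb, pa)
    L = better.alignment.L
    if L < 2:
        raise AlignmentError("better parent too short for a column cut")
    ids = better.alignment.seq_ids
    last_err: Exception | None = None
    for _ in range(max_retries):
        c = int(rng.integers(1, L))
        a_mat = better.alignment.matrix
        counts = np.count_nonzero(a_mat[:, :c] != GAP_BYTE, axis=1)
        a_left, a_right = a_mat[:, :c], a_mat[:, c:]
        cuts = _cut_by_residue_counts(other.alignment.matrix, counts)
        b_left, b_right = _pad_pieces(other.alignment.matrix, cuts)
        try:
            child1 = _child_from_pieces([a_left, b_right], ids, fm)
            child2 = _child_from_pieces([b_left, a_right], ids, fm)
        except AlignmentError as exc:  # degenerate cut; redraw
            last_err = exc
            continue
        aln, fit = child1 if child1[1] >= child2[1] else child2
        return Individual(aln, fit, "crossover")
    raise AlignmentError(f"single-point crossover failed: {last_err}")


def _score_leading(fm: FitnessModel, aln: Alignment, n: int) -> float:
    return fm.score_range(aln, 0, n)


def multi_point_crossover(
    pa: Individual,
    pb: Individual,
    fm: FitnessModel,
    rng: np.random.Generator,
) -> Individual:
    """Two-cut crossover exchanging the middle pieces.

    Step 1 compares the WSPM of each parent's leading 25% of columns
    (fractional boundaries round up); the better parent is cut there and the
    other is tailored by residue counts.  Step 2 repeats the procedure on
    the trailing 25% of the remaining right pieces.  The middle pieces are
    swapped and the better of the two reassemblies becomes the child.
    """
    if pa.alignment.L < 8 or pb.alignment.L < 8:
        raise AlignmentError("multi-point crossover needs parents with L >= 8")
    ids = pa.alignment.seq_ids

    # Step 1: leading quarter.
    na = math.ceil(pa.alignment.L / 4)
    nb = math.ceil(pb.alignment.L / 4)
    sa = _score_leading(fm, pa.alignment, na)
    sb = _score_leading(fm, pb.alignment, nb)
    if sa >= sb:
        first, second, cut = pa, pb, na
    else:
        first, second, cut = pb, pa, nb
    f_mat = first.alignment.matrix
    a1, a2 = f_mat[:, :cut], f_mat[:, cut:]
    counts = np.count_nonzero(a1 != GAP_BYTE, axis=1)
    cuts = _cut_by_residue_counts(second.alignment.matrix, counts)
    b1, b2 = _pad_pieces(second.alignment.matrix, cuts)

    # Step 2: trailing quarter of the right pieces.
    def tail_score(mat: np.ndarray, n_cols: int) -> float:
        sub = mat[:, mat.shape[1] - n_cols :]
        keep = (sub != GAP_BYTE).any(axis=0)
        if not keep.any():
            return -np.inf
        aln = Alignment(np.ascontiguousarray(sub[:, keep]), ids)
        return fm.score(aln)

    ma = math.ceil(a2.shape[1] / 4)
    mb = math.ceil(b2.shape[1] / 4)
    ta = tail_score(a2, ma)
    tb = tail_score(b2, mb)
    if ta >= tb:
        lead_mid, lead_tail_cut = a2, a2.shape[1] - ma
        trail_mat = b2
        a_is_leader = True
    else:
        lead_mid, lead_tail_cut = b2, b2.shape[1] - mb
        trail_mat = a2
        a_is_leader = False
    mid_l = lead_mid[:, :lead_tail_cut]
    tail_l = lead_mid[:, lead_tail_cut:]
    tail_counts = np.count_nonzero(tail_l != GAP_BYTE, axis=1)
    total_res = np.count_nonzero(trail_mat != GAP_BYTE, axis=1)
    cuts2 = _cut_by_residue_counts(trail_mat, total_res - tail_counts)
    mid_t, tail_t = _pad_pieces(trail_mat, cuts2)

    if a_is_leader:
        a2p, a3, b2p, b3 = mid_l, tail_l, mid_t, tail_t
    else:
        a2p, a3, b2p, b3 = mid_t, tail_t, mid_l, tail_l

    if a2p.shape[1] == 0 or b2p.shape[1] == 0:
        warnings.warn(
            "multi-point crossover produced an empty middle piece; "
            "returning the better parent",
            RuntimeWarning,
        )
        best = pa if pa.fitness >= pb.fitness else pb
        return Individual(best.alignment, best.fitness, "crossover")

    try:
        child1 = _child_from_pieces([a1, b2p, a3], ids, fm)
        child2 = _child_from_pieces([b1, a2p, b3], ids, fm)
    except AlignmentError:
        best = pa if pa.fitness >= pb.fitness else pb
        return Individual(best.alignment, best.fitness, "crossover")
    aln, fit = child1 if child1[1] >= child2[1] else child2
    return Individual(aln, fit, "crossover")


# ---------------------------------------------------------------------------
# mutation and vertical decomposition


def mutate(
    pop: Population,
    cfg: GAConfig,
    fm: FitnessModel,
    seqs: list[Sequence],
    rng: np.random.Generator,
) -> Optional[Individual]:
    """Tree-shuffling mutation.

    One individual is drawn uniformly; a guide tree is rebuilt from the
    Kimura distances of its alignment and hill-climbed by leaf-label swaps,
    realigning after each swap and accepting swaps that improve the loop's
    best WSPM.  The loop stops after ``mutation_patience`` consecutive
    failures.  The best alignment found is returned as a child only if it
    strictly beats the source individual; otherwise the generation is
    unaffected and ``None`` is returned.
    """
    src = pop[int(rng.integers(0, len(pop)))]
    try:
        tree = build_guide_tree(distance_matrix_kimura(src.alignment))
    except AlignmentError:
        return None
    best_tree = tree
    best_aln = progressive_align(seqs, tree, fm.matrix, fm.gaps)
    best_fit = fm.score(best_aln)
    failures = 0
    while failures < cfg.mutation_patience:
        cand_tree = mechanism2_swap(best_tree, rng)
        cand_aln = progressive_align(seqs, cand_tree, fm.matrix, fm.gaps)
        cand_fit = fm.score(cand_aln)
        if cand_fit > best_fit:
            best_tree, best_aln, best_fit = cand_tree, cand_aln, cand_fit
            failures = 0
        else:
            failures += 1
    if best_fit > src.fitness:
        return Individual(best_aln, best_fit, "mutation")
    return None


def vertical_division(ind: Individual, k: int, fm: FitnessModel) -> Individual:
    """Vertical decomposition with keep-if-better.

    The alignment's columns are split into k contiguous blocks of
    near-equal width (the first L mod k blocks one column wider).  Each
    block is gap-stripped per row and re-aligned from scratch with the
    guide-tree method (DP distances -> NJ -> progressive); rows emptied by
    stripping re-enter as all-gap rows.  The re-assembled alignment replaces
    the individual only if its WSPM strictly improves, so the fitness never
    decreases.
    """
    aln = ind.alignment
    if k < 1:
        raise AlignmentError("number of divisions must be >= 1")
    if k > aln.L:
        raise AlignmentError(f"cannot split {aln.L} columns into {k} blocks")
    base, extra = divmod(aln.L, k)
    blocks: list[np.ndarray] = []
    start = 0
    for b in range(k):
        width = base + (1 if b < extra else 0)
        block = aln.matrix[:, start : start + width]
        start += width
        stripped = [
            bytes(row[row != GAP_BYTE]).decode("ascii") for row in block
        ]
        nonempty = [i for i, s in enumerate(stripped) if s]
        if len(nonempty) >= 2:
            sub_seqs = [Sequence(aln.seq_ids[i], stripped[i]) for i in nonempty]
            dm = distance_matrix_dp(sub_seqs, fm.matrix, fm.gaps)
            sub_tree = build_guide_tree(dm)
            sub_aln = progressive_align(sub_seqs, sub_tree, fm.matrix, fm.gaps)
            width_new = sub_aln.L
            out = np.full((aln.N, width_new), GAP_BYTE, dtype=np.uint8)
            out[nonempty] = sub_aln.matrix
        elif len(nonempty) == 1:
            i = nonempty[0]
            row = block[i][block[i] != GAP_BYTE]
            out = np.full((aln.N, len(row)), GAP_BYTE, dtype=np.uint8)
            out[i] = row
        else:  # all-gap block (cannot happen on canonical alignments)
            continue
        blocks.append(out)
    mat = np.concatenate(blocks, axis=1)
    keep = (mat != GAP_BYTE).any(axis=0)
    new_aln = Alignment(np.ascontiguousarray(mat[:, keep]), aln.seq_ids)
    new_fit = fm.score(new_aln)
    if new_fit > ind.fitness:
        return Individual(new_aln, new_fit, "decomposition")
    return ind


# ---------------------------------------------------------------------------
# generational replacement and the main loop


def next_generation(
    parents: Population, children: list[Individual]
) -> Population:
    """Best-half replacement: parents and children are pooled, exact
    duplicates (by canonical alignment text) dropped keeping the first seen,
    and the top ``pop_size`` by fitness retained.  The previous best is in
    the pool, so elitism holds by construction."""
    pool = list(parents.individuals) + list(children)
    seen: set[str] = set()
    unique: list[Individual] = []
    for ind in pool:
        key = ind.alignment.text
        if key in seen:
            continue
        seen.add(key)
        unique.append(ind)
    unique.sort(key=lambda ind: -ind.fitness)
    if len(unique) < parents.size:
        warnings.warn(
            "population shrank below its nominal size after deduplication",
            RuntimeWarning,
        )
        return Population(unique, parents.size)
    return Population(unique[: parents.size], parents.size)


def run_vdga(seqs: list[Sequence], cfg: GAConfig) -> VdgaResult:
    """Run the full GA and return the best individual plus the per-generation
    best/mean fitness trace."""
    rng = np.random.default_rng(cfg.seed)
    pop, fm, tr1, msa1 = init_population(seqs, cfg, rng)

    pop = Population(
        [vertical_division(ind, cfg.decomp_k, fm) for ind in pop.individuals],
        cfg.pop_size,
    )

    n_single = int(cfg.pop_size * cfg.crossover_fraction / 2)
    n_multi = int(cfg.pop_size * cfg.crossover_fraction / 2)
    n_mut = int(cfg.pop_size * cfg.mutation_fraction)

    trace = [
        GenerationStats(0, pop.best.fitness, pop.mean_fitness(), len(pop), 0)
    ]
    stall = 0
    best_fit = pop.best.fitness
    generation = 0
    while stall < cfg.termination_patience and generation < cfg.max_generations:
        generation += 1
        children: list[Individual] = []
        mutations_failed = 0
        # a population collapsed to one unique alignment cannot recombine
        if len(pop) >= 2:
            for _ in range(n_single):
                pa, pb = select_parents(pop, rng)
                children.append(single_point_crossover(pa, pb, fm, rng))
            for _ in range(n_multi):
                pa, pb = select_parents(pop, rng)
                if pa.alignment.L < 8 or pb.alignment.L < 8:
                    children.append(single_point_crossover(pa, pb, fm, rng))
                else:
                    children.append(multi_point_crossover(pa, pb, fm, rng))
        for _ in range(n_mut):
            child = mutate(pop, cfg, fm, seqs, rng)
            if child is None:
                mutations_failed += 1
            else:
                children.append(child)
        children = [vertical_division(c, cfg.decomp_k, fm) for c in children]
        pop = next_generation(pop, children)
        if pop.best.fitness > best_fit:
            best_fit = pop.best.fitness
            stall = 0
        else:
            stall += 1
        trace.append(
            GenerationStats(
                generation,
                pop.best.fitness,
                pop.mean_fitness(),
                len(children),
                mutations_failed,
            )
        )
    return VdgaResult(pop.best, pop, trace, fm, tr1, msa1, cfg)
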