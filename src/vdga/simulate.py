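"""Synthetic protein-family generator with a recorded true alignment.

Families are produced by evolving a random ancestor down a random binary
tree, applying per-site substitutions and geometric-length indels on each
edge.  Insertion/deletion coordinates are tracked through a global column
registry, so the generator knows the true multiple alignment of the leaves
— the ground truth against which SPS/CS accuracy is measured in tests.

The defaults emulate a moderately divergent family of eight homologues of
length ~150 (roughly 50-70% pairwise identity with occasional short indels),
the regime the alignment benchmark families this package targets live in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import AMINO_ACIDS, Alignment, AlignmentError, Sequence


@dataclass(frozen=True)
class FamilyParams:
    """Knobs of the family simulator.

    ``substitution_rate`` and ``indel_rate`` are per-site rates per unit
    branch length; ``tree_depth`` is the mean root-to-leaf path length, so a
    depth-1 tree with substitution rate 0.2 gives ~18% expected substitutions
    per site along a root-leaf path.
    """

    n: int = 8
    length: int = 150
    substitution_rate: float = 0.2
    indel_rate: float = 0.03
    mean_indel_length: float = 3.0
    tree_depth: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise AlignmentError("substitution_rate must be in [0, 1]")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise AlignmentError("indel_rate must be in [0, 1]")
        if self.n < 2:
            raise AlignmentError("a family needs at least 2 descendants")
        if self.length < 10:
            raise AlignmentError("ancestor length must be >= 10")
        if self.mean_indel_length < 1.0:
            raise AlignmentError("mean indel length must be >= 1")
        if self.tree_depth <= 0:
            raise AlignmentError("tree depth must be positive")


@dataclass(frozen=True)
class SyntheticFamily:
    """A simulated family: ancestor, descendants and their true alignment."""

    ancestor: Sequence
    descendants: list[Sequence]
    true_alignment: Alignment
    params: FamilyParams
    seed: int


class _Node:
    __slots__ = ("children", "length")

    def __init__(self) -> None:
        self.children: list[tuple[_Node, float]] = []
        self.length = 0.0


def _random_tree(n: int, depth: float, rng: np.random.Generator) -> _Node:
    """Random binary topology by successive joins; edges rescaled so the
    mean root-to-leaf path length equals ``depth``."""
    lineages = [_Node() for _ in range(n)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = _Node()
        for child in (lineages[i], lineages[j]):
            parent.children.append((child, float(rng.uniform(0.5, 1.5))))
        lineages[j:j + 1] = []
        lineages[i] = parent
    root = lineages[0]

    depths: list[float] = []

    def walk(node: _Node, d: float) -> None:
        if not node.children:
            depths.append(d)
        for child, blen in node.children:
            walk(child, d + blen)

    walk(root, 0.0)
    scale = depth / (sum(depths) / len(depths))

    def rescale(node: _Node) -> None:
        node.children = [(c, b * scale) for c, b in node.children]
        for c, _ in node.children:
            rescale(c)

    rescale(root)
    return root


def generate_family(
    params: Optional[FamilyParams] = None, seed: int = 0, **overrides
) -> SyntheticFamily:
    """Simulate a family; identical ``(params, seed)`` give identical output.

    Keyword overrides patch individual :class:`FamilyParams` fields, e.g.
    ``generate_family(seed=3, n=6, length=80)``.
    """
    params = replace(params or FamilyParams(), **overrides)
    rng = np.random.default_rng(seed)

    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    ancestor_res = rng.choice(aa, size=params.length)

    # Global column registry: every site ever created gets a unique id; the
    # master list keeps ids in left-to-right alignment order.
    master: list[int] = list(range(params.length))
    next_id = params.length

    root = _random_tree(params.n, params.tree_depth, rng)

    leaf_states: list[tuple[list[int], dict[int, int]]] = []

    def evolve(cols: list[int], res: dict[int, int], blen: float):
        nonlocal next_id
        cols = list(cols)
        res = dict(res)
        p_sub = 1.0 - np.exp(-params.substitution_rate * blen)
        if p_sub > 0 and cols:
            hits = np.nonzero(rng.random(len(cols)) < p_sub)[0]
            for k in hits:
                old = res[cols[k]]
                choices = aa[aa != old]
                res[cols[k]] = int(rng.choice(choices))
        n_events = rng.poisson(params.indel_rate * blen * len(cols))
        for _ in range(n_events):
            size = int(rng.geometric(1.0 / params.mean_indel_length))
            if rng.random() < 0.5 and len(cols) - size >= 10:
                # deletion
                p = int(rng.integers(0, len(cols) - size + 1))
                for cid in cols[p : p + size]:
                    res.pop(cid, None)
                del cols[p : p + size]
            else:
                # insertion between positions p-1 and p
                p = int(rng.integers(0, len(cols) + 1))
                new_ids = list(range(next_id, next_id + size))
                next_id += size
                anchor = master.index(cols[p - 1]) + 1 if p > 0 else (
                    master.index(cols[0]) if cols else 0
                )
                master[anchor:anchor] = new_ids
                cols[p:p] = new_ids
                for cid in new_ids:
                    res[cid] = int(rng.choice(aa))
        return cols, res

    def descend(node: _Node, cols: list[int], res: dict[int, int]) -> None:
        if not node.children:
            leaf_states.append((cols, res))
            return
        for child, blen in node.children:
            c2, r2 = evolve(cols, res, blen)
            descend(child, c2, r2)

    root_cols = list(range(params.length))
    root_res = {cid: int(ancestor_res[i]) for i, cid in enumerate(root_cols)}
    descend(root, root_cols, root_res)

    order = {cid: k for k, cid in enumerate(master)}
    rows = []
    for cols, res in leaf_states:
        row = ["-"] * len(master)
        for cid in cols:
            row[order[cid]] = chr(res[cid])
        rows.append("".join(row))
    # drop columns absent from every leaf (sites lost everywhere or internal-only)
    keep = [any(r[k] != "-" for r in rows) for k in range(len(master))]
    rows = ["".join(r[k] for k in range(len(master)) if keep[k]) for r in rows]

    ids = [f"seq{i + 1}" for i in range(params.n)]
    descendants = [
        Sequence(sid, row.replace("-", "")) for sid, row in zip(ids, rows)
    ]
    true_alignment = Alignment(rows, ids)
    ancestor = Sequence("ancestor", bytes(ancestor_res).decode("ascii"))
    return SyntheticFamily(ancestor, descendants, true_alignment, params, seed)
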