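"""Guide trees: neighbour-joining construction, CLUSTAL W-style sequence
weights, and the two tree perturbations used to seed the GA population.

Trees are rooted binary trees whose leaves carry sequence indices.  The
final neighbour-joining agglomeration becomes the root with the last edge
split equally; negative branch-length estimates are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignmentError
from .distances import DistanceMatrix


class TreeNode:
    __slots__ = ("children", "leaf", "length")

    def __init__(self, leaf: int | None = None, length: float = 0.0):
        self.leaf = leaf
        self.children: list["TreeNode"] = []
        self.length = float(length)

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def copy(self) -> "TreeNode":
        node = TreeNode(self.leaf, self.length)
        node.children = [c.copy() for c in self.children]
        return node


class GuideTree:
    """A rooted binary tree over sequence indices with branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: list[int] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                if node.children:
                    raise AlignmentError("leaf node with children")
                seen.append(node.leaf)
                return
            if len(node.children) != 2:
                raise AlignmentError("internal nodes must have exactly two children")
            if node.length < 0:
                raise AlignmentError("negative branch length")
            for c in node.children:
                walk(c)

        walk(self.root)
        if len(seen) != len(set(seen)):
            raise AlignmentError("duplicate leaf labels in guide tree")
        self._leaf_order = seen

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_order)

    def leaf_indices(self) -> list[int]:
        """Leaf labels in left-to-right traversal order."""
        return list(self._leaf_order)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def canonical_form(self) -> str:
        """Order-invariant serialisation (topology and labels only)."""

        def canon(node: TreeNode) -> str:
            if node.is_leaf:
                return str(node.leaf)
            parts = sorted(canon(c) for c in node.children)
            return "(" + ",".join(parts) + ")"

        return canon(self.root)

    def newick(self, names: list[str] | None = None) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = names[node.leaf] if names else str(node.leaf)
                return f"{label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def copy(self) -> "GuideTree":
        return GuideTree(self.root.copy())

    def __repr__(self) -> str:
        return f"<GuideTree n_leaves={self.n_leaves}>"


@dataclass(frozen=True)
class WeightVector:
    """Per-sequence weights; the pair weight W_ij is the product w_i * w_j."""

    w: np.ndarray

    def pair_weight(self, i: int, j: int) -> float:
        return float(self.w[i] * self.w[j])


def build_guide_tree(d: DistanceMatrix) -> GuideTree:
    """Neighbour-joining agglomeration of a distance matrix.

    Ties in the Q criterion are broken towards the smallest (i, j) pair in
    the current agglomeration order, making construction deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise AlignmentError("need at least two sequences to build a tree")
    nodes: list[TreeNode] = [TreeNode(leaf=i) for i in range(n)]
    D = [list(map(float, row)) for row in d.d]
    active = list(range(n))

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best_q = None
        best = (0, 0)
        for ii in range(r - 1):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * D[i][j] - sums[i] - sums[j]
                if best_q is None or q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = TreeNode()
        for child, blen in ((nodes[i], li), (nodes[j], lj)):
            child.length = max(0.0, blen)
            parent.children.append(child)
        new = len(nodes)
        nodes.append(parent)
        D.append([0.0] * len(nodes))
        for row in D[:-1]:
            row.append(0.0)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[new][k] = D[k][new] = dk
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    half = max(0.0, D[i][j] / 2.0)
    root = TreeNode()
    for child in (nodes[i], nodes[j]):
        child.length = half
        root.children.append(child)
    return GuideTree(root)


def clustalw_weights(t: GuideTree) -> WeightVector:
    """CLUSTAL W-style weights: each leaf accumulates, over the edges on its
    root-to-leaf path, the edge length divided by the number of leaves below
    that edge; weights are then rescaled to mean 1.

    A star-like or all-zero-length tree (all raw weights zero) falls back to
    uniform weights of 1.
    """
    n = t.n_leaves
    w = np.zeros(max(t.leaf_indices()) + 1)

    def n_below(node: TreeNode) -> int:
        if node.is_leaf:
            return 1
        return sum(n_below(c) for c in node.children)

    def walk(node: TreeNode, acc: float) -> None:
        if node.is_leaf:
            w[node.leaf] = acc
            return
        for c in node.children:
            walk(c, acc + c.length / n_below(c))

    walk(t.root, 0.0)
    total = w.sum()
    if total <= 0.0:
        return WeightVector(np.ones_like(w))
    return WeightVector(w * (n / total))


def _prune(node: TreeNode, keep: set[int]) -> TreeNode | None:
    """Subtree over the kept leaves, preserving relative branching order;
    unary nodes are collapsed with their branch lengths summed."""
    if node.is_leaf:
        if node.leaf in keep:
            return TreeNode(node.leaf, node.length)
        return None
    kept = [_prune(c, keep) for c in node.children]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    out = TreeNode(length=node.length)
    out.children = kept
    return out


def mechanism1_split(
    t: GuideTree, rng: np.random.Generator, max_retries: int = 20
) -> GuideTree:
    """Random-subset split: every leaf is chosen independently with
    probability 1/2 (redrawn while the set is empty or complete); the chosen
    leaves and their complement each form a subtree that preserves the base
    tree's relative branching order, and the two are joined under a new root.

    The draw is retried (bounded) if the result equals the input tree.
    """
    leaves = t.leaf_indices()
    if len(leaves) < 3:
        raise AlignmentError("mechanism 1 needs at least 3 leaves")
    root_mean = sum(c.length for c in t.root.children) / len(t.root.children)
    base = t.canonical_form
    result = None
    for _ in range(max_retries):
        mask = rng.random(len(leaves)) < 0.5
        if mask.all() or not mask.any():
            continue
        chosen = {leaf for leaf, m in zip(leaves, mask) if m}
        sub_a = _prune(t.root.copy(), chosen)
        sub_b = _prune(t.root.copy(), set(leaves) - chosen)
        root = TreeNode()
        for sub in (sub_a, sub_b):
            sub.length = root_mean
            root.children.append(sub)
        result = GuideTree(root)
        if result.canonical_form != base:
            return result
    if result is None:  # pathological rng; keep the contract total
        raise AlignmentError("mechanism 1 failed to draw a non-trivial split")
    return result


def mechanism2_swap(t: GuideTree, rng: np.random.Generator) -> GuideTree:
    """Shuffle mechanism: two distinct leaves exchange their sequence labels;
    topology and branch lengths are untouched.  Applying the same swap twice
    restores the original tree."""
    if t.n_leaves < 2:
        raise AlignmentError("mechanism 2 needs at least 2 leaves")
    out = t.copy()
    nodes = out.leaves()
    i, j = rng.choice(len(nodes), size=2, replace=False)
    nodes[i].leaf, nodes[j].leaf = nodes[j].leaf, nodes[i].leaf
    return GuideTree(out.root)
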