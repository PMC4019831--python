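"""Numerical taxonomy of binary phenotypic traits.

Strains are scored for a panel of binary characters (carbon/nitrogen source
utilisation, antibiotic and dye tolerance, enzyme activities, ...), pairwise
resemblance is measured with the simple matching coefficient

    SM = (a + d) / (a + b + c + d)

where a, b, c, d count 1/1, 1/0, 0/1 and 0/0 character pairs over positions
scored in both strains, and strains are clustered by UPGMA (unweighted
pair-group method with arithmetic averages) on the distance 1 - SM.  Phena
are read off the resulting ultrametric tree by cutting it at a stated
similarity level.

Missing character states use pairwise deletion: a position contributes to a
strain pair only when both strains are scored there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

__all__ = [
    "UndefinedSimilarityError",
    "TraitMatrix",
    "SimilarityMatrix",
    "DistanceMatrix",
    "simple_matching",
    "similarity_matrix",
    "similarity_to_distance",
    "upgma",
    "cut_at_similarity",
    "cophenetic_distances",
    "node_height",
]

_SYM_TOL = 1e-12
_HEIGHT_TOL = 1e-9


class UndefinedSimilarityError(ValueError):
    """No jointly scored positions (or no bands) to compare two strains on."""


@dataclass
class TraitMatrix:
    """Strains x binary characters, with NaN marking missing scores."""

    strains: list[str]
    characters: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.strains), len(self.characters)):
            raise ValueError(
                f"trait matrix shape {self.values.shape} does not match "
                f"{len(self.strains)} strains x {len(self.characters)} characters"
            )
        bad = ~(np.isnan(self.values) | (self.values == 0) | (self.values == 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary trait value {self.values[i, j]!r} for strain "
                f"{self.strains[i]!r}, character {self.characters[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _check_square(ids: list[str], values: np.ndarray, kind: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(ids)
    if values.shape != (n, n):
        raise ValueError(f"{kind} matrix shape {values.shape} does not match {n} ids")
    if np.isnan(values).any():
        raise ValueError(f"{kind} matrix contains NaN")
    if np.abs(values - values.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError(f"{kind} matrix is not symmetric")
    return values


@dataclass
class SimilarityMatrix:
    """Symmetric strain x strain similarities in [0, 1] with unit diagonal."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _check_square(self.ids, self.values, "similarity")
        if self.values.min(initial=1.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _check_square(self.ids, self.values, "distance")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("distances must be non-negative")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("distance diagonal must be exactly 0")


def simple_matching(x: np.ndarray, y: np.ndarray) -> float:
    """Simple matching coefficient (a+d)/(a+b+c+d) over jointly scored positions.

    Positions where either vector is NaN (unscored) are excluded.  Raises
    :class:`UndefinedSimilarityError` when no position is scored in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trait vectors differ in length")
    scored = ~(np.isnan(x) | np.isnan(y))
    n = int(scored.sum())
    if n == 0:
        raise UndefinedSimilarityError("no jointly scored positions")
    return float((x[scored] == y[scored]).sum()) / n


def similarity_matrix(m: TraitMatrix) -> SimilarityMatrix:
    """All-pairs simple matching similarity for a trait matrix."""
    n = len(m.strains)
    if n < 2:
        raise ValueError("similarity requires at least 2 strains")
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s[i, j] = s[j, i] = simple_matching(m.values[i], m.values[j])
            except UndefinedSimilarityError as exc:
                raise UndefinedSimilarityError(
                    f"similarity undefined for strains "
                    f"{m.strains[i]!r} and {m.strains[j]!r}: {exc}"
                ) from None
    return SimilarityMatrix(list(m.strains), s)


def similarity_to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    """Elementwise d = 1 - s; the scale on which phenogram heights live."""
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(s.ids), d)


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering into a rooted ultrametric tree.

    At every step the pair of clusters with the smallest average distance is
    merged at a node of height d/2 (so cophenetic distances equal merge
    distances); inter-cluster distances are updated as size-weighted means,
    which equals the arithmetic mean over all cross-cluster member pairs.
    Ties are broken toward the lexicographically smallest index pair in the
    current cluster ordering, so the result is deterministic.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    work = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        bi = bj = -1
        best = np.inf
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                dab = work[active[a], active[b]]
                if dab < best:
                    best, bi, bj = dab, a, b
        i, j = active[bi], active[bj]
        h = best / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        for k in active:
            if k in (i, j):
                continue
            avg = (sizes[i] * work[i, k] + sizes[j] * work[j, k]) / (
                sizes[i] + sizes[j]
            )
            work[i, k] = work[k, i] = avg
        nodes[i] = parent
        heights[i] = h
        sizes[i] += sizes[j]
        del active[bj]
    root = nodes[active[0]]
    root.length = None
    return root


def node_height(node: TreeNode) -> float:
    """Height of a node in an ultrametric tree: distance down to any tip."""
    h = 0.0
    while node.children:
        node = node.children[0]
        h += node.length or 0.0
    return h


def cut_at_similarity(tree: TreeNode, level: float) -> list[list[str]]:
    """Phena at a similarity level: remove merges above distance 1 - level.

    A cluster that forms at cophenetic (merge) distance d sits at
    similarity 1 - d on the phenogram axis, so cutting at ``level`` keeps
    exactly the merges with d <= 1 - level.  Returns the leaf partition in
    tree traversal order.  Raising the level only refines the partition
    (clusters are nested across levels).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("similarity level must lie in [0, 1]")
    threshold = 1.0 - level
    clusters: list[list[str]] = []

    def visit(node: TreeNode) -> None:
        # merge distance = cophenetic distance = twice the tip-ward height
        if node.is_tip() or 2.0 * node_height(node) <= threshold + _HEIGHT_TOL:
            clusters.append([t.name for t in node.tips()] or [node.name])
        else:
            for child in node.children:
                visit(child)

    visit(tree)
    return clusters


def cophenetic_distances(tree: TreeNode, ids: list[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path lengths of a tree, as a :class:`DistanceMatrix`."""
    skb = tree.tip_tip_distances()
    order = ids if ids is not None else [str(i) for i in skb.ids]
    values = np.array(
        [[0.0 if a == b else skb[a, b] for b in order] for a in order]
    )
    return DistanceMatrix(list(order), values)
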