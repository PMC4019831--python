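"""Alignment-based 16S rDNA analytics.

Consumes a multiple alignment (computed externally; this package does not
align) and provides pairwise percent identity, Kimura two-parameter (K2P)
distances, neighbor-joining trees, column-resampling bootstrap supports and
the 95%-identity genus-assignment rule.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P of comparable
columns) from transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Gaps are handled by pairwise deletion; N is never comparable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .phenotype import DistanceMatrix

__all__ = [
    "UndefinedIdentityError",
    "SaturationError",
    "Alignment",
    "pairwise_identity",
    "identity_matrix",
    "k2p_distance",
    "k2p_matrix",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "GenusCall",
    "assign_genus",
]

_ALPHABET = set("ACGTN-")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class UndefinedIdentityError(ValueError):
    """No comparable alignment columns between two rows."""


class SaturationError(ValueError):
    """Observed divergence too high for the K2P correction (log of <= 0)."""


@dataclass
class Alignment:
    """Equal-length gapped nucleotide rows over A/C/G/T/N/-."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        if not self.seqs:
            raise ValueError("alignment is empty")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        for name, s in zip(self.ids, self.seqs):
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"row {name!r} has invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def row(self, name: str) -> str:
        return self.seqs[self.ids.index(name)]

    def as_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            len(self.seqs), self.length
        )


def _byte_rows(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError("rows differ in length; not from the same alignment?")
    xa = np.frombuffer(a.upper().encode(), dtype="S1")
    xb = np.frombuffer(b.upper().encode(), dtype="S1")
    comparable = np.isin(xa, _BASES) & np.isin(xb, _BASES)
    return xa, xb, comparable


def pairwise_identity(a: str, b: str, mode: str = "ignore-gaps") -> float:
    """Percent identity of two aligned rows, in [0, 100].

    ``ignore-gaps`` (default): matches over columns where both rows carry a
    base; ``count-gaps``: the denominator additionally includes columns
    where exactly one row carries a base (a gap opposite a base counts as
    a mismatch).  N never matches anything.
    """
    xa, xb, comparable = _byte_rows(a, b)
    matches = int(((xa == xb) & comparable).sum())
    if mode == "ignore-gaps":
        denom = int(comparable.sum())
    elif mode == "count-gaps":
        either = np.isin(xa, _BASES) | np.isin(xb, _BASES)
        denom = int(either.sum())
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise UndefinedIdentityError("no comparable columns")
    return 100.0 * matches / denom


def identity_matrix(aln: Alignment, mode: str = "ignore-gaps") -> pd.DataFrame:
    """All-pairs percent identity as a DataFrame (diagonal 100)."""
    n = len(aln.ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                m[i, j] = m[j, i] = pairwise_identity(aln.seqs[i], aln.seqs[j], mode)
            except UndefinedIdentityError:
                raise UndefinedIdentityError(
                    f"identity undefined for {aln.ids[i]!r} and {aln.ids[j]!r}"
                ) from None
    return pd.DataFrame(m, index=aln.ids, columns=aln.ids)


_TRANSITIONS = {(b"A", b"G"), (b"G", b"A"), (b"C", b"T"), (b"T", b"C")}


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance (substitutions/site) of two rows."""
    xa, xb, comparable = _byte_rows(a, b)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedIdentityError("no comparable columns")
    diff = (xa != xb) & comparable
    ts = 0
    for pa, pb in _TRANSITIONS:
        ts += int(((xa == pa) & (xb == pb) & comparable).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}); K2P distance undefined"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = k2p_distance(aln.seqs[i], aln.seqs[j])
            except SaturationError as exc:
                raise SaturationError(
                    f"{aln.ids[i]!r} vs {aln.ids[j]!r}: {exc}"
                ) from None
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The pair minimising the Q-criterion is agglomerated at each step, with
    ties broken toward the lexicographically smallest index pair in the
    current node ordering (deterministic across platforms).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling edge so the pair's summed length is preserved.  The returned
    tree is rooted at the final three-way junction (degree-3 "root").
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    work = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    active = list(range(n))

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(work[i, k] for k in active if k != i) for i in active}
        best, bi, bj = np.inf, -1, -1
        for a in range(m):
            for b in range(a + 1, m):
                i, j = active[a], active[b]
                q = (m - 2) * work[i, j] - r[i] - r[j]
                if q < best:
                    best, bi, bj = q, a, b
        i, j = active[bi], active[bj]
        vi = 0.5 * work[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = work[i, j] - vi
        vi, vj = clamp_pair(vi, vj)
        left, right = nodes[i], nodes[j]
        left.length, right.length = vi, vj
        parent = TreeNode(children=[left, right])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (work[i, k] + work[j, k] - work[i, j])
            work[i, k] = work[k, i] = max(duk, 0.0)
        nodes[i] = parent
        del active[bj]
    a, b, c = active
    va = 0.5 * (work[a, b] + work[a, c] - work[b, c])
    vb = 0.5 * (work[a, b] + work[b, c] - work[a, c])
    vc = 0.5 * (work[a, c] + work[b, c] - work[a, b])
    children = []
    for idx, v in zip((a, b, c), (va, vb, vc)):
        nodes[idx].length = max(v, 0.0)
        children.append(nodes[idx])
    root = TreeNode(children=children)
    root.length = None
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the leaf set induced by internal edges.

    Each bipartition is the frozenset of its two sides, so the
    representation is invariant to tree rooting and orientation.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.add(frozenset({side, all_tips - side}))
    return out


def bootstrap_support(
    aln: Alignment, reps: int = 100, seed: int | None = None
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports on internal nodes.

    Each replicate resamples the alignment columns with replacement,
    recomputes K2P distances and a NJ tree, and every bipartition of the
    full-data tree is scored by the percentage of replicate trees that
    contain it.  Replicates in which some pair saturates are skipped; more
    than 50% skipped raises.  Supports are stored on ``node.support``
    (rounded percentages), which Newick serialization emits as internal
    node labels.
    """
    if reps < 1:
        raise ValueError("bootstrap requires at least 1 replicate")
    full = neighbor_joining(k2p_matrix(aln))
    rng = np.random.default_rng(seed)
    arr = aln.as_array()
    counts: dict[frozenset, int] = defaultdict(int)
    skipped = 0
    for _ in range(reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rows = ["".join(row.astype(str)) for row in arr[:, cols]]
        try:
            rep_tree = neighbor_joining(k2p_matrix(Alignment(list(aln.ids), rows)))
        except SaturationError:
            skipped += 1
            continue
        for bp in bipartitions(rep_tree):
            counts[bp] += 1
    if skipped > reps / 2:
        raise SaturationError(
            f"{skipped}/{reps} bootstrap replicates had saturated pairs"
        )
    valid = reps - skipped
    all_tips = frozenset(t.name for t in full.tips())
    for node in full.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            node.support = round(100.0 * counts[frozenset({side, all_tips - side})] / valid)
    return full


# ---------------------------------------------------------------------------
# Genus assignment


@dataclass(frozen=True)
class GenusCall:
    """Outcome of the identity-threshold genus rule for one query."""

    query: str
    status: str  # "assigned" | "unassigned" | "ambiguous"
    genus: str | None
    best_identity: float
    best_reference: str | None
    tied_genera: tuple[str, ...] = ()


def assign_genus(
    identities: pd.DataFrame,
    genus_of: dict[str, str],
    threshold: float = 95.0,
) -> dict[str, GenusCall]:
    """Assign each query the genus of its best >= threshold reference.

    ``identities`` has query rows and reference columns (percent scale).
    A query whose best identity falls below the threshold is
    "unassigned"; an exact best-identity tie across different genera is
    "ambiguous", listing the tied genera.
    """
    missing = [r for r in identities.columns if r not in genus_of]
    if missing:
        raise ValueError(f"reference(s) without genus label: {missing}")
    calls: dict[str, GenusCall] = {}
    for query in identities.index:
        row = identities.loc[query]
        best = float(row.max())
        if best < threshold:
            calls[query] = GenusCall(query, "unassigned", None, best, None)
            continue
        best_refs = [r for r in identities.columns if row[r] == best]
        genera = sorted({genus_of[r] for r in best_refs})
        if len(genera) > 1:
            calls[query] = GenusCall(
                query, "ambiguous", None, best, None, tuple(genera)
            )
        else:
            calls[query] = GenusCall(query, "assigned", genera[0], best, best_refs[0])
    return calls
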