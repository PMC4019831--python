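"""Independent brute-force oracles used to check the library's algorithms.

Everything here deliberately recomputes from first principles (positional
loops, averages over the original matrix, graph shortest paths) and shares
no code path with the implementations under test.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def sm_oracle(x, y) -> float:
    """Simple matching by explicit enumeration of the four match classes."""
    a = b = c = d = 0
    for xi, yi in zip(x, y):
        if math.isnan(xi) or math.isnan(yi):
            continue
        if xi == 1 and yi == 1:
            a += 1
        elif xi == 1 and yi == 0:
            b += 1
        elif xi == 0 and yi == 1:
            c += 1
        else:
            d += 1
    return (a + d) / (a + b + c + d)


def naive_digest_oracle(seq: str, recognition: str, cut_offset: int) -> tuple[int, ...]:
    """Position-by-position IUPAC scan; fragments between interior cuts."""
    cuts = []
    k = len(recognition)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in IUPAC[recognition[j]] for j in range(k)):
            cut = i + cut_offset
            if 0 < cut < len(seq):
                cuts.append(cut)
    bounds = [0] + sorted(set(cuts)) + [len(seq)]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


def upgma_oracle(D: np.ndarray) -> np.ndarray:
    """Brute-force UPGMA cophenetic matrix.

    Clusters are explicit index sets and every inter-cluster distance is
    recomputed at each step as the plain mean over all cross pairs of the
    ORIGINAL matrix; the cophenetic entry of every cross pair is the merge
    distance.  Ties break toward the first pair in scan order.
    """
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros_like(D, dtype=float)
    while len(clusters) > 1:
        best, bi, bj = np.inf, -1, -1
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if avg < best:
                    best, bi, bj = avg, a, b
        for i in clusters[bi]:
            for j in clusters[bj]:
                coph[i, j] = coph[j, i] = best
        clusters[bi] = clusters[bi] + clusters[bj]
        del clusters[bj]
    return coph


def nj_oracle_bipartitions(D: np.ndarray, ids: list[str]) -> set[frozenset[frozenset[str]]]:
    """Plain NJ re-implementation tracking leaf sets; returns the topology
    as the set of non-trivial bipartitions."""
    n = D.shape[0]
    work = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    leafsets: dict[int, frozenset[str]] = {i: frozenset([ids[i]]) for i in range(n)}
    every = frozenset(ids)
    biparts: set[frozenset[frozenset[str]]] = set()
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(work[(i, k)] for k in active if k != i) for i in active}
        best, pi, pj = np.inf, -1, -1
        for a in range(m):
            for b in range(a + 1, m):
                i, j = active[a], active[b]
                q = (m - 2) * work[(i, j)] - r[i] - r[j]
                if q < best:
                    best, pi, pj = q, a, b
        i, j = active[pi], active[pj]
        u = next_id
        next_id += 1
        leafsets[u] = leafsets[i] | leafsets[j]
        if 1 < len(leafsets[u]) < len(every) - 1:
            biparts.add(frozenset({leafsets[u], every - leafsets[u]}))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (work[(i, k)] + work[(j, k)] - work[(i, j)])
            work[(u, k)] = work[(k, u)] = duk
        active[pi] = u
        del active[pj]
    return biparts


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[list[str], np.ndarray, set[frozenset[frozenset[str]]]]:
    """Random unrooted binary tree with positive branch lengths.

    Returns leaf ids, the exact leaf-to-leaf path-length matrix (additive
    by construction, via graph shortest paths) and the set of non-trivial
    bipartitions.
    """
    assert n_leaves >= 4
    g = nx.Graph()
    center = "n0"
    leaves = [f"L{i}" for i in range(n_leaves)]
    for leaf in leaves[:3]:
        g.add_edge(center, leaf, weight=float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for leaf in leaves[3:]:
        u, v = list(g.edges)[rng.integers(0, g.number_of_edges())]
        w_uv = g[u][v]["weight"]
        split = float(rng.uniform(0.2, 0.8))
        mid = f"n{next_internal}"
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=w_uv * split)
        g.add_edge(mid, v, weight=w_uv * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.05, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    D = np.array([[0.0 if a == b else dist[a][b] for b in leaves] for a in leaves])
    every = frozenset(leaves)
    biparts: set[frozenset[frozenset[str]]] = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in every)
        if 1 < len(side) < n_leaves - 1:
            biparts.add(frozenset({side, every - side}))
    return leaves, D, biparts


def dendropy_nj_bipartitions(ids: list[str], D: np.ndarray) -> set[frozenset[frozenset[str]]]:
    """Neighbor joining via dendropy, as an independent implementation."""
    import io as _io

    import dendropy

    rows = ["," + ",".join(ids)]
    for i, a in enumerate(ids):
        rows.append(a + "," + ",".join(str(D[i, j]) for j in range(len(ids))))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO("\n".join(rows)), delimiter=","
    )
    tree = pdm.nj_tree()
    every = frozenset(ids)
    out: set[frozenset[frozenset[str]]] = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        if 1 < len(side) < len(every) - 1:
            out.add(frozenset({side, every - side}))
    return out
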