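"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (textbook
dynamic programming, exhaustive topology enumeration, grid scans, naive
agglomeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Affine-gap global alignment score (Gotoh three-matrix DP)

NEG = -1e18


def gotoh_global_score(a: str, b: str, submat, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score; a gap of length k costs open + k*extend.

    End gaps are penalized like internal gaps.  ``submat`` is a Biopython
    substitution matrix (indexable by residue pair).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (vertical moves)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal moves)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        si = submat[a[i - 1]]
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + si[b[j - 1]]
            Ix[i, j] = max(
                M[i - 1, j] - (gap_open + gap_extend),
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - (gap_open + gap_extend),
            )
            Iy[i, j] = max(
                M[i, j - 1] - (gap_open + gap_extend),
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - (gap_open + gap_extend),
            )
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


# ---------------------------------------------------------------------------
# Exhaustive unrooted-topology enumeration with least-squares fits


def _enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies over leaves 0..n-1 as edge lists.

    Built by inserting each new leaf on every edge of every smaller
    topology; internal nodes are numbered from n upwards.
    """
    base = [[(0, n), (1, n), (2, n)]]  # 3-leaf star with one internal node
    next_internal = n + 1
    topologies = base
    for leaf in range(3, n):
        grown = []
        for edges in topologies:
            for k, (u, v) in enumerate(edges):
                new_node = next_internal
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges += [(u, new_node), (v, new_node), (leaf, new_node)]
                grown.append(new_edges)
        next_internal += 1
        topologies = grown
    return topologies


def _design_matrix(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    """Rows: leaf pairs (i<j); columns: edges; 1 iff edge lies on the path."""
    adjacency: dict[int, list[tuple[int, int]]] = {}
    for e_idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, e_idx))
        adjacency.setdefault(v, []).append((u, e_idx))

    def path_edges(src: int, dst: int) -> list[int]:
        stack = [(src, -1, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == dst:
                return used
            for nxt, e_idx in adjacency[node]:
                if nxt != prev:
                    stack.append((nxt, node, used + [e_idx]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(range(n), 2))
    design = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        design[row, path_edges(i, j)] = 1.0
    return design


def _bipartitions_of(edges: list[tuple[int, int]], n: int) -> frozenset:
    adjacency: dict[int, list[int]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    parts = set()
    for u, v in edges:
        # leaves on the u-side of edge (u, v)
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n - 2:
            parts.add(frozenset(side) if 0 not in side else frozenset(range(n)) - frozenset(side))
    return frozenset(parts)


@lru_cache(maxsize=None)
def _topology_cache(n: int):
    topologies = _enumerate_topologies(n)
    projectors = []
    parts = []
    for edges in topologies:
        design = _design_matrix(edges, n)
        # residual projector I - A (A^T A)^-1 A^T via pseudo-inverse
        pinv = np.linalg.pinv(design)
        projectors.append(np.eye(design.shape[0]) - design @ pinv)
        parts.append(_bipartitions_of(edges, n))
    return np.stack(projectors), parts


def ls_best_topology(dist: np.ndarray) -> frozenset:
    """Least-squares brute force: the topology (as index bipartitions)
    whose best branch-length fit has minimal residual."""
    n = dist.shape[0]
    d = dist[np.triu_indices(n, 1)]
    projectors, parts = _topology_cache(n)
    residuals = np.einsum("tij,j->ti", projectors, d)
    best = int(np.argmin((residuals ** 2).sum(axis=1)))
    return parts[best]


# ---------------------------------------------------------------------------
# Random additive trees


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (distance matrix over leaves 0..n-1, set of index bipartitions).
    """
    topologies = _enumerate_topologies(n)
    edges = topologies[int(rng.integers(len(topologies)))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    design = _design_matrix(edges, n)
    d = design @ lengths
    dist = np.zeros((n, n))
    dist[np.triu_indices(n, 1)] = d
    dist += dist.T
    return dist, _bipartitions_of(edges, n)


# ---------------------------------------------------------------------------
# Isoelectric point by grid scan


def pi_grid_scan(charge_fn, step: float = 1e-4) -> float:
    """Brute-force pH scan for the zero crossing of a net-charge function."""
    grid = np.arange(0.0, 14.0 + step, step)
    values = np.array([charge_fn(ph) for ph in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(values)) != 0)
    if len(sign_change) == 0:
        raise AssertionError("no zero crossing on [0, 14]")
    k = sign_change[0]
    return float((grid[k] + grid[k + 1]) / 2.0)


# ---------------------------------------------------------------------------
# Naive agglomerative clustering (recomputes every inter-cluster distance)


def naive_agglomeration(dmat: np.ndarray, linkage: str = "average"):
    """Exhaustive agglomeration: at each step recompute all cluster-pair
    distances from the item-level matrix and merge the smallest (ties to the
    smallest cluster-id pair).  Returns the merge list (i, j, height)."""
    n = dmat.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    agg = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]
    while len(clusters) > 1:
        candidates = []
        for ci, cj in itertools.combinations(sorted(clusters), 2):
            pair_d = [dmat[a, b] for a in clusters[ci] for b in clusters[cj]]
            candidates.append((float(agg(pair_d)), ci, cj))
        h, ci, cj = min(candidates)
        clusters[next_id] = clusters.pop(ci) | clusters.pop(cj)
        merges.append((ci, cj, h))
        next_id += 1
    return merges
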