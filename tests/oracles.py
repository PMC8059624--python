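"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive: explicit Python loops over pairs,
traits and edges, kept free of any code path shared with the package.
"""

from __future__ import annotations

import numpy as np

from funcvar.traits import FUZZY, ORDINAL, Dendrogram, TraitTable


def gower_pair(tt: TraitTable, i: int, j: int) -> float:
    """Gower dissimilarity of one species pair by per-trait looping."""
    num = 0.0
    den = 0.0
    for m in tt.trait_meta:
        if m.type == FUZZY:
            a = tt.values[m.columns].iloc[i].to_numpy(dtype=float)
            b = tt.values[m.columns].iloc[j].to_numpy(dtype=float)
            if np.all(np.isnan(a)) or np.all(np.isnan(b)):
                continue
            delta = 0.5 * sum(abs(x - y) for x, y in zip(a, b))
        else:
            col = tt.values[m.name].to_numpy(dtype=float)
            if m.type == ORDINAL:
                ranked = np.full_like(col, np.nan)
                # average ranks for ties, computed the slow way
                vals = col[~np.isnan(col)]
                ranks = np.array(
                    [np.mean(np.flatnonzero(np.sort(vals) == v)) + 1 for v in vals]
                )
                ranked[~np.isnan(col)] = ranks
                col = ranked
            if np.isnan(col[i]) or np.isnan(col[j]):
                continue
            rng = np.nanmax(col) - np.nanmin(col)
            delta = 0.0 if rng == 0 else abs(col[i] - col[j]) / rng
        num += m.weight * delta
        den += m.weight
    if den == 0:
        raise ValueError("no shared trait")
    return num / den


def gower_full(tt: TraitTable) -> np.ndarray:
    n = tt.n_species
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = gower_pair(tt, i, j)
    return d


def rao_q_loop(p: np.ndarray, d: np.ndarray) -> float:
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * d[i, j]
    return q


def cwm_loop(p: np.ndarray, X: np.ndarray) -> np.ndarray:
    out = np.zeros(X.shape[1])
    for t in range(X.shape[1]):
        for i in range(len(p)):
            out[t] += p[i] * X[i, t]
    return out


def cwv_loop(p: np.ndarray, X: np.ndarray) -> np.ndarray:
    m = cwm_loop(p, X)
    out = np.zeros(X.shape[1])
    for t in range(X.shape[1]):
        for i in range(len(p)):
            out[t] += p[i] * (X[i, t] - m[t]) ** 2
    return out


def subtree_length_by_path_marking(tree: Dendrogram, present: list[str]) -> float:
    """FRic oracle: union of leaf-to-root edge paths, minus the shared
    path above the deepest node covering all present leaves."""
    idx = {s: i for i, s in enumerate(tree.leaf_ids)}
    leaves = [idx[s] for s in present]
    if len(leaves) <= 1:
        return 0.0
    parents = tree.parent_map()
    edges = tree.edge_lengths()
    marked: set[int] = set()  # child node of each marked edge
    for leaf in leaves:
        node = leaf
        while node in parents:
            marked.add(node)
            node = parents[node]
    # the MRCA is the deepest marked-path node whose subtree holds all leaves
    sets = tree.leaf_sets()
    want = frozenset(leaves)
    total = 0.0
    for child in marked:
        if want <= sets[child]:
            continue  # edge above the MRCA: shared by all, not spanning
        total += edges[child]
    return total


def upgma_by_hand(d: np.ndarray) -> list[tuple[frozenset, float]]:
    """Average-linkage merges as (merged leaf set, height) pairs, using
    explicit all-pairs averages over the original matrix."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bi]
                avg = np.mean([d[x, y] for x in a for y in b])
                key = (avg, min(min(a), min(b)), max(min(a), min(b)))
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        (avg, _, _), ai, bi = best
        merged = clusters[ai] | clusters[bi]
        merges.append((merged, avg / 2.0))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)] + [merged]
    return merges
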