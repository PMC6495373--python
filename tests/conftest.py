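"""Shared fixtures and independent oracles.

The oracles here deliberately take the slow, obviously-correct route
(per-pair path walks, explicit density-reachability, naive Lance-Williams)
so they stay independent of the implementations they check.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest


def random_tree(rng: np.random.Generator, n_tips: int, scale: float = 1.0) -> dendropy.Tree:
    """Random binary tree built by sequential joining, Exp(scale) edges."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(f"t{i + 1:02d}")
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(scale))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree


def brute_force_patristic(tree: dendropy.Tree, tip_a: str, tip_b: str) -> float:
    """Path-sum oracle: climb both tips to the root, drop the shared suffix."""

    def path_to_root(label):
        node = next(
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == label
        )
        path = []
        while node.parent_node is not None:
            path.append((id(node.parent_node), node.edge.length or 0.0))
            node = node.parent_node
        return path

    pa, pb = path_to_root(tip_a), path_to_root(tip_b)
    ancestors_a = {nid for nid, _ in pa}
    ancestors_b = {nid for nid, _ in pb}
    total = 0.0
    for nid, length in pa:
        total += length
        if nid in ancestors_b:
            # everything above the first common ancestor is shared
            mrca = nid
            break
    for nid, length in pb:
        total += length
        if nid == mrca:
            break
    return total


def brute_force_dbscan(dist: np.ndarray, eps: float, min_neighbors: int) -> list[set]:
    """Density-connected components over core points; returns clusters as
    index sets (border points joined to every cluster that reaches them,
    which is enough to check partition structure on unambiguous data)."""
    n = dist.shape[0]
    neighbors = [set(np.where(dist[i] <= eps)[0]) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_neighbors}
    clusters = []
    unvisited = set(core)
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nb in neighbors[cur] & core:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
                    unvisited.discard(nb)
        # attach border points reachable from this component
        for i in set(range(n)) - core:
            if neighbors[i] & comp:
                comp.add(i)
        clusters.append(comp)
    return clusters


def brute_force_ward(points: np.ndarray) -> list[tuple[frozenset, float]]:
    """Naive Lance-Williams agglomeration under the ward.D2 convention.

    Returns the merge sequence as (leaf index set, merge height) pairs.
    Heights are Euclidean-scale (square root of the updated squared
    dissimilarity), matching scipy's ward linkage.
    """
    n = len(points)
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))

    def get(i, j):
        return d2[(i, j) if i < j else (j, i)]

    merges = []
    next_id = n
    while len(clusters) > 1:
        best = min(
            ((get(i, j), i, j) for i in clusters for j in clusters if i < j),
        )
        dist2, i, j = best
        merged = clusters[i] | clusters[j]
        ni, nj = sizes[i], sizes[j]
        for k in clusters:
            if k in (i, j):
                continue
            nk = sizes[k]
            upd = (
                (ni + nk) * get(i, k) + (nj + nk) * get(j, k) - nk * dist2
            ) / (ni + nj + nk)
            d2[(k, next_id) if k < next_id else (next_id, k)] = upd
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        merges.append((merged, float(np.sqrt(dist2))))
        next_id += 1
    return merges


def enumerate_five_tip_topologies() -> list[str]:
    """All 15 unrooted binary 5-tip topologies as Newick strings.

    Each is determined by its pair of disjoint cherry tip-pairs:
    ((x,y),(u,v),w).
    """
    tips = ["A", "B", "C", "D", "E"]
    out = []
    from itertools import combinations

    seen = set()
    for pair1 in combinations(tips, 2):
        rest = [t for t in tips if t not in pair1]
        for pair2 in combinations(rest, 2):
            key = frozenset([frozenset(pair1), frozenset(pair2)])
            if key in seen:
                continue
            seen.add(key)
            w = next(t for t in rest if t not in pair2)
            out.append(
                f"(({pair1[0]}:1,{pair1[1]}:1):1,({pair2[0]}:1,{pair2[1]}:1):1,{w}:1);"
            )
    assert len(out) == 15
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
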