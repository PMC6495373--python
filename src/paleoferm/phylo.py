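"""Patristic-distance species delimitation and intertree comparison.

The delimitation logic: on a barcode tree (e.g. LSU rRNA) whose reference
tips carry species labels, the distribution of intraspecific patristic
distances defines what "same species" looks like in branch-length units
(substitutions per base, SPB).  A query isolate whose distance to its
closest relative falls in the right tail of that distribution is flagged as
a novel-species candidate.  Robinson-Foulds distances (raw or weighted) and
density-based clustering of gene trees support the companion
phylogenomic-conflict assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

SpeciesMap = dict  # tip label -> species label


@dataclass
class MembershipResult:
    """Outcome of testing one query distance against the intraspecific set."""

    d_obs: float
    n_reference: int
    p_value: float
    verdict: str  # "conspecific" | "novel-species-candidate"
    method: str


# ---------------------------------------------------------------------------
# Patristic distances


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All pairwise tip-to-tip path-length sums, via one post-order pass.

    At each internal node the tip-depth lists of its child subtrees are
    combined, so every pair is resolved exactly once at its LCA; no per-pair
    path search.  Root placement cannot affect the result because tip-to-tip
    paths do not depend on where the tree is rooted.
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(tips) < 2:
        raise ValueError("patristic matrix requires at least 2 tips")
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    dist = np.zeros((n, n))
    # depths[node] = list of (tip index, distance from node)
    depths: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depths[id(node)] = [(idx[node.taxon.label], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        for child in node.child_nodes():
            below = [
                (i, d + (child.edge.length or 0.0))
                for i, d in depths.pop(id(child))
            ]
            for i, di in below:
                for j, dj in merged:
                    dist[i, j] = dist[j, i] = di + dj
            merged.extend(below)
        depths[id(node)] = merged
    return pd.DataFrame(dist, index=tips, columns=tips)


def intraspecific_distances(matrix: pd.DataFrame, species_map: SpeciesMap) -> list[float]:
    """Distances between tip pairs sharing a species label, sorted.

    Tips absent from the map are ignored (unlabelled references and the
    queries themselves carry no species information).
    """
    by_species: dict[str, list[str]] = {}
    for tip, sp in species_map.items():
        if tip in matrix.index:
            by_species.setdefault(sp, []).append(tip)
    values = []
    for members in by_species.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                values.append(float(matrix.at[a, b]))
    if not values:
        raise ValueError("no intraspecific pairs: no species has >= 2 mapped tips")
    return sorted(values)


def species_membership_test(
    d_obs: float,
    intraspecific: list[float],
    method: str = "parametric",
    alpha: float = 0.05,
    parametric_family: str = "lognormal",
) -> MembershipResult:
    """Test whether a query distance belongs to the intraspecific distribution.

    ``empirical``: p = (#{x >= d_obs} + 1) / (n + 1), the add-one exceedance
    rule.  ``parametric``: right-tail probability of a maximum-likelihood
    lognormal (or gamma) fitted to the positive reference distances — needed
    because a query larger than every reference value still deserves a
    graded p rather than a floor.  Falls back to empirical (with a warning)
    when fewer than 5 positive reference values are available.
    """
    if not intraspecific:
        raise ValueError("intraspecific reference set is empty")
    if d_obs < 0:
        raise ValueError("d_obs must be >= 0")
    ref = np.asarray(intraspecific, dtype=float)
    used = method
    if method == "parametric":
        positive = ref[ref > 0]
        if len(positive) < 5 or len(positive) < len(ref):
            warnings.warn(
                "parametric membership test needs >= 5 strictly positive "
                "reference distances; falling back to empirical",
                stacklevel=2,
            )
            used = "empirical"
        else:
            if parametric_family == "lognormal":
                shape, loc, scale = stats.lognorm.fit(positive, floc=0)
                p = float(stats.lognorm.sf(d_obs, shape, loc=loc, scale=scale))
            elif parametric_family == "gamma":
                a, loc, scale = stats.gamma.fit(positive, floc=0)
                p = float(stats.gamma.sf(d_obs, a, loc=loc, scale=scale))
            else:
                raise ValueError(f"unknown parametric family {parametric_family!r}")
            used = f"parametric-{parametric_family}"
    if used == "empirical":
        n = len(ref)
        p = (int(np.sum(ref >= d_obs)) + 1) / (n + 1)
    elif not used.startswith("parametric"):
        raise ValueError(f"unknown method {method!r}")
    p = min(1.0, max(p, np.finfo(float).tiny))
    verdict = "novel-species-candidate" if p < alpha else "conspecific"
    return MembershipResult(
        d_obs=float(d_obs),
        n_reference=len(ref),
        p_value=p,
        verdict=verdict,
        method=used,
    )


def closest_relative(matrix: pd.DataFrame, query_tip: str) -> tuple[str, float]:
    """Minimum-distance non-query tip; ties broken to the smaller label."""
    if query_tip not in matrix.index:
        raise KeyError(query_tip)
    row = matrix.loc[query_tip].drop(query_tip)
    best = row.min()
    candidates = sorted(row.index[row == best])
    return candidates[0], float(best)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Non-trivial splits of the unrooted form, as canonical tip-sets.

    Canonical side = the side NOT containing the lexicographically smallest
    tip.  A bifurcating root induces the same split twice; the two edge
    lengths are summed, matching the single edge of the unrooted tree.
    """
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_tips)
    splits: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_tips - below
        if len(below) < 2 or len(other) < 2:
            continue
        key = below if ref not in below else other
        splits[key] = splits.get(key, 0.0) + (node.edge.length or 0.0)
    return splits


def robinson_foulds(
    tree1: dendropy.Tree,
    tree2: dendropy.Tree,
    weighted: bool = False,
    normalized: bool = False,
) -> float:
    """Robinson-Foulds distance between two trees on the same tip set.

    Unweighted: size of the symmetric difference of the non-trivial
    bipartition sets.  Weighted: sum over the union of bipartitions of
    |w1 - w2|, an absent bipartition contributing weight 0.  ``normalized``
    divides by the maximum attainable value (total split count for
    unweighted, total weight for weighted).
    """
    tips1 = {leaf.taxon.label for leaf in tree1.leaf_node_iter()}
    tips2 = {leaf.taxon.label for leaf in tree2.leaf_node_iter()}
    if tips1 != tips2:
        raise ValueError(
            f"tip sets differ: only in tree1 {sorted(tips1 - tips2)}, "
            f"only in tree2 {sorted(tips2 - tips1)}"
        )
    b1, b2 = _bipartitions(tree1), _bipartitions(tree2)
    if weighted:
        total = 0.0
        for split in set(b1) | set(b2):
            total += abs(b1.get(split, 0.0) - b2.get(split, 0.0))
        if normalized:
            denom = sum(b1.values()) + sum(b2.values())
            total = total / denom if denom > 0 else 0.0
        return total
    diff = len(set(b1) ^ set(b2))
    if normalized:
        denom = len(b1) + len(b2)
        return diff / denom if denom > 0 else 0.0
    return float(diff)


# ---------------------------------------------------------------------------
# Density-based tree clustering


def dbscan_cluster(
    distances: pd.DataFrame,
    eps: float,
    min_neighbors: int,
) -> dict[str, int | None]:
    """DBSCAN over a precomputed intertree distance matrix.

    A core tree has >= ``min_neighbors`` trees (itself included) within
    ``eps``.  Returns tree id -> cluster id, or None for noise.  Rows are
    processed in sorted-id order so border-point assignment is deterministic
    regardless of input row order.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    order = sorted(distances.index)
    mat = distances.loc[order, order].to_numpy(dtype=float)
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = DBSCAN(eps=eps, min_samples=min_neighbors, metric="precomputed").fit(mat).labels_
    return {tid: (None if lab == -1 else int(lab)) for tid, lab in zip(order, labels)}
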