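"""Seeded generators emulating every input the pipeline consumes.

Each generator plants a known ground truth (species membership of query
tips, growth-rate regimes, CNV concordance fraction, group recovery rates,
compound clusters) so every downstream stage has a parameter-recovery test
surface.  All randomness flows from one seed, fanned out through
independent per-generator streams, so adding a generator never perturbs the
outputs of the others.

Defaults are the study conditions: intra-/inter-specific branch-length
scales of 0.005 vs 0.2 substitutions per base, three replicate colonies per
strain, 79 signature clusters with a planted concordance fraction of 0.85
(~67 of 79), and isolation-group sizes of 21 beverage vs 110 control
samples with recovery rates 6/21 and 2/110.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .cnv import DELETION, DUPLICATION
from .enrichment import SampleRecord
from .growth import GrowthCurve

# stable stream ids: appending keeps earlier generators' outputs fixed
_STREAMS = {
    "species_tree": 0,
    "growth": 1,
    "cnv": 2,
    "isolation": 3,
    "compounds": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class TreeSpec:
    n_species: int = 5
    tips_per_species: int = 4
    intra_scale: float = 0.005  # SPB, within-species branch scale
    inter_scale: float = 0.2  # SPB, backbone branch scale
    n_conspecific_queries: int = 1
    n_novel_queries: int = 1


@dataclass
class GrowthSpec:
    n_beverage: int = 4  # strains sharing the control growth regime
    n_other: int = 4
    n_replicates: int = 3
    times: tuple = tuple(float(t) for t in range(0, 49, 2))  # hours
    K: float = 1.3  # OD600 carrying capacity
    N0: float = 0.05
    r_control: float = 0.5  # per hour
    r_other: float = 0.25
    r_jitter_sd: float = 0.02  # replicate-to-replicate spread of r
    noise_sd: float = 0.02  # additive OD600 noise


@dataclass
class CnvSpec:
    n_clusters: int = 200
    signature_size: int = 79
    concordance_fraction: float = 0.85  # toward isolate A
    baseline_copy: int = 2
    background_cnv_prob: float = 0.3  # non-signature jitter
    isolate_a: str = "EBEgT12"
    isolate_b: str = "EBEgB8"


@dataclass
class IsolationSpec:
    n_beverage: int = 21
    n_control: int = 110
    rate_beverage: float = 6 / 21
    rate_control: float = 2 / 110


@dataclass
class CompoundSpec:
    n_clusters: int = 3
    samples_per_cluster: int = 3
    n_compounds: int = 20
    separation: float = 10.0  # cluster-mean spread / within noise, log scale
    noise_sigma: float = 0.1  # lognormal within-cluster noise


@dataclass
class SimSpec:
    seed: int = 0
    tree: TreeSpec = field(default_factory=TreeSpec)
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    cnv: CnvSpec = field(default_factory=CnvSpec)
    isolation: IsolationSpec = field(default_factory=IsolationSpec)
    compounds: CompoundSpec = field(default_factory=CompoundSpec)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


# ---------------------------------------------------------------------------
# Species tree with planted queries


def _join_random(
    nodes: list[dendropy.Node], rng: np.random.Generator, scale: float
) -> dendropy.Node:
    """Coalescent-style sequential joining with Exp(scale) child edges."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(scale))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def gen_species_tree(
    spec: SimSpec,
) -> tuple[dendropy.Tree, dict[str, str], dict[str, dict]]:
    """Tree + species map + planted queries with known membership truth.

    Species subtrees use exponential branch lengths at the intra scale and
    hang off a star backbone whose edges are inter_scale/2 plus an
    Exp(inter_scale/2) draw, so every between-species path exceeds
    inter_scale — guaranteeing the intra/inter separation when the scales
    are well separated.  Conspecific queries are grafted as a sibling of a
    reference tip; novel queries hang off the backbone on their own long
    edge.  The query tips are excluded from the species map.
    """
    ts = spec.tree
    if ts.n_species < 2:
        raise ValueError("need >= 2 species")
    if ts.tips_per_species < 2:
        raise ValueError("need >= 2 tips per species for intraspecific pairs")
    if ts.intra_scale <= 0 or ts.inter_scale <= 0:
        raise ValueError("branch-length scales must be > 0")
    rng = _rng(spec.seed, "species_tree")
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    species_map: dict[str, str] = {}
    truth: dict[str, dict] = {}
    species_tip_nodes: dict[str, list[dendropy.Node]] = {}

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        return node

    for s in range(ts.n_species):
        sp = f"sp{s + 1}"
        tips = []
        for t in range(ts.tips_per_species):
            label = f"{sp}_t{t + 1}"
            tips.append(leaf(label))
            species_map[label] = sp
        species_tip_nodes[sp] = tips
        sub_root = _join_random(tips, rng, ts.intra_scale)
        root.add_child(sub_root)
        sub_root.edge.length = float(
            ts.inter_scale / 2 + rng.exponential(ts.inter_scale / 2)
        )

    for q in range(ts.n_conspecific_queries):
        sp = f"sp{int(rng.integers(ts.n_species)) + 1}"
        host = species_tip_nodes[sp][int(rng.integers(ts.tips_per_species))]
        label = f"query_cons{q + 1}"
        # graft as sibling of the host tip, preserving the host's depth
        parent = host.parent_node
        old_len = host.edge.length
        mid = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(mid)
        mid.edge.length = old_len / 2
        mid.add_child(host)
        host.edge.length = old_len / 2
        qnode = leaf(label)
        mid.add_child(qnode)
        qnode.edge.length = float(rng.exponential(ts.intra_scale))
        truth[label] = {"truth": "conspecific", "species": sp}

    for q in range(ts.n_novel_queries):
        label = f"query_novel{q + 1}"
        qnode = leaf(label)
        root.add_child(qnode)
        qnode.edge.length = float(
            ts.inter_scale / 2 + rng.exponential(ts.inter_scale / 2)
        )
        truth[label] = {"truth": "novel", "species": None}

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree, species_map, truth


# ---------------------------------------------------------------------------
# Growth curves


def gen_growth_curves(
    spec: SimSpec,
) -> tuple[list[GrowthCurve], dict[str, bool], str]:
    """Replicate logistic OD600 trajectories with planted origin labels.

    Beverage-vessel strains (and the control) share the control growth-rate
    regime; the rest sit at the shifted regime.  Additive Gaussian noise is
    truncated at 0.  Returns (curves, strain -> is_beverage, control id).
    """
    gs = spec.growth
    if gs.noise_sd < 0 or gs.r_jitter_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if gs.n_replicates < 3:
        raise ValueError("need >= 3 replicate colonies per strain")
    rng = _rng(spec.seed, "growth")
    control = "control"
    strains = (
        [(control, True, gs.r_control)]
        + [(f"bev{i + 1}", True, gs.r_control) for i in range(gs.n_beverage)]
        + [(f"env{i + 1}", False, gs.r_other) for i in range(gs.n_other)]
    )
    times = np.asarray(gs.times, dtype=float)
    curves: list[GrowthCurve] = []
    origins: dict[str, bool] = {}
    for strain, is_bev, r_mean in strains:
        origins[strain] = is_bev
        for rep in range(gs.n_replicates):
            r = max(1e-3, float(rng.normal(r_mean, gs.r_jitter_sd)))
            od = gs.K / (1 + ((gs.K - gs.N0) / gs.N0) * np.exp(-r * times))
            od = np.maximum(od + rng.normal(0, gs.noise_sd, size=len(times)), 0.0)
            curves.append(
                GrowthCurve(strain=strain, replicate=f"c{rep + 1}", times=times, od=od)
            )
    return curves, origins, control


# ---------------------------------------------------------------------------
# Copy-number tables


def gen_cnv_table(
    spec: SimSpec,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Copy-number table + directional signature + planted concordance.

    Every signature cluster shows CNV between the pair: with probability f
    it is perturbed in isolate A's expected direction, otherwise toward B.
    Non-signature clusters get direction-free background jitter.  Returns
    (isolates x clusters table, cluster -> direction, truth dict).
    """
    cs = spec.cnv
    if not 0 <= cs.concordance_fraction <= 1:
        raise ValueError("concordance fraction must be in [0, 1]")
    if cs.signature_size > cs.n_clusters:
        raise ValueError("signature larger than cluster universe")
    rng = _rng(spec.seed, "cnv")
    clusters = [f"OG{i + 1:04d}" for i in range(cs.n_clusters)]
    sig_clusters = sorted(
        rng.choice(cs.n_clusters, size=cs.signature_size, replace=False)
    )
    signature = {
        clusters[i]: (DUPLICATION if rng.random() < 0.5 else DELETION)
        for i in sig_clusters
    }
    a = np.full(cs.n_clusters, cs.baseline_copy, dtype=int)
    b = np.full(cs.n_clusters, cs.baseline_copy, dtype=int)
    toward_a = 0
    for i in sig_clusters:
        direction = signature[clusters[i]]
        if rng.random() < cs.concordance_fraction:
            toward_a += 1
            if direction == DUPLICATION:
                a[i] += 1
            else:
                a[i] -= 1
        else:
            if direction == DUPLICATION:
                b[i] += 1
            else:
                b[i] -= 1
    sig_set = set(sig_clusters)
    for i in range(cs.n_clusters):
        if i not in sig_set and rng.random() < cs.background_cnv_prob:
            which = a if rng.random() < 0.5 else b
            which[i] = max(0, which[i] + (1 if rng.random() < 0.5 else -1))
    table = pd.DataFrame(
        [a, b], index=[cs.isolate_a, cs.isolate_b], columns=clusters
    )
    truth = {
        "concordance_fraction": cs.concordance_fraction,
        "planted_count_a": toward_a,
        "signature_total": cs.signature_size,
    }
    return table, signature, truth


# ---------------------------------------------------------------------------
# Isolation outcomes


def gen_isolation_samples(spec: SimSpec) -> list[SampleRecord]:
    """Bernoulli yeast-recovery outcomes at two group-specific rates.

    Beverage-vessel samples recover at ``rate_beverage``; the control
    samples (split across control-vessel / sediment-stone / off-site
    categories in the study's proportions) at ``rate_control``.
    """
    isp = spec.isolation
    for rate in (isp.rate_beverage, isp.rate_control):
        if not 0 <= rate <= 1:
            raise ValueError("recovery rates must be in [0, 1]")
    if isp.n_beverage < 1 or isp.n_control < 1:
        raise ValueError("group sizes must be >= 1")
    rng = _rng(spec.seed, "isolation")
    records = []
    for i in range(isp.n_beverage):
        records.append(
            SampleRecord(
                sample_id=f"bev{i + 1:03d}",
                site="site-A",
                category="putative-beverage",
                yeast_recovered=bool(rng.random() < isp.rate_beverage),
            )
        )
    control_cats = ["control-vessel", "sediment/stone", "off-site"]
    for i in range(isp.n_control):
        records.append(
            SampleRecord(
                sample_id=f"ctl{i + 1:03d}",
                site="site-A",
                category=control_cats[i % 3],
                yeast_recovered=bool(rng.random() < isp.rate_control),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Compound matrices


def gen_compound_matrix(
    spec: SimSpec,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample x compound peak areas with planted sample clusters.

    Cluster-specific log-mean profiles are drawn with spread
    ``separation * noise_sigma``; samples add lognormal within-cluster
    noise.  Returns (matrix, sample -> planted cluster id).
    """
    cp = spec.compounds
    if cp.n_clusters < 2 or cp.samples_per_cluster < 2 or cp.n_compounds < 3:
        raise ValueError("need >= 2 clusters, >= 2 samples each, >= 3 compounds")
    rng = _rng(spec.seed, "compounds")
    compounds = [f"compound{j + 1:02d}" for j in range(cp.n_compounds)]
    rows, labels = [], {}
    means = rng.normal(
        0.0, cp.separation * cp.noise_sigma, size=(cp.n_clusters, cp.n_compounds)
    )
    for c in range(cp.n_clusters):
        for s in range(cp.samples_per_cluster):
            sid = f"cl{c + 1}_s{s + 1}"
            labels[sid] = c
            noise = rng.normal(0.0, cp.noise_sigma, size=cp.n_compounds)
            rows.append(pd.Series(np.exp(means[c] + noise), index=compounds, name=sid))
    return pd.DataFrame(rows), labels
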