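"""CoRisk network: directed comorbidity risk merged onto the biclusters.

The CoRisk network superimposes two results: (1) the bipartite
patient-comorbidity network with its bicluster partition, and (2) a
directed unipartite risk network over the comorbidities, with one arrow
per significant replicated directionality sub-test.  An arrow points
*toward* the comorbidity against which the pair adds significant risk
alone: if "A&B versus B" is significant, patients with both A and B are
at significantly higher risk than patients with B alone, and the arrow
runs from A to B.  A comorbidity receiving more arrows than it sends is
an *asymmetrical hub* — a condition that raises risk mainly by
exacerbating its partners.

Patients with exactly one of the network's comorbidities sit on the
outer rim of their bicluster ("outer"), those with several in the core
("inner"); the 2 x C inner/outer tally is tested for heterogeneity
across biclusters with a Pearson chi-square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .bicluster import BiclusterPartition, BipartiteGraph
from .errors import ComputationError, DataValidationError
from .risk import OrResult, ReplicatedPairSet

__all__ = [
    "RiskEdge",
    "CoRiskNetwork",
    "HeterogeneityResult",
    "build_corisk",
    "classify_inner_outer",
    "heterogeneity_chi_square",
    "detect_asymmetric_hubs",
    "explode_layout",
    "export_network",
    "read_network",
    "inner_outer_table",
    "plot_network",
]


@dataclass(frozen=True)
class RiskEdge:
    """Directed risk arrow between two comorbidities.

    ``source -> target`` records that the pair carries significantly more
    risk than ``target`` alone; ``or_pair`` is the pair's overall-test OR.
    """

    source: str
    target: str
    or_pair: float
    significant_direction: str  # which sub-test justified the arrow

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise DataValidationError("risk edge cannot be a self-loop")


@dataclass
class CoRiskNetwork:
    bipartite: BipartiteGraph
    partition: BiclusterPartition
    risk_edges: list[RiskEdge] = field(default_factory=list)
    node_or: dict = field(default_factory=dict)
    patient_class: dict = field(default_factory=dict)
    coordinates: dict = field(default_factory=dict)


@dataclass
class HeterogeneityResult:
    counts: np.ndarray
    chi2: float
    df: int
    p_value: float
    n: int


def build_corisk(
    bipartite: BipartiteGraph,
    partition: BiclusterPartition,
    replicated: ReplicatedPairSet,
    single_or: dict | None = None,
) -> CoRiskNetwork:
    """Merge replicated directional risk onto the bicluster network.

    One arrow per significant replicated sub-test: pattern ``a_only``
    ("A&B vs A" significant) gives the single arrow B -> A, ``b_only``
    gives A -> B, and ``both`` gives two opposing arrows.
    """
    com_nodes = set(bipartite.comorbidity_nodes)
    edges: list[RiskEdge] = []
    for name_a, name_b, train, _ in replicated.pairs:
        if name_a not in com_nodes or name_b not in com_nodes:
            raise DataValidationError(
                f"replicated pair ({name_a}, {name_b}) references a "
                "comorbidity absent from the bipartite network"
            )
        or_pair = train.overall.or_point if train.overall else float("nan")
        pattern = train.direction_pattern
        if pattern in ("a_only", "both"):
            edges.append(RiskEdge(name_b, name_a, or_pair, "ab_vs_a"))
        if pattern in ("b_only", "both"):
            edges.append(RiskEdge(name_a, name_b, or_pair, "ab_vs_b"))
    node_or = {}
    if single_or:
        for name, res in single_or.items():
            if name in com_nodes:
                node_or[name] = res.or_point if isinstance(res, OrResult) else float(res)
    net = CoRiskNetwork(bipartite, partition, edges, node_or)
    net.patient_class, _ = classify_inner_outer(net)
    return net


def classify_inner_outer(network: CoRiskNetwork):
    """Label each patient inner (degree > 1) or outer (degree = 1).

    Returns the label mapping and the 2 x C tally (rows: exactly one /
    more than one comorbidity; columns: biclusters in ascending index).
    """
    degree: dict = {p: 0 for p in network.bipartite.patient_nodes}
    for p, _ in network.bipartite.edges:
        degree[p] += 1
    patient_class = {
        p: "inner" if deg > 1 else "outer" for p, deg in degree.items()
    }
    comm_of = network.partition.community_of
    comms = sorted({comm_of[p] for p in network.bipartite.patient_nodes})
    counts = np.zeros((2, len(comms)), dtype=int)
    col = {c: i for i, c in enumerate(comms)}
    for p in network.bipartite.patient_nodes:
        row = 0 if patient_class[p] == "outer" else 1
        counts[row, col[comm_of[p]]] += 1
    table = pd.DataFrame(
        counts, index=["one_comorbidity", "multiple_comorbidities"],
        columns=[f"bicluster_{c}" for c in comms],
    )
    return patient_class, table


def heterogeneity_chi_square(counts) -> HeterogeneityResult:
    """Pearson chi-square (no continuity correction) on the 2 x C tally."""
    arr = np.asarray(counts, dtype=float)
    if isinstance(counts, pd.DataFrame):
        arr = counts.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise DataValidationError("expected a 2 x C table")
    if (arr < 0).any():
        raise DataValidationError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ComputationError("zero margin: chi-square undefined")
    res = stats.chi2_contingency(arr, correction=False)
    return HeterogeneityResult(
        arr.astype(int), float(res.statistic), int(res.dof),
        float(res.pvalue), int(arr.sum()),
    )


def detect_asymmetric_hubs(network: CoRiskNetwork):
    """Comorbidities receiving more risk arrows than they send.

    Returns (comorbidity, in_degree, out_degree) sorted by in-out excess
    descending (node label breaks ties).
    """
    indeg: dict = {}
    outdeg: dict = {}
    for e in network.risk_edges:
        indeg[e.target] = indeg.get(e.target, 0) + 1
        outdeg[e.source] = outdeg.get(e.source, 0) + 1
    hubs = []
    for c in network.bipartite.comorbidity_nodes:
        i, o = indeg.get(c, 0), outdeg.get(c, 0)
        if i > o:
            hubs.append((c, i, o))
    hubs.sort(key=lambda t: (-(t[1] - t[2]), str(t[0])))
    return hubs


def _base_layout(bipartite: BipartiteGraph, seed: int, dense_limit: int = 3000):
    """Seeded force-directed base positions for every node.

    Up to ``dense_limit`` nodes the full graph gets a Fruchterman-Reingold
    layout.  Beyond that (patient counts in the tens of thousands make the
    quadratic layout impractical) the comorbidity nodes are laid out by
    force direction on their patient-overlap projection and each patient
    sits at the mean position of its comorbidities with seeded jitter —
    the same visual logic at linear cost.
    """
    g = bipartite.to_networkx()
    if g.number_of_nodes() <= dense_limit:
        return nx.spring_layout(g, seed=seed)
    proj = nx.Graph()
    proj.add_nodes_from(bipartite.comorbidity_nodes)
    by_patient: dict = {}
    for p, c in bipartite.edges:
        by_patient.setdefault(p, []).append(c)
    for coms in by_patient.values():
        for i, a in enumerate(coms):
            for b in coms[i + 1:]:
                w = proj.get_edge_data(a, b, {"weight": 0})["weight"]
                proj.add_edge(a, b, weight=w + 1)
    base = nx.spring_layout(proj, seed=seed, weight="weight")
    rng = np.random.default_rng(seed)
    out = dict(base)
    for p in sorted(by_patient, key=str):
        anchor = np.mean([base[c] for c in by_patient[p]], axis=0)
        out[p] = tuple(anchor + rng.normal(scale=0.08, size=2))
    return out


def explode_layout(
    network: CoRiskNetwork, explode_factor: float = 0.5, seed: int = 0
) -> dict:
    """Separated bicluster layout: force-directed base + radial translation.

    A seeded Fruchterman-Reingold layout of the bipartite graph is
    computed, then every community is translated rigidly along the unit
    vector from the global centroid to the community centroid by
    ``explode_factor`` times the layout radius.  Within-community
    pairwise distances are preserved exactly.
    """
    if explode_factor < 0:
        raise DataValidationError("explode_factor must be non-negative")
    base = _base_layout(network.bipartite, seed)
    nodes = list(base)
    pos = np.array([base[n] for n in nodes])
    centroid = pos.mean(axis=0)
    radius = float(np.linalg.norm(pos - centroid, axis=1).max()) or 1.0
    comm_of = network.partition.community_of
    out = {}
    for comm in sorted({comm_of[n] for n in nodes}):
        members = [i for i, n in enumerate(nodes) if comm_of[n] == comm]
        cpos = pos[members]
        ccent = cpos.mean(axis=0)
        vec = ccent - centroid
        norm = np.linalg.norm(vec)
        shift = (vec / norm) * explode_factor * radius if norm > 0 else 0.0
        for i in members:
            out[nodes[i]] = tuple((pos[i] + shift).tolist())
    return out


def inner_outer_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Inner/outer tally with column percentages (2 decimals) and totals."""
    totals = counts.sum(axis=0)
    pct = (100 * counts / totals).round(2)
    out = counts.astype(str) + " (" + pct.astype(str) + ")"
    out.loc["total"] = totals.astype(str) + " (100.0)"
    out["total"] = [
        f"{int(counts.iloc[0].sum())} ({100 * counts.iloc[0].sum() / counts.values.sum():.2f})",
        f"{int(counts.iloc[1].sum())} ({100 * counts.iloc[1].sum() / counts.values.sum():.2f})",
        f"{int(counts.values.sum())} (100.0)",
    ]
    return out


# -- export / import ----------------------------------------------------

def _to_multigraph(network: CoRiskNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for p in network.bipartite.patient_nodes:
        attrs = {
            "type": "patient",
            "community": int(network.partition.community_of[p]),
        }
        if p in network.patient_class:
            attrs["patient_class"] = network.patient_class[p]
        if p in network.coordinates:
            attrs["x"], attrs["y"] = map(float, network.coordinates[p])
        g.add_node(str(p), **attrs)
    for c in network.bipartite.comorbidity_nodes:
        attrs = {
            "type": "comorbidity",
            "community": int(network.partition.community_of[c]),
        }
        if c in network.node_or:
            attrs["odds_ratio"] = float(network.node_or[c])
        if c in network.coordinates:
            attrs["x"], attrs["y"] = map(float, network.coordinates[c])
        g.add_node(str(c), **attrs)
    for p, c in sorted(network.bipartite.edges, key=lambda e: (str(e[0]), str(e[1]))):
        g.add_edge(str(p), str(c), kind="bipartite")
    for e in network.risk_edges:
        g.add_edge(
            e.source, e.target, kind="risk", or_pair=float(e.or_pair),
            direction=e.significant_direction,
        )
    return g


def export_network(network: CoRiskNetwork, fmt: str, path) -> None:
    """Write the CoRisk network as GraphML or JSON (same schema)."""
    g = _to_multigraph(network)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = {
            "nodes": [{"id": n, **g.nodes[n]} for n in g.nodes],
            "edges": [
                {"source": u, "target": v, **data}
                for u, v, data in g.edges(data=True)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise DataValidationError(f"unknown export format {fmt!r}")


def read_network(fmt: str, path) -> CoRiskNetwork:
    """Re-import an exported network (inverse of :func:`export_network`)."""
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        nodes = {n: dict(g.nodes[n]) for n in g.nodes}
        edge_iter = [(u, v, dict(d)) for u, v, d in g.edges(data=True)]
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        nodes = {n.pop("id"): n for n in payload["nodes"]}
        edge_iter = [
            (e.pop("source"), e.pop("target"), e) for e in payload["edges"]
        ]
    else:
        raise DataValidationError(f"unknown import format {fmt!r}")
    patients = [n for n, a in nodes.items() if a.get("type") == "patient"]
    comorbs = [n for n, a in nodes.items() if a.get("type") == "comorbidity"]
    bip_edges = set()
    risk_edges = []
    for u, v, d in edge_iter:
        if d.get("kind") == "bipartite":
            bip_edges.add((u, v))
        else:
            risk_edges.append(
                RiskEdge(u, v, float(d.get("or_pair", float("nan"))),
                         d.get("direction", ""))
            )
    bip = BipartiteGraph(patients, comorbs, bip_edges)
    community_of = {n: int(a["community"]) for n, a in nodes.items()}
    n_comm = len(set(community_of.values()))
    from .bicluster import barber_modularity
    q = barber_modularity(bip, community_of) if bip.m else 0.0
    partition = BiclusterPartition(community_of, n_comm, q)
    net = CoRiskNetwork(bip, partition, risk_edges)
    net.node_or = {
        n: float(a["odds_ratio"]) for n, a in nodes.items() if "odds_ratio" in a
    }
    net.patient_class = {
        n: a["patient_class"] for n, a in nodes.items() if "patient_class" in a
    }
    net.coordinates = {
        n: (float(a["x"]), float(a["y"]))
        for n, a in nodes.items() if "x" in a and "y" in a
    }
    return net


def plot_network(network: CoRiskNetwork, path, figsize=(8.0, 8.0)) -> None:
    """Static vector figure of the exploded CoRisk network."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = network.coordinates or explode_layout(network)
    fig, ax = plt.subplots(figsize=figsize)
    comm_of = network.partition.community_of
    cmap = plt.get_cmap("tab10")
    for p, c in network.bipartite.edges:
        xs = [coords[p][0], coords[c][0]]
        ys = [coords[p][1], coords[c][1]]
        ax.plot(xs, ys, color="0.85", lw=0.3, zorder=1)
    for p in network.bipartite.patient_nodes:
        ax.scatter(*coords[p], s=6, color=cmap(comm_of[p] % 10), zorder=2)
    for c in network.bipartite.comorbidity_nodes:
        ax.scatter(*coords[c], s=120, marker="^",
                   color=cmap(comm_of[c] % 10), edgecolor="k", zorder=3)
        ax.annotate(str(c), coords[c], fontsize=8, zorder=4)
    for e in network.risk_edges:
        ax.annotate(
            "", xy=coords[e.target], xytext=coords[e.source],
            arrowprops={"arrowstyle": "-|>", "color": "crimson", "lw": 1.2},
            zorder=5,
        )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
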