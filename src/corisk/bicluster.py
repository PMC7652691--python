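"""Bipartite patient-comorbidity networks and Barber-modularity biclustering.

Biclusters are communities in the bipartite graph containing both patient
and comorbidity nodes.  They are found by maximizing Barber's bipartite
modularity

    Q_B = (1/m) * sum_{i in patients, j in comorbidities}
              (A_ij - k_i * d_j / m) * delta(g_i, g_j)

with a BRIM-style alternating reassignment: holding the comorbidity
assignments fixed, each patient's optimal community is independent of the
other patients (and symmetrically), so each half-step is an exact
coordinate maximization.  Runs restart from seeded random initializations
over a sweep of initial community counts; ties break toward fewer
communities, then the lexicographically smallest canonical assignment.

Significance is assessed against random bipartite graphs that preserve
only the node sets and the edge count (network size and density), per the
study design; a degree-preserving rewiring null is available as a
sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cohort import CohortMatrix
from .errors import ComputationError, DataValidationError

__all__ = [
    "BipartiteGraph",
    "BiclusterPartition",
    "ModularitySignificance",
    "build_bipartite",
    "barber_modularity",
    "find_biclusters",
    "random_bipartite_same_density",
    "modularity_significance",
    "write_partition",
    "read_partition",
    "write_edgelist",
    "read_edgelist",
]


@dataclass
class BipartiteGraph:
    """Patient-comorbidity bipartite graph (undirected, unweighted)."""

    patient_nodes: list
    comorbidity_nodes: list
    edges: set

    def __post_init__(self) -> None:
        self.patient_nodes = list(self.patient_nodes)
        self.comorbidity_nodes = list(self.comorbidity_nodes)
        self.edges = set(self.edges)
        pset, cset = set(self.patient_nodes), set(self.comorbidity_nodes)
        if len(pset) != len(self.patient_nodes):
            raise DataValidationError("duplicate patient nodes")
        if len(cset) != len(self.comorbidity_nodes):
            raise DataValidationError("duplicate comorbidity nodes")
        for p, c in self.edges:
            if p not in pset or c not in cset:
                raise DataValidationError(
                    f"edge ({p!r}, {c!r}) does not connect the two node types"
                )

    @property
    def m(self) -> int:
        return len(self.edges)

    def biadjacency(self) -> np.ndarray:
        """Dense 0/1 matrix, rows = patients, cols = comorbidities."""
        pi = {p: i for i, p in enumerate(self.patient_nodes)}
        ci = {c: j for j, c in enumerate(self.comorbidity_nodes)}
        A = np.zeros((len(pi), len(ci)), dtype=np.int8)
        for p, c in self.edges:
            A[pi[p], ci[c]] = 1
        return A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.patient_nodes, kind="patient", bipartite=0)
        g.add_nodes_from(self.comorbidity_nodes, kind="comorbidity", bipartite=1)
        g.add_edges_from(self.edges)
        return g


@dataclass
class BiclusterPartition:
    """Community assignment for every node plus its Barber modularity."""

    community_of: dict
    n_communities: int
    q: float

    def comorbidity_labels(self, graph: BipartiteGraph) -> dict:
        return {c: self.community_of[c] for c in graph.comorbidity_nodes}


@dataclass
class ModularitySignificance:
    q_observed: float
    random_mean: float
    random_sd: float
    n_permutations: int
    p_value: float


def build_bipartite(
    cohort: CohortMatrix, comorbidities: list[str], cases_only: bool = True
) -> BipartiteGraph:
    """Graph over the given comorbidities and the patients carrying >= 1.

    With ``cases_only`` (the default, matching the readmitted-patient
    networks), only cases become patient nodes.
    """
    if not comorbidities:
        raise DataValidationError("empty comorbidity subset")
    missing = set(comorbidities) - set(cohort.comorbidity_names)
    if missing:
        raise DataValidationError(f"comorbidities not in cohort: {sorted(missing)}")
    sub = cohort.subset_comorbidities(list(comorbidities))
    mask = sub.X.sum(axis=1) > 0
    if cases_only:
        mask &= sub.is_case
    if not mask.any():
        raise ComputationError("no patients carry any of the listed comorbidities")
    sub = sub.subset_patients(mask)
    edges = {
        (sub.patient_ids[i], comorbidities[j])
        for i, j in zip(*np.nonzero(sub.X))
    }
    return BipartiteGraph(list(sub.patient_ids), list(comorbidities), edges)


def barber_modularity(graph: BipartiteGraph, community_of) -> float:
    """Barber bipartite modularity of a given node partition."""
    if graph.m == 0:
        raise ComputationError("modularity undefined for an edgeless graph")
    for node in graph.patient_nodes + graph.comorbidity_nodes:
        if node not in community_of:
            raise DataValidationError(f"node {node!r} missing from partition")
    A = graph.biadjacency()
    k = A.sum(axis=1).astype(float)
    d = A.sum(axis=0).astype(float)
    m = float(graph.m)
    gp = np.array([community_of[p] for p in graph.patient_nodes])
    gc = np.array([community_of[c] for c in graph.comorbidity_nodes])
    same = gp[:, None] == gc[None, :]
    return float(((A - np.outer(k, d) / m) * same).sum() / m)


def _brim_once(B: np.ndarray, g_c: np.ndarray, m: float, max_iter: int = 200):
    """Alternating exact half-steps from an initial comorbidity assignment.

    Assignment value -1 marks a detached node (its own singleton
    community, contributing 0).  Returns (g_p, g_c, Q).
    """
    n_p, n_c = B.shape
    g_p = np.full(n_p, -1, dtype=int)
    q = -np.inf
    for _ in range(max_iter):
        # patient step: exact argmax per patient given comorbidity labels
        labels = np.unique(g_c[g_c >= 0])
        if labels.size == 0:
            return g_p, g_c, 0.0
        T = (g_c[:, None] == labels[None, :]).astype(float)
        Sp = B @ T
        best = Sp.argmax(axis=1)
        best_val = Sp[np.arange(n_p), best]
        g_p = np.where(best_val >= 0, labels[best], -1)
        # comorbidity step, symmetric
        plabels = np.unique(g_p[g_p >= 0])
        if plabels.size == 0:
            g_c = np.full(n_c, -1, dtype=int)
            return g_p, g_c, 0.0
        R = (g_p[:, None] == plabels[None, :]).astype(float)
        Sc = B.T @ R
        best = Sc.argmax(axis=1)
        best_val = Sc[np.arange(n_c), best]
        g_c = np.where(best_val >= 0, plabels[best], -1)
        # score: sum of within-community B entries
        same = (g_p[:, None] == g_c[None, :]) & (g_p[:, None] >= 0)
        q_new = float((B * same).sum() / m)
        if q_new <= q + 1e-12:
            return g_p, g_c, max(q, q_new)
        q = q_new
    return g_p, g_c, q


def _brim_with_merges(B: np.ndarray, g_c0: np.ndarray, m: float):
    """BRIM to a fixed point, then greedy community merges with re-descent.

    Alternating reassignment alone fragments into many small communities
    on weakly-coupled blocks; merging the community pair with the largest
    positive cross-term (and re-running the alternating steps) escapes
    those local optima while never lowering Q.
    """
    g_p, g_c, q = _brim_once(B, g_c0, m)
    while True:
        labs = np.unique(np.concatenate([g_p[g_p >= 0], g_c[g_c >= 0]]))
        if labs.size <= 1:
            return g_p, g_c, q
        R = (g_p[:, None] == labs[None, :]).astype(float)
        T = (g_c[:, None] == labs[None, :]).astype(float)
        M = R.T @ B @ T
        gain = (M + M.T) / m
        np.fill_diagonal(gain, -np.inf)
        i, j = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[i, j] <= 1e-12:
            return g_p, g_c, q
        a, b = labs[i], labs[j]
        g_p = np.where(g_p == b, a, g_p)
        g_c = np.where(g_c == b, a, g_c)
        g_p2, g_c2, q2 = _brim_once(B, g_c, m)
        if q2 >= q + gain[i, j] - 1e-12:
            g_p, g_c, q = g_p2, g_c2, q2
        else:  # keep the plain merge if re-descent drifted elsewhere
            q = q + gain[i, j]


def _canonical(order_p, order_c, g_p, g_c):
    """Relabel communities by first appearance (patients first)."""
    mapping: dict[int, int] = {}
    nxt = 0
    for g in list(g_p) + list(g_c):
        if g != -1 and g not in mapping:
            mapping[g] = nxt
            nxt += 1
    # singletons (detached / isolated) get the next indices in node order
    labels = []
    for g in list(g_p) + list(g_c):
        if g == -1:
            labels.append(nxt)
            nxt += 1
        else:
            labels.append(mapping[g])
    out_p = labels[: len(g_p)]
    out_c = labels[len(g_p):]
    return np.array(out_p), np.array(out_c), nxt


def find_biclusters(
    graph: BipartiteGraph,
    seed: int = 0,
    restarts: int = 20,
    max_communities: int | None = None,
) -> BiclusterPartition:
    """Maximize Barber modularity by BRIM with restarts.

    Deterministic given ``seed``.  Isolated nodes are assigned singleton
    communities and contribute 0 to Q.  Ties between equal-Q optima break
    toward fewer communities, then the lexicographically smallest
    canonical assignment vector.
    """
    if graph.m == 0:
        raise ComputationError("cannot bicluster an edgeless graph")
    A = graph.biadjacency().astype(float)
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    live_p = np.nonzero(k > 0)[0]
    live_c = np.nonzero(d > 0)[0]
    m = float(graph.m)
    B = (A - np.outer(k, d) / m)[np.ix_(live_p, live_c)]
    n_c = live_c.size
    c_max = n_c if max_communities is None else min(max_communities, n_c)
    rng = np.random.default_rng(seed)
    best = None  # (q, n_comm, labels_p, labels_c)
    inits = [np.zeros(n_c, dtype=int), np.arange(n_c)]
    for n_comm in range(1, c_max + 1):
        for _ in range(restarts):
            inits.append(rng.integers(0, n_comm, size=n_c))
    for g_c0 in inits:
        g_p, g_c, q = _brim_with_merges(B, np.asarray(g_c0, dtype=int), m)
        lp, lc, n_live = _canonical(live_p, live_c, g_p, g_c)
        ncomm = n_live
        cand = (q, ncomm, tuple(lp) + tuple(lc))
        if (
            best is None
            or cand[0] > best[0] + 1e-12
            or (abs(cand[0] - best[0]) <= 1e-12
                and (cand[1], cand[2]) < (best[1], best[2]))
        ):
            best = cand
    q, _, labels = best
    community_of: dict = {}
    nxt = 0
    # live nodes first (canonical labels), then isolated singletons
    lp = labels[: live_p.size]
    lc = labels[live_p.size:]
    for idx, lab in zip(live_p, lp):
        community_of[graph.patient_nodes[idx]] = int(lab)
    for idx, lab in zip(live_c, lc):
        community_of[graph.comorbidity_nodes[idx]] = int(lab)
    nxt = int(max(labels) + 1) if labels else 0
    for idx in np.nonzero(k == 0)[0]:
        community_of[graph.patient_nodes[idx]] = nxt
        nxt += 1
    for idx in np.nonzero(d == 0)[0]:
        community_of[graph.comorbidity_nodes[idx]] = nxt
        nxt += 1
    q_final = barber_modularity(graph, community_of)
    return BiclusterPartition(community_of, int(nxt), q_final)


def random_bipartite_same_density(
    graph: BipartiteGraph, seed=0
) -> BipartiteGraph:
    """Uniform random graph with the same node sets and edge count.

    Degree sequences are *not* preserved; this is the size-and-density
    null of the permutation test.  ``seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n_p, n_c = len(graph.patient_nodes), len(graph.comorbidity_nodes)
    if graph.m > n_p * n_c:
        raise DataValidationError("more edges than grid cells")
    flat = rng.choice(n_p * n_c, size=graph.m, replace=False)
    edges = {
        (graph.patient_nodes[f // n_c], graph.comorbidity_nodes[f % n_c])
        for f in flat
    }
    return BipartiteGraph(
        list(graph.patient_nodes), list(graph.comorbidity_nodes), edges
    )


def _degree_preserving_rewire(
    graph: BipartiteGraph, rng: np.random.Generator
) -> BipartiteGraph:
    """Double-edge-swap null preserving both degree sequences (sensitivity)."""
    edges = list(graph.edges)
    edge_set = set(edges)
    n_swaps = 10 * len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        (p1, c1), (p2, c2) = edges[i], edges[j]
        if p1 == p2 or c1 == c2:
            continue
        if (p1, c2) in edge_set or (p2, c1) in edge_set:
            continue
        edge_set -= {(p1, c1), (p2, c2)}
        edge_set |= {(p1, c2), (p2, c1)}
        edges[i], edges[j] = (p1, c2), (p2, c1)
    return BipartiteGraph(
        list(graph.patient_nodes), list(graph.comorbidity_nodes), edge_set
    )


def modularity_significance(
    graph: BipartiteGraph,
    q_observed: float,
    n_permutations: int = 1000,
    seed: int = 0,
    restarts: int = 20,
    max_communities: int | None = None,
    null: str = "density",
) -> ModularitySignificance:
    """Permutation test of Q against re-optimized random graphs.

    Each permutation draws a fresh null graph, maximizes its own Q with
    the same optimizer settings, and the p-value uses the (r+1)/(R+1)
    convention, so the minimum attainable with 1000 permutations is
    1/1001 (< .001).
    """
    if n_permutations < 1:
        raise DataValidationError("need >= 1 permutation")
    rng = np.random.default_rng(seed)
    qs = np.empty(n_permutations)
    for r in range(n_permutations):
        if null == "density":
            g = random_bipartite_same_density(graph, rng)
        elif null == "degree":
            g = _degree_preserving_rewire(graph, rng)
        else:
            raise DataValidationError(f"unknown null model {null!r}")
        part = find_biclusters(
            g, seed=int(rng.integers(2**31)), restarts=restarts,
            max_communities=max_communities,
        )
        qs[r] = part.q
    p = (1 + int((qs >= q_observed).sum())) / (n_permutations + 1)
    return ModularitySignificance(
        q_observed, float(qs.mean()), float(qs.std(ddof=1)) if n_permutations > 1
        else 0.0, n_permutations, p,
    )


# -- plain-text export/import -------------------------------------------

def write_partition(partition: BiclusterPartition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tcommunity\n")
        for node, comm in partition.community_of.items():
            fh.write(f"{node}\t{comm}\n")


def read_partition(path) -> dict:
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("node"):
            raise DataValidationError(f"{path}: missing partition header")
        for line in fh:
            node, comm = line.rstrip("\n").split("\t")
            out[node] = int(comm)
    return out


def write_edgelist(graph: BipartiteGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient\tcomorbidity\n")
        for p, c in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{p}\t{c}\n")


def read_edgelist(path) -> BipartiteGraph:
    patients: dict = {}
    comorbs: dict = {}
    edges = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("patient"):
            raise DataValidationError(f"{path}: missing edge-list header")
        for line in fh:
            p, c = line.rstrip("\n").split("\t")
            patients[p] = None
            comorbs[c] = None
            edges.add((p, c))
    return BipartiteGraph(list(patients), list(comorbs), edges)
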