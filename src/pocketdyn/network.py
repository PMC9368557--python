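"""Calpha cross-correlation networks and community analysis.

The dynamical cross-correlation matrix (DCCM) holds, for every pair of
nodes, C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) where dr is the
displacement of a node from its time-mean position: +1 fully correlated,
-1 fully anticorrelated. One Calpha per residue is the usual node choice;
the ligand enters as a single extra node at its heavy-atom centroid.

The residue network follows the standard dynamical-network convention:
an edge joins two nodes when they stay in heavy-atom contact in at least a
fraction ``f_min`` of frames, weighted w_ij = -log|C_ij| so that strong
correlation means short distance. Communities come from Girvan-Newman
edge removal (weighted betweenness, weights as distances) scored by
Newman-Girvan modularity Q (weights as strengths) on the original graph;
the partition with the highest Q over the removal sequence is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .model import Selection, Topology, Trajectory

LIGAND_NODE = "LIG"


@dataclass
class Dccm:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix, dtype=np.float64)
        if c.shape != (len(self.labels), len(self.labels)):
            raise InputError("matrix shape must match the label count")
        self.matrix = c


@dataclass
class CommunityPartition:
    mapping: dict  # node -> community id
    q: float

    def community_of(self, node) -> int:
        return self.mapping[node]

    def members(self, community: int) -> list:
        return [n for n, c in self.mapping.items() if c == community]


def node_positions(
    trajectory: Trajectory,
    node_selection: Selection,
    ligand: Selection | None = None,
) -> np.ndarray:
    """(F, N[, +1], 3) positions: one atom per node, plus the ligand
    heavy-atom centroid as a final node when given."""
    pos = trajectory.coordinates[:, node_selection.atom_indices, :]
    if ligand is not None and len(ligand):
        cen = trajectory.coordinates[:, ligand.atom_indices, :].mean(axis=1)
        pos = np.concatenate([pos, cen[:, None, :]], axis=1)
    return pos


def compute_dccm(
    trajectory: Trajectory,
    node_selection: Selection,
    node_labels: list[str] | None = None,
    fit_selection: Selection | None = None,
    ligand: Selection | None = None,
) -> Dccm:
    """Cross-correlation of node displacement vectors.

    When ``fit_selection`` is given the trajectory is first superposed on
    the mean structure, iterated twice so the mean is self-consistent.
    A node with zero displacement variance is an error (its correlation is
    undefined); the error names the node.
    """
    if trajectory.n_frames < 10:
        raise InputError("need at least 10 frames for a meaningful DCCM")
    traj = trajectory
    if fit_selection is not None:
        from .cluster import superpose

        for _ in range(2):
            mean = traj.coordinates.mean(axis=0)
            traj = superpose(traj, mean, fit_selection)
    pos = node_positions(traj, node_selection, ligand)
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(len(node_selection))]
    labels = list(node_labels)
    if ligand is not None and len(ligand):
        labels = labels + [LIGAND_NODE]
    if len(labels) != pos.shape[1]:
        raise InputError("label count does not match node count")

    disp = pos - pos.mean(axis=0)  # (F, N, 3)
    cov = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov)
    # relative threshold: mean subtraction leaves ~1e-30 residuals on
    # genuinely static nodes
    zero = np.nonzero(var <= var.max() * 1e-18)[0]
    if zero.size:
        raise InputError(f"node {labels[zero[0]]} has zero displacement variance")
    c = cov / np.sqrt(np.outer(var, var))
    c = (c + c.T) / 2.0
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return Dccm(labels, c)


def contact_eligibility(
    trajectory: Trajectory,
    topology: Topology,
    node_residues: list[int],
    ligand: Selection | None = None,
    f_min: float = 0.75,
    cutoff: float = 0.45,
) -> np.ndarray:
    """Boolean eligibility matrix for network edges: node pairs whose
    heavy atoms are within ``cutoff`` in at least ``f_min`` of frames.
    The ligand (last node when given) uses its heavy atoms."""
    sels = []
    for resid in node_residues:
        res = topology.residue(resid)
        idx = [i for i in range(res.first_atom, res.last_atom) if topology.atoms[i].is_heavy]
        sels.append(np.asarray(idx))
    if ligand is not None and len(ligand):
        heavy = [i for i in ligand.atom_indices if topology.atoms[i].is_heavy]
        sels.append(np.asarray(heavy))
    n = len(sels)
    counts = np.zeros((n, n))
    for f in range(trajectory.n_frames):
        x = trajectory.coordinates[f]
        for i in range(n):
            for j in range(i + 1, n):
                if cdist(x[sels[i]], x[sels[j]]).min() <= cutoff:
                    counts[i, j] += 1
    counts = counts + counts.T
    elig = counts / trajectory.n_frames >= f_min
    np.fill_diagonal(elig, False)
    return elig


def build_network(
    dccm: Dccm,
    eligibility: np.ndarray | None = None,
) -> nx.Graph:
    """Correlation-weighted graph: edge (i, j) iff eligible and |C_ij| > 0,
    with weight -log|C_ij| (0 = strongest possible link)."""
    n = len(dccm.labels)
    if eligibility is not None and np.asarray(eligibility).shape != (n, n):
        raise InputError("eligibility matrix shape mismatch")
    g = nx.Graph()
    g.add_nodes_from(dccm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if eligibility is not None and not eligibility[i, j]:
                continue
            c = abs(dccm.matrix[i, j])
            if c <= 0:
                continue
            g.add_edge(dccm.labels[i], dccm.labels[j], weight=float(-np.log(c)))
    return g


def modularity(graph: nx.Graph, partition: dict) -> float:
    """Weighted Newman-Girvan modularity Q = sum_c (L_c/m - (d_c/2m)^2)."""
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise InputError(f"partition is missing node {missing[0]!r}")
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    internal: dict = {}
    degree: dict = {}
    for u, v, w in graph.edges(data="weight", default=1.0):
        cu, cv = partition[u], partition[v]
        degree[cu] = degree.get(cu, 0.0) + w
        degree[cv] = degree.get(cv, 0.0) + w
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
    q = 0.0
    for c in set(partition.values()):
        q += internal.get(c, 0.0) / m - (degree.get(c, 0.0) / (2 * m)) ** 2
    return float(q)


def _components_partition(graph: nx.Graph) -> dict:
    part = {}
    for cid, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda s: sorted(map(str, s)))
    ):
        for node in comp:
            part[node] = cid
    return part


def girvan_newman(graph: nx.Graph) -> CommunityPartition:
    """Best-modularity partition along the Girvan-Newman removal sequence.

    Repeatedly removes the edge of highest weighted betweenness (weights
    as distances; ties broken by lexicographic edge order), evaluating the
    connected-component partition against the ORIGINAL graph's modularity
    after every removal. Disconnected inputs are handled naturally: their
    components are already separate communities.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("empty graph")
    for u, v in graph.edges:
        if u == v:
            raise InputError("graph must not contain self-loops")
    work = graph.copy()
    best_part = _components_partition(work)
    best_q = modularity(graph, best_part)
    while work.number_of_edges() > 0:
        bet = nx.edge_betweenness_centrality(work, weight="weight", normalized=False)
        best_edge = min(
            bet,
            key=lambda e: (-bet[e], tuple(sorted((str(e[0]), str(e[1]))))),
        )
        work.remove_edge(*best_edge)
        part = _components_partition(work)
        q = modularity(graph, part)
        if q > best_q + 1e-12:
            best_q = q
            best_part = part
    return CommunityPartition(best_part, best_q)


def ligand_coupling(
    partition: CommunityPartition,
    ligand_node: str = LIGAND_NODE,
    ss_map: dict[int, str] | None = None,
) -> dict:
    """Residues sharing the ligand's community, grouped by secondary-
    structure element.

    Node labels are expected to embed the author residue index (e.g.
    "I35"); ``ss_map`` maps that index to an element name ("alphaA", ...).
    Unmapped residues land under "other".
    """
    if ligand_node not in partition.mapping:
        raise InputError(f"ligand node {ligand_node!r} not in partition")
    community = partition.mapping[ligand_node]
    residues = [n for n in partition.members(community) if n != ligand_node]
    by_element: dict[str, list] = {}
    for node in sorted(residues, key=str):
        digits = "".join(ch for ch in str(node) if ch.isdigit())
        element = "other"
        if ss_map is not None and digits:
            element = ss_map.get(int(digits), "other")
        by_element.setdefault(element, []).append(str(node))
    return {
        "community": int(community),
        "elements": {e: {"residues": v, "count": len(v)} for e, v in sorted(by_element.items())},
    }
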