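"""DCCM, network construction, communities and the modularity oracle.

The modularity oracle enumerates every partition of the node set (feasible
for <= 8 nodes) and evaluates weighted Newman-Girvan modularity through
networkx, independently of the package's implementation.
"""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from pocketdyn.errors import InputError
from pocketdyn.model import Selection, Trajectory
from pocketdyn.network import (
    Dccm,
    build_network,
    compute_dccm,
    girvan_newman,
    ligand_coupling,
    modularity,
)
from pocketdyn.synthetic import (
    PlantedCovariance,
    gen_correlated_trajectory,
    gen_planted_graph,
)


def _set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_best_modularity(graph):
    """Independent oracle: global maximum of weighted modularity."""
    nodes = list(graph.nodes)
    best = -np.inf
    best_part = None
    for part in _set_partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in part], weight="weight")
        if q > best + 1e-12:
            best, best_part = q, part
    return best, best_part


def _graph(edges):
    g = nx.Graph()
    g.add_weighted_edges_from((u, v, 1.0) for u, v in edges)
    return g


BRIDGE = _graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])
TRIANGLES = _graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
PATH6 = _graph([(i, i + 1) for i in range(5)])
STAR6 = _graph([(0, i) for i in range(1, 6)])
CLIQUE5 = _graph(combinations(range(5), 2))


class TestDccm:
    def test_duplicate_motion_perfectly_correlated(self, rng):
        base = rng.normal(size=(3, 3))
        disp = rng.normal(size=(50, 1, 3))
        coords = np.broadcast_to(base, (50, 3, 3)).copy()
        coords[:, 0] += disp[:, 0]
        coords[:, 1] += disp[:, 0]  # same motion
        coords[:, 2] -= disp[:, 0]  # opposite motion
        d = compute_dccm(Trajectory(coords), Selection("n", [0, 1, 2]))
        assert d.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert d.matrix[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_planted_recovery(self, rng):
        c = np.eye(10)
        c[0, 1] = c[1, 0] = 0.8
        c[2, 3] = c[3, 2] = -0.8
        base = rng.normal(size=(10, 3))
        traj = gen_correlated_trajectory(base, PlantedCovariance(c), 5000, seed=3)
        d = compute_dccm(traj, Selection("n", np.arange(10)))
        assert np.abs(d.matrix - c).max() < 0.05

    def test_rigid_motion_invariance(self, rng):
        base = rng.normal(size=(6, 3))
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.7
        traj = gen_correlated_trajectory(
            base, PlantedCovariance(c), 200, seed=5, node_indices=np.arange(4)
        )
        fit = Selection("fit", np.arange(6))
        nodes = Selection("n", np.arange(4))
        d1 = compute_dccm(traj, nodes, fit_selection=fit)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True)
        moved = Trajectory(rot.apply(
            traj.coordinates.reshape(-1, 3)).reshape(traj.coordinates.shape)
            + np.array([1.0, 2.0, -3.0]))
        d2 = compute_dccm(moved, nodes, fit_selection=fit)
        np.testing.assert_allclose(d1.matrix, d2.matrix, atol=1e-10)

    def test_zero_variance_node_named(self, rng):
        coords = np.broadcast_to(rng.normal(size=(4, 3)), (20, 4, 3)).copy()
        coords[:, 0] += rng.normal(size=(20, 3))
        with pytest.raises(InputError, match="frozen"):
            compute_dccm(Trajectory(coords), Selection("n", [0, 1]),
                         node_labels=["moving", "frozen"])


class TestBuildNetwork:
    def test_weight_closed_forms(self):
        c = np.array([[1.0, 1.0, np.exp(-1)],
                      [1.0, 1.0, 0.5],
                      [np.exp(-1), 0.5, 1.0]])
        g = build_network(Dccm(["a", "b", "c"], c))
        assert g["a"]["b"]["weight"] == pytest.approx(0.0)
        assert g["a"]["c"]["weight"] == pytest.approx(1.0)

    def test_contact_filter_vetoes_edges(self):
        c = np.array([[1.0, 0.9], [0.9, 1.0]])
        elig = np.array([[False, False], [False, False]])
        g = build_network(Dccm(["a", "b"], c), elig)
        assert g.number_of_edges() == 0


class TestModularity:
    def test_single_community_zero(self):
        part = {n: 0 for n in CLIQUE5}
        assert modularity(CLIQUE5, part) == pytest.approx(0.0)

    def test_all_singletons_negative(self):
        part = {n: n for n in CLIQUE5}
        assert modularity(CLIQUE5, part) < 0

    def test_missing_node_rejected(self):
        with pytest.raises(InputError):
            modularity(CLIQUE5, {0: 0})

    @pytest.mark.parametrize("graph", [BRIDGE, TRIANGLES, PATH6, STAR6, CLIQUE5])
    def test_matches_networkx_on_fixtures(self, graph):
        part = {n: n % 2 for n in graph}
        comms = [set(n for n in graph if n % 2 == c) for c in (0, 1)]
        assert modularity(graph, part) == pytest.approx(
            nx.community.modularity(graph, comms, weight="weight")
        )


class TestGirvanNewman:
    @pytest.mark.parametrize("graph", [BRIDGE, TRIANGLES, PATH6, STAR6, CLIQUE5])
    def test_attains_exhaustive_maximum(self, graph):
        part = girvan_newman(graph)
        best_q, _ = exhaustive_best_modularity(graph)
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_self_consistency(self):
        part = girvan_newman(BRIDGE)
        assert part.q == pytest.approx(modularity(BRIDGE, part.mapping))

    def test_bridge_graph_splits_at_bridge(self):
        part = girvan_newman(BRIDGE)
        assert part.mapping[0] == part.mapping[1] == part.mapping[2]
        assert part.mapping[3] == part.mapping[4] == part.mapping[5]
        assert part.mapping[0] != part.mapping[3]
        assert part.q == pytest.approx(5 / 14)  # oracle-computed maximum

    def test_disconnected_triangles(self):
        part = girvan_newman(TRIANGLES)
        assert part.q == pytest.approx(0.5)

    def test_single_clique_one_community(self):
        part = girvan_newman(CLIQUE5)
        assert len(set(part.mapping.values())) == 1
        assert part.q == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            girvan_newman(nx.Graph())

    def test_planted_sbm_recovery_sample(self):
        hits = 0
        for seed in range(20):
            g, labels = gen_planted_graph([8, 8], 0.9, 0.05, seed=seed)
            part = girvan_newman(g)
            pred = [part.mapping[i] for i in range(16)]
            hits += adjusted_rand_score(labels, pred) == 1.0
        assert hits >= 19


class TestLigandCoupling:
    def test_report_groups_by_element(self):
        from pocketdyn.network import CommunityPartition

        part = CommunityPartition({"LIG": 0, "A58": 0, "K83": 1, "I35": 0}, 0.3)
        rep = ligand_coupling(part, ss_map={58: "alphaA", 83: "alphaB", 35: "betaB"})
        assert set(rep["elements"]) == {"alphaA", "betaB"}
        assert rep["elements"]["alphaA"]["count"] == 1

    def test_isolated_ligand_empty(self):
        from pocketdyn.network import CommunityPartition

        part = CommunityPartition({"LIG": 0, "A58": 1}, 0.0)
        assert ligand_coupling(part, ss_map={58: "alphaA"})["elements"] == {}

    def test_planted_coupling_recovered(self, rng):
        """When the ligand node's latent motion equals that of the
        alphaA-labelled nodes, the coupling report names alphaA."""
        c = np.eye(7)
        alpha_nodes = [0, 1, 2]  # will be labelled A56..A58 (alphaA)
        lig = 6
        for i in alpha_nodes:
            c[i, lig] = c[lig, i] = 0.95
            for j in alpha_nodes:
                if i != j:
                    c[i, j] = c[j, i] = 0.95
        base = rng.normal(scale=2.0, size=(7, 3))
        traj = gen_correlated_trajectory(base, PlantedCovariance(c), 2000, seed=6)
        labels = ["A56", "A57", "A58", "K83", "V84", "A87", "LIG"]
        d = compute_dccm(Trajectory(traj.coordinates), Selection("n", np.arange(7)),
                         node_labels=labels)
        # contact filter: only pairs with planted interaction are eligible
        elig = np.abs(c) > 0
        np.fill_diagonal(elig, False)
        part = girvan_newman(build_network(d, elig))
        rep = ligand_coupling(
            part, ss_map={56: "alphaA", 57: "alphaA", 58: "alphaA",
                          83: "alphaB", 84: "alphaB", 87: "alphaB"})
        assert "alphaA" in rep["elements"]
        assert rep["elements"]["alphaA"]["count"] == 3
        assert "alphaB" not in rep["elements"]
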