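"""Bayesian-network search, transitive pruning, Boolean gates, sensor screen."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mhbcircuit.circuit import (
    BayesNetStructure,
    BooleanCircuit,
    GateFit,
    NodeTable,
    _exhaustive_fit,
    _FamilyScorer,
    _label_gate,
    build_node_table,
    candidate_genes,
    circuit_to_dot,
    cluster_node_name,
    condition_states,
    discretize_nodes,
    fit_gates,
    learn_structure,
    screen_sensor_candidates,
    transitive_prune,
)
from mhbcircuit.cluster import ClusterModel
from mhbcircuit.io import CONDITIONS, IntegrityError

from test_anova import DESIGN


def discrete_table(frame, n_states=None, presence=()):
    """NodeTable over pre-discretized states (values double as states)."""
    kinds = {c: ("presence" if c in presence else "cluster") for c in frame.columns}
    cluster_of = {c: i for i, c in enumerate(frame.columns) if c not in presence}
    if n_states is None:
        n_states = {c: int(frame[c].max()) + 1 for c in frame.columns}
    return NodeTable(
        frame.astype(float), kinds, cluster_of, frame.astype(int), n_states
    )


# ---------------------------------------------------------------------------
# node table and discretization
# ---------------------------------------------------------------------------

class TestNodeTable:
    def make_model_matrix(self):
        genes = [f"g{i}" for i in range(4)]
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(
            rng.normal(size=(4, 12)), index=genes, columns=DESIGN.sample_ids
        )
        assignment = pd.Series([0, 0, 1, 1], index=genes, name="cluster")
        model = ClusterModel(2, assignment, np.zeros((2, 12)), {2: 0.1})
        return model, matrix

    def test_cluster_node_is_mean_member_expression(self):
        model, matrix = self.make_model_matrix()
        table = build_node_table(model, matrix, DESIGN)
        expected = matrix.loc[["g0", "g1"]].mean(axis=0)
        np.testing.assert_allclose(table.values["cluster_0"], expected)
        assert table.kinds["fungus"] == "presence"
        assert set(table.values["fungus"].unique()) <= {0.0, 1.0}

    def test_single_gene_cluster_equals_gene_row(self):
        genes = ["g0"]
        matrix = pd.DataFrame(
            [np.arange(12.0)], index=genes, columns=DESIGN.sample_ids
        )
        model = ClusterModel(
            1, pd.Series([0], index=genes), np.zeros((1, 12)), {}
        )
        table = build_node_table(model, matrix, DESIGN)
        np.testing.assert_array_equal(
            table.values["cluster_0"], matrix.loc["g0"].to_numpy()
        )

    def test_sample_permutation_permutes_rows_identically(self):
        model, matrix = self.make_model_matrix()
        base = build_node_table(model, matrix, DESIGN)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(DESIGN.frame))
        from mhbcircuit.io import StudyDesign

        permuted_design = StudyDesign(DESIGN.frame.iloc[perm].reset_index(drop=True))
        permuted = build_node_table(model, matrix, permuted_design)
        pd.testing.assert_frame_equal(
            permuted.values, base.values.iloc[perm]
        )


class TestDiscretize:
    def test_quantile_thirds(self):
        frame = pd.DataFrame({"cluster_0": [1.0, 2, 3, 4, 5, 6]})
        table = NodeTable(frame, {"cluster_0": "cluster"}, {"cluster_0": 0})
        out = discretize_nodes(table, n_bins=3)
        assert out.states["cluster_0"].tolist() == [0, 0, 1, 1, 2, 2]
        assert out.n_states["cluster_0"] == 3

    def test_presence_nodes_pass_through(self):
        frame = pd.DataFrame(
            {"fungus": [0.0, 1, 0, 1], "cluster_0": [1.0, 2, 3, 4]}
        )
        table = NodeTable(
            frame,
            {"fungus": "presence", "cluster_0": "cluster"},
            {"cluster_0": 0},
        )
        out = discretize_nodes(table, n_bins=2)
        assert out.states["fungus"].tolist() == [0, 1, 0, 1]

    def test_monotone_transform_leaves_states_unchanged(self):
        values = np.array([0.3, -1.2, 2.0, 0.9, -0.4, 1.1])
        frame = pd.DataFrame({"cluster_0": values})
        table = NodeTable(frame, {"cluster_0": "cluster"}, {"cluster_0": 0})
        mono = pd.DataFrame({"cluster_0": np.exp(values)})
        table2 = NodeTable(mono, {"cluster_0": "cluster"}, {"cluster_0": 0})
        a = discretize_nodes(table, 3).states
        b = discretize_nodes(table2, 3).states
        pd.testing.assert_frame_equal(a, b)

    def test_constant_node_flagged(self):
        frame = pd.DataFrame({"cluster_0": [1.0, 1, 1, 1]})
        table = NodeTable(frame, {"cluster_0": "cluster"}, {"cluster_0": 0})
        with pytest.warns(UserWarning, match="constant"):
            out = discretize_nodes(table, 2)
        assert out.states["cluster_0"].nunique() == 1


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------

def enumerate_dags(nodes):
    """All DAGs over the node set (brute force over edge subsets)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


def mec_signature(g):
    """Markov-equivalence class: skeleton plus v-structures."""
    skeleton = frozenset(frozenset(e) for e in g.edges())
    vs = set()
    for c in g.nodes():
        for a, b in itertools.combinations(sorted(g.predecessors(c)), 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                vs.add((a, b, c))
    return skeleton, frozenset(vs)


class TestLearnStructure:
    def test_independent_nodes_stay_mostly_unconnected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(
                rng.integers(0, 3, size=(30, 4)),
                columns=[f"n{i}" for i in range(4)],
            )
            net = learn_structure(
                discrete_table(frame), max_parents=3, n_restarts=2, seed=seed
            )
            hits += len(net.edges) <= 1
        assert hits >= 45  # >= 90% of seeds

    def test_chain_recovered_up_to_markov_equivalence(self):
        rng = np.random.default_rng(3)
        n = 200
        x0 = rng.integers(0, 2, size=n)
        cols = {"A": x0}
        prev = x0
        for name in ("B", "C", "D"):
            flip = rng.random(n) < 0.1
            prev = np.where(flip, 1 - prev, prev)
            cols[name] = prev
        frame = pd.DataFrame(cols)
        table = discrete_table(frame)
        net = learn_structure(table, max_parents=3, n_restarts=5, seed=0)

        scorer = _FamilyScorer(table.states, table.n_states)
        best_g, best_s = None, -np.inf
        for g in enumerate_dags(list(frame.columns)):
            s = scorer.total({v: tuple(g.predecessors(v)) for v in g.nodes()})
            if s > best_s:
                best_g, best_s = g, s
        assert net.score == pytest.approx(best_s, abs=1e-9)
        assert mec_signature(net.to_networkx()) == mec_signature(best_g)
        # the chain itself has no v-structures and the right skeleton
        truth = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "D")])
        truth.add_nodes_from(frame.columns)
        assert mec_signature(net.to_networkx()) == mec_signature(truth)

    def test_presence_nodes_are_never_children(self, fitted):
        for u, v in fitted.network.edges:
            assert v not in ("fungus", "bacterium")
        assert fitted.network.parents["fungus"] == ()
        assert fitted.network.parents["bacterium"] == ()

    def test_learned_score_beats_empty_graph(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, size=60)
        frame = pd.DataFrame({"A": x, "B": x})  # perfectly dependent pair
        table = discrete_table(frame)
        net = learn_structure(table, n_restarts=2, seed=1)
        scorer = _FamilyScorer(table.states, table.n_states)
        assert net.score > scorer.total({"A": (), "B": ()})
        assert len(net.edges) == 1

    def test_requires_discretized_states_and_samples(self):
        frame = pd.DataFrame({"A": [0, 1, 0]})
        bare = NodeTable(frame.astype(float), {"A": "cluster"}, {"A": 0})
        with pytest.raises(ValueError, match="discretized"):
            learn_structure(bare)
        with pytest.raises(IntegrityError):
            learn_structure(discrete_table(frame.iloc[:1]))

    def test_max_parents_cap_respected(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=100)
        cols = {f"n{i}": np.where(rng.random(100) < 0.2, 1 - y, y) for i in range(6)}
        frame = pd.DataFrame(cols)
        net = learn_structure(discrete_table(frame), max_parents=2, n_restarts=3, seed=2)
        assert all(len(ps) <= 2 for ps in net.parents.values())


# ---------------------------------------------------------------------------
# transitive pruning
# ---------------------------------------------------------------------------

def structure_from_edges(nodes, edges):
    parents = {n: tuple(sorted(u for u, v in edges if v == n)) for n in nodes}
    return BayesNetStructure(tuple(nodes), parents, 0.0)


def brute_force_reduction(g):
    """An edge of a DAG is redundant iff another path links its endpoints."""
    out = g.copy()
    for u, v in g.edges():
        g2 = g.copy()
        g2.remove_edge(u, v)
        if nx.has_path(g2, u, v):
            out.remove_edge(u, v)
    return out


class TestTransitivePrune:
    def test_documented_triangle(self):
        net = structure_from_edges("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        pruned = transitive_prune(net)
        assert set(pruned.edges) == {("A", "B"), ("B", "C")}

    def test_chain_unchanged(self):
        net = structure_from_edges("ABC", [("A", "B"), ("B", "C")])
        assert set(transitive_prune(net).edges) == {("A", "B"), ("B", "C")}

    def test_random_dags_match_bruteforce_and_preserve_reachability(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            nodes = [f"n{i}" for i in range(n)]
            order = rng.permutation(n)
            edges = [
                (nodes[order[i]], nodes[order[j]])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            net = structure_from_edges(nodes, edges)
            pruned = transitive_prune(net)
            expected = brute_force_reduction(net.to_networkx())
            assert set(pruned.edges) == set(expected.edges())
            closure_before = nx.transitive_closure_dag(net.to_networkx())
            closure_after = nx.transitive_closure_dag(pruned.to_networkx())
            assert set(closure_before.edges()) == set(closure_after.edges())
            # idempotent
            assert set(transitive_prune(pruned).edges) == set(pruned.edges)

    def test_cyclic_input_rejected(self):
        net = structure_from_edges("AB", [("A", "B"), ("B", "A")])
        with pytest.raises(IntegrityError):
            transitive_prune(net)


# ---------------------------------------------------------------------------
# Boolean gates
# ---------------------------------------------------------------------------

ALL_COMBOS = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])


class TestGateFitting:
    @pytest.mark.parametrize("fn", range(16))
    def test_every_two_input_table_is_reproduced_exactly(self, fn):
        target = np.array([(fn >> j) & 1 for j in range(4)])
        table, mismatches = _exhaustive_fit(ALL_COMBOS, target)
        assert mismatches == 0
        idx = ALL_COMBOS[:, 0] + 2 * ALL_COMBOS[:, 1]
        np.testing.assert_array_equal(np.array(table)[idx], target)

    def test_constant_and_single_input_labels(self):
        assert _label_gate((1, 1, 1, 1), 2)[0] == "CONST1"
        assert _label_gate((0, 0, 0, 0), 2)[0] == "CONST0"
        assert _label_gate((0, 1, 0, 1), 2)[0] == "ID"
        assert _label_gate((1, 0, 1, 0), 2)[0] == "NOT"

    def test_named_two_input_gates(self):
        assert _label_gate((0, 0, 0, 1), 2)[0] == "AND"
        assert _label_gate((0, 1, 1, 1), 2)[0] == "OR"
        assert _label_gate((0, 1, 1, 0), 2)[0] == "XOR"
        assert _label_gate((1, 0, 0, 1), 2)[0] == "XNOR"
        assert _label_gate((1, 1, 1, 0), 2)[0] == "NAND"
        assert _label_gate((1, 0, 0, 0), 2)[0] == "NOR"
        assert _label_gate((1, 1, 0, 1), 2)[0] == "GENERIC-2"

    def test_labels_invariant_to_input_permutation(self):
        for fn in range(16):
            table = tuple((fn >> j) & 1 for j in range(4))
            swapped = tuple(table[(j >> 1) | ((j & 1) << 1)] for j in range(4))
            assert _label_gate(table, 2)[0] == _label_gate(swapped, 2)[0]


def xor_node_table():
    """A cluster node ON exactly in the single-inoculation conditions."""
    cond = DESIGN.condition
    up = cond.isin(["fungus", "bacterium"]).astype(float).to_numpy() * 2.0
    frame = pd.DataFrame(
        {
            "cluster_0": up,
            "fungus": DESIGN.frame["fungus"].to_numpy(dtype=float),
            "bacterium": DESIGN.frame["bacterium"].to_numpy(dtype=float),
        },
        index=DESIGN.sample_ids,
    )
    kinds = {"cluster_0": "cluster", "fungus": "presence", "bacterium": "presence"}
    return NodeTable(frame, kinds, {"cluster_0": 0})


class TestFitGates:
    def test_xor_gate_for_single_inoculation_activation(self):
        table = xor_node_table()
        net = structure_from_edges(
            table.nodes, [("fungus", "cluster_0"), ("bacterium", "cluster_0")]
        )
        circuit = fit_gates(net, table, DESIGN, up_threshold=0.5)
        gate = circuit.gates["cluster_0"]
        assert gate.gate == "XOR"
        assert gate.mismatches == 0
        assert set(gate.relevant) == {"fungus", "bacterium"}
        assert circuit.xor_nodes() == ["cluster_0"]
        states = circuit.condition_states["cluster_0"]
        assert states.loc[list(CONDITIONS)].tolist() == [0, 1, 1, 0]

    def test_condition_states_dead_zone(self):
        table = xor_node_table()
        # halve the activation so it sits inside a wide dead zone
        table = NodeTable(
            table.values.assign(cluster_0=table.values["cluster_0"] / 4),
            table.kinds,
            table.cluster_of,
        )
        states = condition_states(table, DESIGN, up_threshold=0.6)
        assert states["cluster_0"].tolist() == [0, 0, 0, 0]

    def test_gate_label_invariant_to_parent_order(self):
        table = xor_node_table()
        for parent_order in (("fungus", "bacterium"), ("bacterium", "fungus")):
            net = BayesNetStructure(
                tuple(table.nodes),
                {"cluster_0": parent_order, "fungus": (), "bacterium": ()},
                0.0,
            )
            circuit = fit_gates(net, table, DESIGN)
            assert circuit.gates["cluster_0"].gate == "XOR"

    def test_dot_export_mentions_gate_and_inhibition_arrows(self):
        table = xor_node_table()
        net = structure_from_edges(
            table.nodes, [("fungus", "cluster_0"), ("bacterium", "cluster_0")]
        )
        circuit = fit_gates(net, table, DESIGN)
        dot = circuit_to_dot(circuit, output_node="cluster_0")
        assert "digraph" in dot and "[XOR]" in dot
        assert dot.count("->") == 2


# ---------------------------------------------------------------------------
# sensor-candidate screen
# ---------------------------------------------------------------------------

class TestSensorScreen:
    def build(self, annotate_second_cluster=False):
        genes = [f"g{i}" for i in range(30)]
        assignment = pd.Series([i // 10 for i in range(30)], index=genes)
        model = ClusterModel(3, assignment, np.zeros((3, 12)), {3: 0.2})
        annotations = {g: {"GO:0000001"} for g in genes}
        planted = genes[10:18]  # 8 genes in cluster 1
        for g in planted:
            annotations[g].add("GO:0048544")
        if annotate_second_cluster:
            for g in genes[0:10]:
                annotations[g].add("GO:0048544")
        from mhbcircuit.enrich import enrich_clusters

        enrichment = enrich_clusters(assignment, annotations, genes)
        cstates = pd.DataFrame(
            {
                "cluster_1": [0, 1, 1, 0],
                "fungus": [0, 1, 0, 1],
                "bacterium": [0, 0, 1, 1],
            },
            index=list(CONDITIONS),
        )
        gate = GateFit(
            "cluster_1",
            ("fungus", "bacterium"),
            (0, 1, 1, 0),
            "XOR",
            ("fungus", "bacterium"),
            0,
        )
        structure = structure_from_edges(
            ["cluster_1", "fungus", "bacterium"],
            [("fungus", "cluster_1"), ("bacterium", "cluster_1")],
        )
        circuit = BooleanCircuit(cstates, {"cluster_1": gate}, structure, 0.5)
        return circuit, enrichment, model, annotations, planted

    def test_planted_unique_sensor_genes_are_returned_exactly(self):
        circuit, enrichment, model, annotations, planted = self.build()
        screen = screen_sensor_candidates(circuit, enrichment, model, annotations)
        assert candidate_genes(screen) == sorted(planted)
        assert screen["crit_i"].all() and screen["crit_ii"].all()
        assert screen["crit_iii"].all()

    def test_nonunique_enrichment_fails_third_criterion(self):
        circuit, enrichment, model, annotations, planted = self.build(
            annotate_second_cluster=True
        )
        screen = screen_sensor_candidates(circuit, enrichment, model, annotations)
        if not screen.empty:
            assert not screen["crit_iii"].any()
        assert candidate_genes(screen) == []

    def test_circuit_without_dual_input_gates_gives_empty_list(self):
        circuit, enrichment, model, annotations, _ = self.build()
        solo = GateFit("cluster_1", ("fungus",), (0, 1), "ID", ("fungus",), 0)
        circuit = BooleanCircuit(
            circuit.condition_states, {"cluster_1": solo}, circuit.structure, 0.5
        )
        screen = screen_sensor_candidates(circuit, enrichment, model, annotations)
        assert screen.empty
        assert candidate_genes(screen) == []
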