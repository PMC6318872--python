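"""Constrained Bayesian-network inference and Boolean logic-gate fitting.

The regulatory model has one node per co-regulation cluster (its value in a
sample is the mean normalized log2 expression of member genes) plus two
presence nodes carrying the 0/1 design indicators for the fungus and the
bacterium.  Structure is learned over discretized node states by greedy
hill climbing (add/delete/reverse edge moves) maximizing a decomposable
score -- BIC by default, BDeu optionally -- under three
hard constraints: acyclicity, at most 5 parents per node, and presence
nodes may not be the child of any node.  The best network over several
random restarts is kept, then pruned of transitively implied edges (if
A -> B, B -> C and A -> C are all present, A -> C is removed).

The pruned DAG is the scaffold of a Boolean circuit: every node is
binarized per condition (a cluster node is ON when its condition-mean log2
fold change vs the host-alone baseline exceeds a threshold), and for each
cluster node the Boolean function of its parents with the fewest
condition mismatches is selected by exhaustive search (up to 3 effective
inputs; larger parent sets are reduced greedily).  Fitted functions are
labeled with canonical gate names (AND, OR, XOR, ...); an XOR of the two
presence nodes is the signature of a cluster activated when exactly one
microbe is present.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from math import lgamma
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .io import CONDITIONS, IntegrityError, StudyDesign
from .cluster import ClusterModel

PRESENCE_NODES = ("fungus", "bacterium")
DEFAULT_MAX_PARENTS = 5
DEFAULT_UP_THRESHOLD = 0.5  # log2 units; |FC| <= threshold is OFF (dead zone)


# ---------------------------------------------------------------------------
# node table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeTable:
    """Per-sample values (and discrete states) of circuit nodes.

    ``values`` is samples x nodes; presence nodes take only {0, 1}.
    ``states`` is filled by :func:`discretize_nodes`; ``n_states`` records
    each node's cardinality for the BDeu score.
    """

    values: pd.DataFrame
    kinds: Dict[str, str]                 # node -> "presence" | "cluster"
    cluster_of: Dict[str, int]            # cluster node -> cluster index
    states: pd.DataFrame | None = None
    n_states: Dict[str, int] | None = None

    @property
    def nodes(self) -> List[str]:
        return list(self.values.columns)

    def presence(self) -> List[str]:
        return [n for n in self.nodes if self.kinds[n] == "presence"]

    def clusters(self) -> List[str]:
        return [n for n in self.nodes if self.kinds[n] == "cluster"]


def cluster_node_name(cluster: int) -> str:
    return f"cluster_{cluster}"


def build_node_table(
    model: ClusterModel, matrix: pd.DataFrame, design: StudyDesign
) -> NodeTable:
    """One cluster node per cluster (mean member expression per sample) plus
    the two presence nodes from the design."""
    samples = design.sample_ids
    cols: Dict[str, np.ndarray] = {}
    kinds: Dict[str, str] = {}
    cluster_of: Dict[str, int] = {}
    for c in sorted(model.assignment.unique()):
        members = model.members(c)
        if not members:
            warnings.warn(f"cluster {c} is empty; excluded from the network")
            continue
        name = cluster_node_name(c)
        cols[name] = matrix.loc[members, samples].mean(axis=0).to_numpy()
        kinds[name] = "cluster"
        cluster_of[name] = int(c)
    dframe = design.frame.set_index("sample_id")
    for node in PRESENCE_NODES:
        cols[node] = dframe.loc[samples, node].to_numpy(dtype=float)
        kinds[node] = "presence"
    values = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return NodeTable(values, kinds, cluster_of)


def discretize_nodes(table: NodeTable, n_bins: int = 2) -> NodeTable:
    """Quantile-bin cluster nodes into ``n_bins`` states; presence nodes pass
    through as binary.  Quantile binning makes states invariant to any
    monotone transformation of a node's values.  Binary states are the
    default: the downstream logic circuit is Boolean, and with few samples
    a finer discretization splits ON/OFF groups across bins and blurs the
    very dependencies the structure search must detect.  A constant node
    collapses to a single state and is flagged with a warning."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    states = {}
    n_states = {}
    for node in table.nodes:
        v = table.values[node]
        if table.kinds[node] == "presence":
            states[node] = v.astype(int)
            n_states[node] = 2
            continue
        if v.nunique() == 1:
            warnings.warn(f"node {node!r} is constant; single discrete state")
            states[node] = pd.Series(0, index=v.index)
            n_states[node] = 2  # keep the score defined
            continue
        binned = pd.qcut(v, q=n_bins, labels=False, duplicates="drop")
        states[node] = binned.astype(int)
        n_states[node] = int(binned.max()) + 1
    return replace(
        table, states=pd.DataFrame(states, index=table.values.index), n_states=n_states
    )


# ---------------------------------------------------------------------------
# structure learning (BDeu hill climbing)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesNetStructure:
    """A learned directed acyclic structure over circuit nodes."""

    nodes: Tuple[str, ...]
    parents: Dict[str, Tuple[str, ...]]
    score: float
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return [(u, v) for v, ps in sorted(self.parents.items()) for u in ps]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


class _FamilyScorer:
    """Decomposable family scores (BIC or BDeu) over discrete states, cached.

    BIC (default) is the multinomial log-likelihood minus
    0.5 * log(N) * q * (r - 1) free parameters per family; its dimension
    penalty keeps the noise-free binary presence nodes competitive against
    many-state expression proxies at small sample sizes.  BDeu is the
    Bayesian-Dirichlet equivalent uniform marginal likelihood with
    equivalent sample size ``ess``.
    """

    def __init__(
        self,
        states: pd.DataFrame,
        n_states: Mapping[str, int],
        score: str = "bic",
        ess: float = 1.0,
    ):
        if score not in ("bic", "bdeu"):
            raise ValueError("score must be 'bic' or 'bdeu'")
        self.data = {n: states[n].to_numpy(dtype=np.int64) for n in states.columns}
        self.r = dict(n_states)
        self.score_kind = score
        self.ess = float(ess)
        self.n = len(states)
        self._cache: Dict[Tuple[str, Tuple[str, ...]], float] = {}

    def _counts(self, node: str, parents: Tuple[str, ...]) -> np.ndarray:
        r_i = self.r[node]
        q = 1
        cfg = np.zeros(self.n, dtype=np.int64)
        mult = 1
        for p in parents:
            cfg += self.data[p] * mult
            mult *= self.r[p]
            q *= self.r[p]
        cell = cfg * r_i + self.data[node]
        return np.bincount(cell, minlength=q * r_i).reshape(q, r_i)

    def family(self, node: str, parents: Tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        njk = self._counts(node, key[1])
        nj = njk.sum(axis=1)
        q, r_i = njk.shape
        if self.score_kind == "bic":
            ll = 0.0
            for j in range(q):
                if nj[j] == 0:
                    continue
                for k in range(r_i):
                    if njk[j, k]:
                        ll += njk[j, k] * np.log(njk[j, k] / nj[j])
            score = ll - 0.5 * np.log(self.n) * q * (r_i - 1)
        else:
            a_j = self.ess / q
            a_jk = self.ess / (q * r_i)
            score = 0.0
            lg_aj = lgamma(a_j)
            lg_ajk = lgamma(a_jk)
            for j in range(q):
                if nj[j] == 0:
                    continue
                score += lg_aj - lgamma(a_j + nj[j])
                for k in range(r_i):
                    if njk[j, k]:
                        score += lgamma(a_jk + njk[j, k]) - lg_ajk
        self._cache[key] = score
        return score

    def total(self, parents: Mapping[str, Tuple[str, ...]]) -> float:
        return sum(self.family(n, ps) for n, ps in parents.items())


def _creates_cycle(parents: Mapping[str, Tuple[str, ...]], u: str, v: str) -> bool:
    """Would adding u -> v create a directed cycle? (is v an ancestor of u)"""
    stack = [u]
    seen = set()
    while stack:
        x = stack.pop()
        if x == v:
            return True
        for p in parents[x]:
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return False


def learn_structure(
    table: NodeTable,
    max_parents: int = DEFAULT_MAX_PARENTS,
    n_restarts: int = 20,
    seed: int | None = None,
    score: str = "bic",
    ess: float = 1.0,
) -> BayesNetStructure:
    """Greedy hill climbing over add/delete/reverse edge moves, plus a
    presence-replacement move (set a cluster node's parents to the best
    subset of the presence nodes).

    The first two restarts climb from deterministic starting points: the
    empty graph, and a "presence-optimal" graph in which every cluster node
    starts with its best-scoring parent set among subsets of the presence
    nodes (these are exogenous roots, so the choice is per-node exhaustive
    and always acyclic).  Both the presence-replacement move and this start
    matter because an XOR-regulated node is *marginally* independent of
    each of its inputs: no single-edge addition is ever profitable, so a
    pure single-edge climb can neither discover the presence pair nor swap
    a trapped parent set for it -- the pair must be evaluated jointly.
    Presence subsets are few (4 in the 2x2 design), so the extra move stays
    local and cheap.  Remaining restarts
    start from random sparse DAGs.  The score is non-decreasing along each
    accepted-move trajectory, and the best local optimum over restarts is
    returned.  Deterministic for a fixed seed (move ties break in canonical
    node order).
    """
    if table.states is None or table.n_states is None:
        raise ValueError("node table must be discretized first")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if len(table.states) < 2:
        raise IntegrityError("need at least 2 samples to score a network")
    nodes = tuple(table.nodes)
    presence = set(table.presence())
    scorer = _FamilyScorer(table.states, table.n_states, score=score, ess=ess)
    rng = np.random.default_rng(seed)
    presence_subsets = [
        tuple(sorted(s))
        for r in range(min(len(presence), max_parents) + 1)
        for s in itertools.combinations(sorted(presence), r)
    ]

    def climb(parents: Dict[str, Tuple[str, ...]]) -> Tuple[Dict[str, Tuple[str, ...]], float]:
        score = scorer.total(parents)
        while True:
            best_delta = 1e-9
            best_apply = None
            # canonical move enumeration for deterministic tie-breaks
            for v in nodes:
                if v in presence:
                    continue
                pv = parents[v]
                fam_v = scorer.family(v, pv)
                # presence-replacement move: parents(v) <- a presence subset
                for ps in presence_subsets:
                    if ps == tuple(sorted(pv)):
                        continue
                    delta = scorer.family(v, ps) - fam_v
                    if delta > best_delta:
                        best_delta, best_apply = delta, (("set", v, ps),)
                for u in nodes:
                    if u == v:
                        continue
                    if u in pv:
                        # delete u -> v
                        new_pv = tuple(p for p in pv if p != u)
                        delta = scorer.family(v, new_pv) - fam_v
                        if delta > best_delta:
                            best_delta, best_apply = delta, (("set", v, new_pv),)
                        # reverse u -> v  (add v -> u; u must accept parents)
                        if (
                            u not in presence
                            and len(parents[u]) < max_parents
                            and not _creates_cycle(
                                {**parents, v: new_pv}, v, u
                            )
                        ):
                            new_pu = tuple(list(parents[u]) + [v])
                            delta = (
                                scorer.family(v, new_pv)
                                - fam_v
                                + scorer.family(u, new_pu)
                                - scorer.family(u, parents[u])
                            )
                            if delta > best_delta:
                                best_delta = delta
                                best_apply = (("set", v, new_pv), ("set", u, new_pu))
                    else:
                        # add u -> v
                        if len(pv) >= max_parents:
                            continue
                        if _creates_cycle(parents, u, v):
                            continue
                        new_pv = tuple(list(pv) + [u])
                        delta = scorer.family(v, new_pv) - fam_v
                        if delta > best_delta:
                            best_delta, best_apply = delta, (("set", v, new_pv),)
            if best_apply is None:
                return parents, score
            for _, node, new_ps in best_apply:
                parents[node] = new_ps
            score += best_delta

    def random_start() -> Dict[str, Tuple[str, ...]]:
        parents = {n: () for n in nodes}
        order = rng.permutation(len(nodes))
        ranked = [nodes[i] for i in order]
        for i, v in enumerate(ranked):
            if v in presence:
                continue
            for u in ranked[:i]:
                if len(parents[v]) < max_parents and rng.random() < 0.2:
                    parents[v] = tuple(list(parents[v]) + [u])
        return parents

    presence_optimal = {
        n: ()
        if n in presence
        else max(presence_subsets, key=lambda ps: scorer.family(n, ps))
        for n in nodes
    }
    best_parents, best_score = climb({n: () for n in nodes})
    for start in [presence_optimal] + [
        random_start() for _ in range(max(0, n_restarts - 2))
    ]:
        cand_parents, cand_score = climb(dict(start))
        if cand_score > best_score + 1e-9:
            best_parents, best_score = cand_parents, cand_score

    parents = {n: tuple(sorted(ps)) for n, ps in best_parents.items()}
    return BayesNetStructure(
        nodes,
        parents,
        best_score,
        metadata={"n_restarts": n_restarts, "seed": seed, "score": score, "ess": ess},
    )


def transitive_prune(net: BayesNetStructure) -> BayesNetStructure:
    """Remove every edge A -> C for which another directed path A => C
    exists (the transitive reduction of the DAG).  Idempotent; reachability
    is unchanged."""
    g = net.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise IntegrityError("transitive pruning requires an acyclic network")
    reduced = nx.transitive_reduction(g)
    parents = {n: tuple(sorted(reduced.predecessors(n))) for n in net.nodes}
    return BayesNetStructure(
        net.nodes, parents, net.score, metadata={**net.metadata, "pruned": True}
    )


# ---------------------------------------------------------------------------
# Boolean gate fitting
# ---------------------------------------------------------------------------

_GATES_1 = {(0, 1): "ID", (1, 0): "NOT"}
# 2-input tables indexed by x1 + 2*x2
_GATES_2 = {
    (0, 0, 0, 1): "AND",
    (0, 1, 1, 1): "OR",
    (1, 1, 1, 0): "NAND",
    (1, 0, 0, 0): "NOR",
    (0, 1, 1, 0): "XOR",
    (1, 0, 0, 1): "XNOR",
}


@dataclass(frozen=True)
class GateFit:
    """One cluster node's fitted Boolean function of its parents."""

    node: str
    parents: Tuple[str, ...]
    table: Tuple[int, ...]            # 2^len(parents) outputs, input index
                                      # sum_i state(parents[i]) << i
    gate: str
    relevant: Tuple[str, ...]         # parents the function depends on
    mismatches: int

    def evaluate(self, inputs: Mapping[str, int]) -> int:
        idx = sum(int(inputs[p]) << i for i, p in enumerate(self.parents))
        return self.table[idx]


@dataclass(frozen=True)
class BooleanCircuit:
    """The fitted logic circuit: per-condition binary node states plus one
    gate per cluster node that has parents."""

    condition_states: pd.DataFrame    # conditions x nodes, 0/1
    gates: Dict[str, GateFit]
    structure: BayesNetStructure
    up_threshold: float

    def xor_nodes(self) -> List[str]:
        return [n for n, g in self.gates.items() if g.gate == "XOR"]


def condition_states(
    table: NodeTable, design: StudyDesign, up_threshold: float = DEFAULT_UP_THRESHOLD
) -> pd.DataFrame:
    """Binarize nodes per condition.

    A cluster node is ON (1) in a condition iff its condition-mean value
    exceeds its baseline-condition mean by more than ``up_threshold`` log2
    units; everything inside the dead zone or below is OFF.  Presence nodes
    take their design values.
    """
    cond = design.condition
    rows = {}
    for condition in CONDITIONS:
        samples = design.samples_of(condition)
        if not samples:
            raise IntegrityError(f"condition {condition!r} has no samples")
        rows[condition] = table.values.loc[samples].mean(axis=0)
    means = pd.DataFrame(rows).T  # conditions x nodes
    out = pd.DataFrame(0, index=means.index, columns=means.columns, dtype=int)
    for node in table.nodes:
        if table.kinds[node] == "presence":
            # presence is constant within a condition, so the mean is 0/1
            out[node] = means[node].round().astype(int)
        else:
            fc = means[node] - means.loc["baseline", node]
            out[node] = (fc > up_threshold).astype(int)
    return out


def _exhaustive_fit(
    inputs: np.ndarray, target: np.ndarray
) -> Tuple[Tuple[int, ...], int]:
    """Best Boolean function of up to 3 inputs by exhaustive search.

    ``inputs`` is conditions x k (0/1), ``target`` length conditions.
    Ties break toward fewer dependent inputs, then the smaller canonical
    truth-table index.  Returns (table, mismatches).
    """
    k = inputs.shape[1]
    size = 1 << k
    idx = np.zeros(len(target), dtype=int)
    for i in range(k):
        idx |= inputs[:, i].astype(int) << i
    best = None
    for fn in range(1 << size):
        table = tuple((fn >> j) & 1 for j in range(size))
        pred = np.array([table[j] for j in idx])
        mism = int(np.sum(pred != target))
        ndep = len(_relevant_inputs(table, k))
        key = (mism, ndep, fn)
        if best is None or key < best[0]:
            best = (key, table)
    return best[1], best[0][0]


def _relevant_inputs(table: Sequence[int], k: int) -> List[int]:
    """Inputs whose flip changes the output for some input vector."""
    out = []
    for i in range(k):
        for j in range(1 << k):
            if table[j] != table[j ^ (1 << i)]:
                out.append(i)
                break
    return out


def _label_gate(table: Sequence[int], k: int) -> Tuple[str, List[int]]:
    rel = _relevant_inputs(table, k)
    if not rel:
        return ("CONST1" if table[0] else "CONST0"), rel
    # reduce the table to the relevant inputs (others fixed at 0)
    reduced = []
    for bits in itertools.product((0, 1), repeat=len(rel)):
        j = sum(b << rel[i] for i, b in enumerate(bits))
        reduced.append(table[j])
    reduced_t = tuple(reduced)
    if len(rel) == 1:
        return _GATES_1.get(reduced_t, "GENERIC-1"), rel
    if len(rel) == 2:
        return _GATES_2.get(reduced_t, "GENERIC-2"), rel
    return f"GENERIC-{len(rel)}", rel


def fit_gates(
    net: BayesNetStructure,
    table: NodeTable,
    design: StudyDesign,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
) -> BooleanCircuit:
    """Fit a Boolean function to every cluster node with parents.

    For up to 3 parents the search over all 2^(2^k) functions is exhaustive;
    larger parent sets are reduced by greedy selection of at most 3
    informative parents before the exhaustive step.  Gate labels depend only
    on the function's behavior on its relevant inputs, so they are invariant
    to parent-order permutation.
    """
    cstates = condition_states(table, design, up_threshold)
    gates: Dict[str, GateFit] = {}
    for node in table.clusters():
        parents = net.parents.get(node, ())
        if not parents:
            continue
        target = cstates[node].to_numpy()
        if len(parents) <= 3:
            chosen = tuple(parents)
        else:
            chosen = _greedy_select(cstates, parents, target)
        inputs = cstates[list(chosen)].to_numpy()
        reduced_table, mism = _exhaustive_fit(inputs, target)
        full_table = _expand_table(reduced_table, chosen, parents)
        label, rel_idx = _label_gate(full_table, len(parents))
        gates[node] = GateFit(
            node=node,
            parents=tuple(parents),
            table=full_table,
            gate=label,
            relevant=tuple(parents[i] for i in rel_idx),
            mismatches=mism,
        )
    return BooleanCircuit(cstates, gates, net, up_threshold)


def _greedy_select(
    cstates: pd.DataFrame, parents: Sequence[str], target: np.ndarray
) -> Tuple[str, ...]:
    """Greedy literal selection: grow the input set one parent at a time,
    keeping the addition that minimizes the exhaustive-fit mismatch."""
    selected: List[str] = []
    remaining = list(parents)
    best_mism = None
    while remaining and len(selected) < 3:
        scored = []
        for p in remaining:
            cols = selected + [p]
            _, mism = _exhaustive_fit(cstates[cols].to_numpy(), target)
            scored.append((mism, parents.index(p), p))
        scored.sort()
        mism, _, p = scored[0]
        if best_mism is not None and mism >= best_mism:
            break
        selected.append(p)
        remaining.remove(p)
        best_mism = mism
        if mism == 0:
            break
    return tuple(selected)


def _expand_table(
    reduced: Sequence[int], chosen: Sequence[str], parents: Sequence[str]
) -> Tuple[int, ...]:
    """Lift a function of a parent subset to the full parent list."""
    pos = {p: i for i, p in enumerate(parents)}
    k = len(parents)
    out = []
    for j in range(1 << k):
        idx = 0
        for i, p in enumerate(chosen):
            idx |= ((j >> pos[p]) & 1) << i
        out.append(int(reduced[idx]))
    return tuple(out)


# ---------------------------------------------------------------------------
# sensor-candidate screen
# ---------------------------------------------------------------------------

def screen_sensor_candidates(
    circuit: BooleanCircuit,
    enrichment: pd.DataFrame,
    model: ClusterModel,
    annotations: Mapping[str, Set[str]],
    sensor_terms: Set[str] = frozenset({"GO:0048544"}),
) -> pd.DataFrame:
    """Three-criteria screen for candidate sensor genes.

    (i) the gene's cluster is controlled by a gate that depends on both
    presence inputs (e.g. an XOR of fungus and bacterium presence);
    (ii) a sensor-class term is enriched in that cluster;
    (iii) that enrichment is unique to the cluster.

    Returns one row per (gene, cluster, term) with boolean columns
    ``crit_i``, ``crit_ii`` and ``crit_iii``; the final candidates are the
    rows where all three hold.
    """
    from .circuit import cluster_node_name  # self-import for clarity

    dual_clusters = []
    for node, gate in circuit.gates.items():
        if set(PRESENCE_NODES) <= set(gate.relevant):
            cluster = int(node.split("_")[-1])
            dual_clusters.append(cluster)

    rows = []
    for cluster in dual_clusters:
        cl_rows = enrichment[enrichment["cluster"] == cluster]
        for term in sorted(sensor_terms):
            hit = cl_rows[cl_rows["term"] == term]
            enriched = bool(hit["enriched_flag"].any())
            unique = bool(hit["unique_flag"].any())
            if not enriched:
                continue
            for gene in model.members(cluster):
                if term in annotations.get(gene, ()):
                    rows.append((gene, cluster, term, True, enriched, unique))
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster", "term", "crit_i", "crit_ii", "crit_iii"]
    )


def candidate_genes(screen: pd.DataFrame) -> List[str]:
    """Genes passing all three sensor criteria."""
    if screen.empty:
        return []
    ok = screen[screen["crit_i"] & screen["crit_ii"] & screen["crit_iii"]]
    return sorted(ok["gene_id"].unique())


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def structure_to_json(net: BayesNetStructure) -> dict:
    return {
        "nodes": list(net.nodes),
        "edges": [list(e) for e in net.edges],
        "score": net.score,
        "metadata": {k: v for k, v in net.metadata.items()},
    }


def circuit_to_dot(
    circuit: BooleanCircuit, output_node: str | None = None
) -> str:
    """Graphviz DOT rendering of the circuit.

    Presence inputs are ellipses, cluster nodes boxes labeled with their
    fitted gate.  Edges whose parent and child condition states associate
    negatively are drawn with a blunt (tee) arrowhead to mark inhibition.
    """
    cs = circuit.condition_states
    lines = ["digraph circuit {", "  rankdir=LR;"]
    for node in cs.columns:
        if node in PRESENCE_NODES:
            lines.append(f'  "{node}" [shape=ellipse];')
        else:
            gate = circuit.gates.get(node)
            label = f"{node}\\n[{gate.gate}]" if gate else node
            shape = "box"
            extra = ' style="bold"' if node == output_node else ""
            lines.append(f'  "{node}" [shape={shape} label="{label}"{extra}];')
    for node, gate in circuit.gates.items():
        for parent in gate.parents:
            x = cs[parent].to_numpy(dtype=float)
            y = cs[node].to_numpy(dtype=float)
            sign = 0.0
            if np.std(x) > 0 and np.std(y) > 0:
                sign = float(np.corrcoef(x, y)[0, 1])
            head = "tee" if sign < 0 else "normal"
            lines.append(f'  "{parent}" -> "{node}" [arrowhead={head}];')
    lines.append("}")
    return "\n".join(lines)


def gates_to_frame(circuit: BooleanCircuit) -> pd.DataFrame:
    rows = [
        (
            g.node,
            ",".join(g.parents),
            g.gate,
            ",".join(g.relevant),
            "".join(map(str, g.table)),
            g.mismatches,
        )
        for g in circuit.gates.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["node", "parents", "gate", "relevant", "truth_table", "mismatches"],
    )
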