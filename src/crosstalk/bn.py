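"""Discrete Bayesian-network structure learning over binary abundance states.

The learner follows a restrict-maximize scheme: a constraint-based phase
(Hiton parents-and-children with G-squared independence tests) proposes an
undirected skeleton of candidate adjacencies, and a greedy hill climb over
add/delete/reverse moves maximizes the BIC score within that skeleton,

    BIC(G) = log P(D | Theta_hat, G) - (1/2) Dim(G) log N,

where Dim(G) counts one free parameter per parent configuration of each
binary node (sum over nodes of 2^|Pa|).  The score is decomposable, so move
deltas touch only the child whose parent set changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2


# ---------------------------------------------------------------------------
# graphs


@dataclass
class Dag:
    """Directed acyclic graph over cell types. Edges are ordered pairs."""

    nodes: tuple[str, ...]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = set(self.edges)
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} (self edges are not allowed)")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) uses unknown nodes")
        if not self.is_acyclic():
            raise ValueError("graph contains a directed cycle")

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def copy(self) -> "Dag":
        return Dag(self.nodes, set(self.edges))

    def to_edge_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("source\ttarget\n")
            for u, v in sorted(self.edges):
                fh.write(f"{u}\t{v}\n")

    def to_dot(self, node_colors: dict[str, str] | None = None) -> str:
        lines = ["digraph celltypes {"]
        for n in self.nodes:
            color = (node_colors or {}).get(n)
            attr = f' [style=filled, fillcolor="{color}"]' if color else ""
            lines.append(f'  "{n}"{attr};')
        for u, v in sorted(self.edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Skeleton:
    """Per-node candidate parents-and-children sets (undirected adjacency)."""

    pc: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for a, nbrs in self.pc.items():
            for b in nbrs:
                if a not in self.pc.get(b, frozenset()):
                    raise ValueError(f"skeleton not symmetric: {a!r}-{b!r}")

    @property
    def pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, nbrs in self.pc.items() for b in nbrs}

    @classmethod
    def complete(cls, nodes: Iterable[str]) -> "Skeleton":
        nodes = list(nodes)
        return cls({n: frozenset(set(nodes) - {n}) for n in nodes})


# ---------------------------------------------------------------------------
# scoring


def _check_data(data: pd.DataFrame, nodes: Iterable[str]) -> None:
    missing = [n for n in nodes if n not in data.columns]
    if missing:
        raise ValueError(f"nodes missing from data: {missing}")
    if len(data) < 1:
        raise ValueError("need at least one sample")


def _family_loglik(child: np.ndarray, parents: np.ndarray | None) -> float:
    """Maximized local log-likelihood sum_config sum_state c*log(c/rowtotal)."""
    if parents is None or parents.shape[1] == 0:
        config = np.zeros(child.shape[0], dtype=np.int64)
        n_config = 1
    else:
        weights = 1 << np.arange(parents.shape[1], dtype=np.int64)
        config = parents.astype(np.int64) @ weights
        n_config = 1 << parents.shape[1]
    idx = config * 2 + child.astype(np.int64)
    counts = np.bincount(idx, minlength=n_config * 2).reshape(n_config, 2)
    rowtot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / rowtot)
    return float(np.nansum(terms))


def loglik(data: pd.DataFrame, dag: Dag) -> float:
    """Maximized log P(D | Theta_hat, G), decomposed over node families."""
    _check_data(data, dag.nodes)
    total = 0.0
    for node in dag.nodes:
        pa = dag.parents(node)
        pmat = data[list(pa)].to_numpy() if pa else None
        total += _family_loglik(data[node].to_numpy(), pmat)
    return total


def dim(dag: Dag) -> int:
    """Number of free parameters: one per parent configuration per binary node."""
    return sum(1 << len(dag.parents(n)) for n in dag.nodes)


def bic_score(data: pd.DataFrame, dag: Dag) -> float:
    """BIC = loglik - 0.5 * Dim(G) * log N."""
    n = len(data)
    return loglik(data, dag) - 0.5 * dim(dag) * np.log(n)


# ---------------------------------------------------------------------------
# G-squared independence tests


def _g2_from_counts(counts: np.ndarray) -> tuple[float, bool]:
    """G2 statistic of a 2x2 table; second value False if any expected < 1
    (the test is then declared unresolved and skipped)."""
    n = counts.sum()
    if n == 0:
        return 0.0, False
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    if (expected < 1).any():
        return 0.0, False
    mask = counts > 0
    g2 = 2.0 * float((counts[mask] * np.log(counts[mask] / expected[mask])).sum())
    return g2, True


def g2_test(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> tuple[float, float] | None:
    """G-squared (conditional) independence test for binary variables.

    Returns ``(statistic, p_value)`` with df = 2^|Z| (1 when Z is empty), or
    ``None`` when any stratum has an expected count below 1, in which case
    the caller must treat dependence as unresolved.
    """
    if z is None or z.shape[1] == 0:
        counts = np.bincount(2 * x + y, minlength=4).reshape(2, 2)
        g2, ok = _g2_from_counts(counts)
        if not ok:
            return None
        return g2, float(chi2.sf(g2, df=1))
    k = z.shape[1]
    weights = 1 << np.arange(k, dtype=np.int64)
    config = z.astype(np.int64) @ weights
    total = 0.0
    for c in range(1 << k):
        sel = config == c
        if not sel.any():
            continue
        counts = np.bincount(2 * x[sel] + y[sel], minlength=4).reshape(2, 2)
        g2, ok = _g2_from_counts(counts)
        if not ok:
            return None
        total += g2
    return total, float(chi2.sf(total, df=1 << k))


# ---------------------------------------------------------------------------
# restrict phase: Hiton parents-and-children


def hiton_pc(
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_condition_size: int = 3,
) -> Skeleton:
    """Constraint-based candidate-adjacency discovery around each node.

    For each target, the other variables are ranked by marginal G-squared
    association and admitted greedily when marginally dependent (p < alpha);
    after each admission, any admitted variable that is conditionally
    independent of the target given some subset (size <= max_condition_size)
    of the other admitted variables is removed.  Unresolvable tests (sparse
    strata) never count as evidence of independence.  The final skeleton
    keeps a-b only if each node is in the other's set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    nodes = list(data.columns)
    arr = {n: data[n].to_numpy().astype(np.int8) for n in nodes}

    def independent(t: str, x: str, members: list[str]) -> bool:
        others = [m for m in members if m != x]
        for size in range(1, min(max_condition_size, len(others)) + 1):
            for z in combinations(others, size):
                zmat = np.column_stack([arr[m] for m in z])
                res = g2_test(arr[t], arr[x], zmat)
                if res is not None and res[1] >= alpha:
                    return True
        return False

    pc: dict[str, set[str]] = {}
    for t in nodes:
        ranked = []
        for v in nodes:
            if v == t:
                continue
            res = g2_test(arr[t], arr[v])
            if res is not None and res[1] < alpha:
                ranked.append((v, res[0]))
        ranked.sort(key=lambda item: (-item[1], item[0]))
        members: list[str] = []
        for v, _ in ranked:
            members.append(v)
            members = [x for x in members if not independent(t, x, members)]
        pc[t] = set(members)

    sym = {
        n: frozenset(v for v in pc[n] if n in pc.get(v, set())) for n in nodes
    }
    return Skeleton(sym)


# ---------------------------------------------------------------------------
# maximize phase: BIC hill climbing


def hill_climb(
    data: pd.DataFrame,
    skeleton: Skeleton,
    max_iter: int = 100,
    seed: int = 0,
    debug: bool = False,
    n_restarts: int = 0,
) -> Dag:
    """Greedy best-first BIC search over add/delete/reverse moves.

    Starts from the empty graph; edge additions are restricted to skeleton
    pairs; every accepted move must keep the graph acyclic and strictly
    increase BIC.  Ties between equal-delta moves (typically the two
    orientations of a newly added edge, whose scores are equal by Markov
    equivalence) are broken uniformly at random with the given seed: a
    deterministic tie-break would stamp an arbitrary, name-dependent
    orientation onto every such edge, and downstream bootstrap direction
    counts would reflect node names instead of data.  Runs are reproducible
    given the seed.

    ``n_restarts`` adds that many extra climbs from random acyclic starting
    graphs within the skeleton, keeping the highest-scoring endpoint.
    Plain single-start climbing cannot enter a collider basin in which every
    single-edge addition scores worse than the empty graph; random starts
    can.  The default is 0 (the plain protocol) — the bootstrap supplies
    robustness in the pipeline — but restarts are the way to certify the
    search engine against exhaustive enumeration.
    """
    nodes = list(data.columns)
    _check_data(data, nodes)
    n = len(data)
    logn = np.log(n)
    arr = {v: data[v].to_numpy().astype(np.int8) for v in nodes}
    allowed = skeleton.pairs
    rng = np.random.default_rng(seed)

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family_score(child: str, parents: tuple[str, ...]) -> float:
        key = (child, parents)
        if key not in cache:
            pmat = np.column_stack([arr[p] for p in parents]) if parents else None
            ll = _family_loglik(arr[child], pmat)
            cache[key] = ll - 0.5 * (1 << len(parents)) * logn
        return cache[key]

    def random_start() -> set[tuple[str, str]]:
        start: set[tuple[str, str]] = set()
        g0 = nx.DiGraph()
        g0.add_nodes_from(nodes)
        pairs = sorted(tuple(sorted(p)) for p in allowed)
        for a, b in pairs:
            if rng.random() < 0.5:
                continue
            u, v = (a, b) if rng.random() < 0.5 else (b, a)
            if not nx.has_path(g0, v, u):
                start.add((u, v))
                g0.add_edge(u, v)
        return start

    def climb(start: set[tuple[str, str]]):
        parents: dict[str, set[str]] = {v: set() for v in nodes}
        edges: set[tuple[str, str]] = set()
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v in sorted(start):
            edges.add((u, v))
            parents[v].add(u)
            g.add_edge(u, v)

        def creates_cycle_add(u: str, v: str) -> bool:
            return nx.has_path(g, v, u)

        def creates_cycle_reverse(u: str, v: str) -> bool:
            g.remove_edge(u, v)
            bad = nx.has_path(g, u, v)
            g.add_edge(u, v)
            return bad

        def pset(v: str) -> tuple[str, ...]:
            return tuple(sorted(parents[v]))

        current_bic = sum(family_score(v, pset(v)) for v in nodes)
        best_so_far = current_bic

        for _ in range(max_iter):
            moves: list[tuple[float, str, str, str]] = []  # (delta, u, v, kind)
            for u in nodes:
                for v in nodes:
                    if u == v:
                        continue
                    if (u, v) in edges:
                        # delete
                        d = family_score(v, tuple(sorted(parents[v] - {u}))) - family_score(
                            v, pset(v)
                        )
                        moves.append((d, u, v, "delete"))
                        # reverse
                        if not creates_cycle_reverse(u, v):
                            d_rev = (
                                family_score(v, tuple(sorted(parents[v] - {u})))
                                - family_score(v, pset(v))
                                + family_score(u, tuple(sorted(parents[u] | {v})))
                                - family_score(u, pset(u))
                            )
                            moves.append((d_rev, u, v, "reverse"))
                    elif (
                        frozenset((u, v)) in allowed
                        and (v, u) not in edges
                        and not creates_cycle_add(u, v)
                    ):
                        d = family_score(v, tuple(sorted(parents[v] | {u}))) - family_score(
                            v, pset(v)
                        )
                        moves.append((d, u, v, "add"))
            if not moves:
                break
            best_delta = max(m[0] for m in moves)
            if best_delta <= 1e-9:
                break
            ties = sorted(
                (m for m in moves if m[0] >= best_delta - 1e-9),
                key=lambda m: (m[1], m[2], m[3]),
            )
            delta, u, v, kind = ties[int(rng.integers(len(ties)))]
            if kind == "add":
                edges.add((u, v))
                parents[v].add(u)
                g.add_edge(u, v)
            elif kind == "delete":
                edges.discard((u, v))
                parents[v].discard(u)
                g.remove_edge(u, v)
            else:  # reverse
                edges.discard((u, v))
                parents[v].discard(u)
                g.remove_edge(u, v)
                edges.add((v, u))
                parents[u].add(v)
                g.add_edge(v, u)
            current_bic += delta
            if debug:
                full = bic_score(data, Dag(tuple(nodes), set(edges)))
                assert abs(full - current_bic) < 1e-8, "incremental BIC drifted"
            assert current_bic > best_so_far, "accepted move did not increase BIC"
            best_so_far = current_bic

        return edges, current_bic

    best_edges, best_score = climb(set())
    for _ in range(n_restarts):
        cand_edges, cand_score = climb(random_start())
        if cand_score > best_score + 1e-9:
            best_edges, best_score = cand_edges, cand_score

    return Dag(tuple(nodes), best_edges)


def learn_network(
    data: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    max_condition_size: int = 3,
    max_iter: int = 100,
) -> Dag:
    """Restrict (Hiton-PC) then maximize (BIC hill climbing)."""
    skeleton = hiton_pc(data, alpha=alpha, max_condition_size=max_condition_size)
    return hill_climb(data, skeleton, max_iter=max_iter, seed=seed)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class BnModel:
    """A DAG plus per-node conditional probability tables.

    ``cpts[node]`` has shape (2^|Pa|, 2); row ``c`` is the distribution of the
    node given the parent configuration whose bits (in ``parent_order[node]``
    order, least-significant first) encode ``c``.
    """

    dag: Dag
    cpts: dict[str, np.ndarray]
    parent_order: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for node, table in self.cpts.items():
            expected = 1 << len(self.parent_order[node])
            if table.shape != (expected, 2):
                raise ValueError(f"CPT shape mismatch for {node!r}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Ancestral sampling of n joint binary states."""
        # lexicographic topological order: a plain topological sort of a
        # graph built from a set is hash-order dependent, which would make
        # the rng consumption order (and hence the draws) vary per process
        order = list(nx.lexicographical_topological_sort(self.dag.to_networkx()))
        out = pd.DataFrame(0, index=range(n), columns=list(self.dag.nodes), dtype=np.int8)
        for node in order:
            pa = self.parent_order[node]
            if pa:
                weights = 1 << np.arange(len(pa), dtype=np.int64)
                config = out[list(pa)].to_numpy().astype(np.int64) @ weights
            else:
                config = np.zeros(n, dtype=np.int64)
            p1 = self.cpts[node][config, 1]
            out[node] = (rng.random(n) < p1).astype(np.int8)
        return out

    def joint(self) -> pd.DataFrame:
        """Exact joint over all 2^Q states (tiny networks only)."""
        q = len(self.dag.nodes)
        states = np.array(
            [[(s >> i) & 1 for i in range(q)] for s in range(1 << q)], dtype=np.int8
        )
        frame = pd.DataFrame(states, columns=list(self.dag.nodes))
        prob = np.ones(len(frame))
        for node in self.dag.nodes:
            pa = self.parent_order[node]
            if pa:
                weights = 1 << np.arange(len(pa), dtype=np.int64)
                config = frame[list(pa)].to_numpy().astype(np.int64) @ weights
            else:
                config = np.zeros(len(frame), dtype=np.int64)
            prob *= self.cpts[node][config, frame[node].to_numpy()]
        frame["prob"] = prob
        return frame


def fit_cpts(data: pd.DataFrame, dag: Dag, pseudocount: float = 1.0) -> BnModel:
    """Maximum-likelihood (pseudocount=0) or Laplace-smoothed CPT estimates."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    _check_data(data, dag.nodes)
    cpts, orders = {}, {}
    for node in dag.nodes:
        pa = dag.parents(node)
        orders[node] = pa
        k = len(pa)
        if pa:
            weights = 1 << np.arange(k, dtype=np.int64)
            config = data[list(pa)].to_numpy().astype(np.int64) @ weights
        else:
            config = np.zeros(len(data), dtype=np.int64)
        idx = config * 2 + data[node].to_numpy().astype(np.int64)
        counts = np.bincount(idx, minlength=(1 << k) * 2).reshape(1 << k, 2).astype(float)
        counts += pseudocount
        rowtot = counts.sum(axis=1, keepdims=True)
        if (rowtot == 0).any():
            # unseen configuration with zero pseudocount: fall back to uniform
            counts[rowtot[:, 0] == 0] = 0.5
            rowtot = counts.sum(axis=1, keepdims=True)
        cpts[node] = counts / rowtot
    return BnModel(dag=dag, cpts=cpts, parent_order=orders)


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle for tiny networks)


def all_dags(nodes: Iterable[str]) -> list[Dag]:
    """Every DAG over the given nodes (feasible only for <= 4 nodes;
    3 nodes give the classic 25 DAGs). Used as an exhaustive-search oracle."""
    nodes = list(nodes)
    pairs = list(combinations(nodes, 2))
    dags = []

    def extend(i: int, edges: set[tuple[str, str]]):
        if i == len(pairs):
            try:
                dags.append(Dag(tuple(nodes), set(edges)))
            except ValueError:
                pass
            return
        a, b = pairs[i]
        for choice in (None, (a, b), (b, a)):
            nxt = set(edges)
            if choice:
                nxt.add(choice)
            extend(i + 1, nxt)

    extend(0, set())
    return dags
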