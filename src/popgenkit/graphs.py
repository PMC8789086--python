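"""Admixture graphs: forward f-statistic predictions and fitting.

A graph is a rooted DAG. Ordinary nodes have one parent; admixture nodes
have exactly two parents whose in-edge weights sum to 1. Every edge
carries a non-negative drift length (in f2 units). Expected
f-statistics follow the standard path-overlap rules: a lineage sampled
in leaf X traverses edge e with probability ``p_X(e)`` (products of
admixture weights summed over paths), and

    E[f4(A,B;C,D)] = sum_e len(e) * (p_A(e)-p_B(e)) * (p_C(e)-p_D(e))

with f2 and f3 as the matching special cases. Fitting minimizes the
worst absolute residual Z against observed statistics (least-squares
warm start, then a direct minimax polish), mirroring model selection by
lowest maximum |Z|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .fstats import FStatResult


@dataclass
class FitSummary:
    worst_abs_z: float = float("nan")
    residuals: pd.DataFrame | None = None
    n_outliers: int = 0
    converged: bool = False
    non_identifiable: bool = False

    @property
    def good(self) -> bool:
        return self.converged and self.worst_abs_z < 3.0


class AdmixtureGraph:
    """Rooted DAG with drift lengths and admixture weights.

    Build with :meth:`add_edge` / :meth:`add_admixture`; leaves are nodes
    with no children and map 1:1 to population labels (node name ==
    population by default).
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()
        self.fit: FitSummary = FitSummary()

    # -- construction ----------------------------------------------------
    def add_edge(self, parent: str, child: str, length: float = 0.0) -> None:
        if length < 0:
            raise ValueError("drift length must be >= 0")
        self.g.add_edge(parent, child, length=float(length), weight=1.0)

    def add_admixture(
        self,
        parent1: str,
        parent2: str,
        child: str,
        w1: float = 0.5,
        length1: float = 0.0,
        length2: float = 0.0,
    ) -> None:
        if not 0.0 < w1 < 1.0:
            raise ValueError("admixture weight must be in (0,1)")
        self.g.add_edge(parent1, child, length=float(length1), weight=float(w1))
        self.g.add_edge(parent2, child, length=float(length2), weight=float(1 - w1))

    def copy(self) -> "AdmixtureGraph":
        out = AdmixtureGraph()
        out.g = self.g.copy()
        return out

    # -- structure -------------------------------------------------------
    @property
    def root(self) -> str:
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        return roots[0]

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.g if self.g.out_degree(n) == 0)

    def admixture_nodes(self) -> list[str]:
        return sorted(n for n in self.g if self.g.in_degree(n) == 2)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError("admixture graph contains a cycle")
        _ = self.root
        for n in self.g:
            deg = self.g.in_degree(n)
            if deg not in (0, 1, 2):
                raise ValueError(f"node {n} has in-degree {deg}")
            if deg == 2:
                w = sum(self.g.edges[p, n]["weight"] for p in self.g.predecessors(n))
                if abs(w - 1.0) > 1e-9:
                    raise ValueError(f"admixture weights at {n} sum to {w}")

    # -- expectations ----------------------------------------------------
    def edge_usage(self, leaf: str) -> dict[tuple[str, str], float]:
        """Probability a lineage from ``leaf`` traverses each edge."""
        if leaf not in self.g or self.g.out_degree(leaf) != 0:
            raise KeyError(f"{leaf!r} is not a leaf")
        mass = {leaf: 1.0}
        usage: dict[tuple[str, str], float] = {}
        for node in nx.topological_sort(self.g.reverse()):
            m = mass.get(node, 0.0)
            if m == 0.0:
                continue
            for parent in self.g.predecessors(node):
                w = self.g.edges[parent, node]["weight"]
                usage[(parent, node)] = usage.get((parent, node), 0.0) + m * w
                mass[parent] = mass.get(parent, 0.0) + m * w
        return usage

    def to_dot(self) -> str:
        lines = ["digraph admixture_graph {"]
        for u, v, d in self.g.edges(data=True):
            label = f"{d['length']:.4g}"
            if self.g.in_degree(v) == 2:
                label += f" ({d['weight']:.2f})"
            lines.append(f'  "{u}" -> "{v}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def expected_f_stats(
    graph: AdmixtureGraph, requests: list[tuple[str, tuple[str, ...]]]
) -> dict[tuple[str, tuple[str, ...]], float]:
    """Predicted f2/f3/f4 values for (kind, pops) requests."""
    graph.validate()
    usages = {leaf: graph.edge_usage(leaf) for leaf in graph.leaves}
    edges = list(graph.g.edges)
    lengths = np.array([graph.g.edges[e]["length"] for e in edges])

    def uvec(leaf: str) -> np.ndarray:
        u = usages[leaf]
        return np.array([u.get(e, 0.0) for e in edges])

    out = {}
    for kind, pops in requests:
        if kind == "f2":
            a, b = (uvec(p) for p in pops)
            val = np.sum(lengths * (a - b) ** 2)
        elif kind == "f3":
            c, a, b = (uvec(p) for p in pops)
            val = np.sum(lengths * (c - a) * (c - b))
        elif kind == "f4":
            a, b, c, d = (uvec(p) for p in pops)
            val = np.sum(lengths * (a - b) * (c - d))
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
        out[(kind, tuple(pops))] = float(val)
    return out


# --------------------------------------------------------------------------
# fitting


def _free_parameters(graph: AdmixtureGraph):
    """Edges with free lengths plus admixture nodes with free weights."""
    edges = list(graph.g.edges)
    adm = graph.admixture_nodes()
    return edges, adm


def _apply_parameters(
    graph: AdmixtureGraph, edges, adm, lengths: np.ndarray, weights: np.ndarray
) -> None:
    for e, ln in zip(edges, lengths):
        graph.g.edges[e]["length"] = float(ln)
    for node, w in zip(adm, weights):
        parents = sorted(graph.g.predecessors(node))
        graph.g.edges[parents[0], node]["weight"] = float(w)
        graph.g.edges[parents[1], node]["weight"] = float(1.0 - w)


def fit_admixture_graph(
    topology: AdmixtureGraph,
    observed: list[FStatResult],
    min_snps: int = 0,
    seed: int = 0,
) -> AdmixtureGraph:
    """Fit drift lengths and admixture weights to observed f-statistics.

    Least-squares warm start on Z residuals, then a Nelder-Mead polish of
    the maximum absolute residual Z (ties broken by the sum of squared
    residuals folded in at small weight). A rank-deficient prediction
    Jacobian at the optimum flags the topology as non-identifiable.
    """
    graph = topology.copy()
    graph.validate()
    usable = [r for r in observed if r.n_snps >= min_snps]
    if not usable:
        raise ValueError("no observed statistics pass the min_snps filter")
    leaves = set(graph.leaves)
    for r in usable:
        missing = [p for p in r.pops if p not in leaves]
        if missing:
            raise ValueError(f"observed statistic uses non-leaf populations {missing}")

    edges, adm = _free_parameters(graph)
    n_e, n_a = len(edges), len(adm)
    obs = np.array([r.estimate for r in usable])
    ses = np.array([max(r.se, 1e-9) for r in usable])
    requests = [(r.kind, r.pops) for r in usable]

    def predict(x: np.ndarray) -> np.ndarray:
        lengths = x[:n_e] ** 2  # squared transform keeps lengths >= 0
        weights = 1.0 / (1.0 + np.exp(-x[n_e:])) if n_a else np.empty(0)
        _apply_parameters(graph, edges, adm, lengths, weights)
        pred = expected_f_stats(graph, requests)
        return np.array([pred[(k, p)] for k, p in requests])

    def residuals(x: np.ndarray) -> np.ndarray:
        return (predict(x) - obs) / ses

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(3):
        x0 = np.concatenate(
            [np.sqrt(rng.uniform(0.001, 0.05, n_e)), rng.normal(0, 0.5, n_a)]
        )
        method = "lm" if len(obs) >= n_e + n_a else "trf"
        ls = optimize.least_squares(residuals, x0, method=method, max_nfev=4000)
        if best is None or ls.cost < best.cost:
            best = ls

    def minimax_obj(x: np.ndarray) -> float:
        r = residuals(x)
        return np.max(np.abs(r)) + 1e-4 * np.sum(r**2)

    polish = optimize.minimize(
        minimax_obj,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 2000 * (n_e + n_a + 1), "xatol": 1e-8, "fatol": 1e-10},
    )
    x_opt = polish.x if polish.fun <= minimax_obj(best.x) else best.x
    r = residuals(x_opt)

    # identifiability: numerical Jacobian rank at the optimum
    eps = 1e-6
    jac = np.empty((len(r), len(x_opt)))
    f0 = predict(x_opt)
    for j in range(len(x_opt)):
        xp = x_opt.copy()
        xp[j] += eps
        jac[:, j] = (predict(xp) - f0) / eps
    rank = np.linalg.matrix_rank(jac, tol=1e-8)
    non_ident = rank < len(x_opt)

    predict(x_opt)  # leave graph at the optimum
    table = pd.DataFrame(
        {
            "kind": [q.kind for q in usable],
            "pops": [";".join(q.pops) for q in usable],
            "observed": obs,
            "predicted": f0,
            "se": ses,
            "z": r,
        }
    )
    graph.fit = FitSummary(
        worst_abs_z=float(np.max(np.abs(r))),
        residuals=table,
        n_outliers=int(np.sum(np.abs(r) > 3.0)),
        converged=True,
        non_identifiable=bool(non_ident),
    )
    return graph


# --------------------------------------------------------------------------
# placement search


def _attach_one_way(
    scaffold: AdmixtureGraph, edge: tuple[str, str], leaf: str
) -> AdmixtureGraph:
    g = scaffold.copy()
    u, v = edge
    mid = f"_n_{u}_{v}"
    d = g.g.edges[u, v]
    g.g.remove_edge(u, v)
    g.g.add_edge(u, mid, length=d["length"] / 2.0, weight=d["weight"])
    g.g.add_edge(mid, v, length=d["length"] / 2.0, weight=1.0)
    g.g.add_edge(mid, leaf, length=0.01, weight=1.0)
    return g


def _attach_two_way(
    scaffold: AdmixtureGraph,
    edge1: tuple[str, str],
    edge2: tuple[str, str],
    leaf: str,
) -> AdmixtureGraph:
    g = scaffold.copy()
    mids = []
    for u, v in (edge1, edge2):
        mid = f"_n_{u}_{v}"
        d = g.g.edges[u, v]
        g.g.remove_edge(u, v)
        g.g.add_edge(u, mid, length=d["length"] / 2.0, weight=d["weight"])
        g.g.add_edge(mid, v, length=d["length"] / 2.0, weight=1.0)
        mids.append(mid)
    adm = f"_adm_{leaf}"
    g.g.add_edge(mids[0], adm, length=0.0, weight=0.5)
    g.g.add_edge(mids[1], adm, length=0.0, weight=0.5)
    g.g.add_edge(adm, leaf, length=0.01, weight=1.0)
    if not nx.is_directed_acyclic_graph(g.g):
        raise ValueError("two-way attachment creates a cycle")
    return g


@dataclass
class Placement:
    kind: str  # "one_way" | "two_way"
    attach: tuple
    graph: AdmixtureGraph

    @property
    def worst_abs_z(self) -> float:
        return self.graph.fit.worst_abs_z


def placement_search(
    scaffold: AdmixtureGraph,
    test_population: str,
    observed: list[FStatResult],
    min_snps: int = 0,
    seed: int = 0,
) -> list[Placement]:
    """Try the test leaf on every scaffold edge (one-way) and edge pair
    (two-way); rank good one-way fits first, then by worst |Z|, then by
    outlier count (parsimony preference for single-origin models)."""
    scaffold.validate()
    edges = list(scaffold.g.edges)
    results: list[Placement] = []
    for e in edges:
        try:
            g = _attach_one_way(scaffold, e, test_population)
            fitted = fit_admixture_graph(g, observed, min_snps, seed)
            results.append(Placement("one_way", (e,), fitted))
        except ValueError:
            continue
    for e1, e2 in itertools.combinations(edges, 2):
        try:
            g = _attach_two_way(scaffold, e1, e2, test_population)
            fitted = fit_admixture_graph(g, observed, min_snps, seed)
            results.append(Placement("two_way", (e1, e2), fitted))
        except ValueError:
            continue

    def rank_key(p: Placement):
        good_one_way = p.kind == "one_way" and p.graph.fit.good
        return (
            0 if good_one_way else 1,
            p.worst_abs_z,
            p.graph.fit.n_outliers,
        )

    results.sort(key=rank_key)
    return results
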