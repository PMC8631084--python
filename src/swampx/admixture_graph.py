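"""Admixture graphs: prediction, fitting, greedy search, and X refitting.

An admixture graph is a rooted DAG whose edges carry drift lengths in f2
units (variance of allele-frequency change along the edge) and whose
admixture nodes have two parents mixed with weight α toward the first.
Writing a leaf's allele-frequency deviation from the root as the α-weighted
sum of independent per-edge drift increments gives the leaf covariance

    V_ij = Σ_e γ_e(i) · γ_e(j) · length(e)

where γ_e(i) is the total mixture weight of root-to-leaf paths through edge
e.  Every f-statistic is then a linear functional of V:

    f2(i, j)       = V_ii + V_jj − 2 V_ij
    f3(a, b; c)    = V_cc − V_ca − V_cb + V_ab
    f4(a, b; c, d) = V_ac − V_ad − V_bc + V_bd

Fitting minimizes the variance-weighted squared residuals of a basis of
observed statistics (all pairwise f2 plus, when an outgroup is named, all
outgroup f3) over bounded drift lengths and mixing weights, with seeded
multi-start least squares.  Model search adds one admixture edge at a time,
each round choosing the candidate that best reduces the largest |Z| among
all predicted-vs-observed f4 configurations, mirroring how reticulations
are added to resolve the strongest treeness violations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fstats import FStatConfig, FStatResult, f_statistic
from .genotype_data import AlleleCountTable, BlockPartition

MAX_DRIFT = 2.0       # generous bound; f2 between fixed populations is <= 2
SE_FLOOR = 1e-9


class GraphError(ValueError):
    pass


# ---------------------------------------------------------------------------
# the graph container
# ---------------------------------------------------------------------------

class AdmixtureGraph:
    """Rooted DAG with drift-length edges and two-parent admixture nodes."""

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction ------------------------------------------------------
    def add_edge(self, parent: str, child: str, length: float = 0.0) -> None:
        if length < 0:
            raise GraphError(f"negative drift length on {parent}->{child}")
        self._g.add_edge(parent, child, length=float(length), admix=False)

    def add_admixture(self, child: str, parent1: str, parent2: str,
                      alpha: float = 0.5) -> None:
        """Make ``child`` an admixture node: α toward ``parent1``."""
        if not 0 <= alpha <= 1:
            raise GraphError("alpha must lie in [0, 1]")
        self._g.add_edge(parent1, child, length=0.0, admix=True)
        self._g.add_edge(parent2, child, length=0.0, admix=True)
        self._g.nodes[child]["parents"] = (parent1, parent2)
        self._g.nodes[child]["alpha"] = float(alpha)

    def set_population(self, leaf: str, label: str) -> None:
        self._g.nodes[leaf]["population"] = label

    def copy(self) -> "AdmixtureGraph":
        out = AdmixtureGraph()
        out._g = self._g.copy()
        return out

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> str:
        roots = [n for n in self._g if self._g.in_degree(n) == 0]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {roots}")
        return roots[0]

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def leaves(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    def populations(self) -> dict[str, str]:
        """population label -> leaf node."""
        out = {}
        for leaf in self.leaves():
            label = self._g.nodes[leaf].get("population", leaf)
            if label in out:
                raise GraphError(f"population {label!r} maps to two leaves")
            out[label] = leaf
        return out

    def admixture_nodes(self) -> list[str]:
        return sorted(n for n in self._g if self._g.in_degree(n) == 2)

    def alpha(self, node: str) -> float:
        return self._g.nodes[node]["alpha"]

    def tree_edges(self) -> list[tuple[str, str]]:
        """Drift-carrying edges (admixture edges are fixed at length 0)."""
        return sorted((u, v) for u, v, d in self._g.edges(data=True)
                      if not d["admix"])

    def edge_length(self, u: str, v: str) -> float:
        return self._g.edges[u, v]["length"]

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._g):
            raise GraphError("admixture graph contains a cycle")
        _ = self.root
        for n in self._g:
            deg = self._g.in_degree(n)
            if deg > 2:
                raise GraphError(f"node {n} has {deg} parents")
            if deg == 2 and "alpha" not in self._g.nodes[n]:
                raise GraphError(f"two-parent node {n} lacks a mixing weight")
        _ = self.populations()

    # -- parameter vector ---------------------------------------------------
    def parameter_names(self) -> list[str]:
        names = [f"len:{u}->{v}" for u, v in self.tree_edges()]
        names += [f"alpha:{n}" for n in self.admixture_nodes()]
        return names

    def get_parameters(self) -> np.ndarray:
        lengths = [self.edge_length(u, v) for u, v in self.tree_edges()]
        alphas = [self.alpha(n) for n in self.admixture_nodes()]
        return np.array(lengths + alphas, dtype=float)

    def set_parameters(self, x: Sequence[float]) -> None:
        edges = self.tree_edges()
        admix = self.admixture_nodes()
        if len(x) != len(edges) + len(admix):
            raise GraphError("parameter vector has wrong length")
        for (u, v), val in zip(edges, x[: len(edges)]):
            self._g.edges[u, v]["length"] = float(max(val, 0.0))
        for n, val in zip(admix, x[len(edges):]):
            self._g.nodes[n]["alpha"] = float(min(max(val, 0.0), 1.0))

    # -- prediction ---------------------------------------------------------
    def expected_covariance(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels and the leaf × leaf allele-frequency covariance."""
        self.validate()
        edges = list(self._g.edges)
        e_idx = {e: i for i, e in enumerate(edges)}
        lengths = np.array([self._g.edges[e]["length"] for e in edges])
        gamma: dict[str, np.ndarray] = {}
        for node in nx.topological_sort(self._g):
            preds = list(self._g.predecessors(node))
            if not preds:
                gamma[node] = np.zeros(len(edges))
            elif len(preds) == 1:
                w = gamma[preds[0]].copy()
                w[e_idx[(preds[0], node)]] += 1.0
                gamma[node] = w
            else:
                p1, p2 = self._g.nodes[node]["parents"]
                a = self._g.nodes[node]["alpha"]
                w1 = gamma[p1].copy()
                w1[e_idx[(p1, node)]] += 1.0
                w2 = gamma[p2].copy()
                w2[e_idx[(p2, node)]] += 1.0
                gamma[node] = a * w1 + (1 - a) * w2
        pops = self.populations()
        labels = sorted(pops)
        W = np.stack([gamma[pops[lbl]] for lbl in labels])
        V = (W * lengths) @ W.T
        return labels, V

    def predict(self, config: FStatConfig) -> float:
        labels, V = self.expected_covariance()
        idx = {lbl: i for i, lbl in enumerate(labels)}
        try:
            ids = [idx[p] for p in config.populations]
        except KeyError as e:
            raise GraphError(f"population {e} not a graph leaf") from None
        return predict_from_covariance(V, ids, config.kind)

    # -- I/O -----------------------------------------------------------------
    def to_text(self) -> str:
        lines = [f"root\t{self.root}"]
        admix = set(self.admixture_nodes())
        for u, v in self.tree_edges():
            lines.append(f"edge\t{u}\t{v}\t{self.edge_length(u, v):.10g}")
        for n in sorted(admix):
            p1, p2 = self._g.nodes[n]["parents"]
            lines.append(f"admix\t{p1}\t{p2}\t{n}\t{self.alpha(n):.10g}")
        for leaf in self.leaves():
            label = self._g.nodes[leaf].get("population", leaf)
            if label != leaf:
                lines.append(f"label\t{leaf}\t{label}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AdmixtureGraph":
        g = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            if kind == "root":
                continue  # implied by in-degree
            if kind == "edge":
                _, u, v, length = parts
                g.add_edge(u, v, float(length))
            elif kind == "admix":
                _, p1, p2, child, alpha = parts
                g.add_admixture(child, p1, p2, float(alpha))
            elif kind == "label":
                g.set_population(parts[1], parts[2])
            else:
                raise GraphError(f"unknown graph line kind {kind!r}")
        g.validate()
        return g

    def to_dot(self) -> str:
        """Graphviz export: solid drift edges, dashed admixture edges."""
        lines = ["digraph admixture_graph {", "  rankdir=TB;"]
        for leaf in self.leaves():
            label = self._g.nodes[leaf].get("population", leaf)
            lines.append(f'  "{leaf}" [shape=box,label="{label}"];')
        for u, v, d in self._g.edges(data=True):
            if d["admix"]:
                p1, _ = self._g.nodes[v]["parents"]
                a = self.alpha(v)
                w = a if u == p1 else 1 - a
                lines.append(f'  "{u}" -> "{v}" [style=dashed,'
                             f'label="{100 * w:.0f}%"];')
            else:
                lines.append(f'  "{u}" -> "{v}" [label="{d["length"]:.4f}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def predict_from_covariance(V: np.ndarray, ids: Sequence[int],
                            kind: str) -> float:
    if kind == "f2":
        i, j = ids
        return float(V[i, i] + V[j, j] - 2 * V[i, j])
    if kind == "f3_outgroup":
        a, b, c = ids
        return float(V[c, c] - V[c, a] - V[c, b] + V[a, b])
    if kind == "f4":
        a, b, c, d = ids
        return float(V[a, c] - V[a, d] - V[b, c] + V[b, d])
    raise GraphError(f"cannot predict statistic kind {kind!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GraphFit:
    graph: AdmixtureGraph
    score: float
    worst_f4: tuple[str, float, float] | None
    n_restarts_used: int
    seed: int
    residuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    unconstrained: list[str] = field(default_factory=list)

    def alphas(self) -> dict[str, float]:
        return {n: self.graph.alpha(n) for n in self.graph.admixture_nodes()}


def fit_basis(table: AlleleCountTable, partition: BlockPartition,
              outgroup: str | None = None) -> list[FStatResult]:
    """Observed statistics used for graph fitting.

    All pairwise f2 among populations, plus — when an outgroup is named —
    every outgroup f3.  Jackknife SEs provide the fitting weights.
    """
    pops = sorted(table.populations)
    observed = []
    for a, b in itertools.combinations(pops, 2):
        observed.append(f_statistic(table, FStatConfig("f2", (a, b)),
                                    partition))
    if outgroup is not None:
        others = [p for p in pops if p != outgroup]
        for a, b in itertools.combinations(others, 2):
            observed.append(f_statistic(
                table, FStatConfig("f3_outgroup", (a, b, outgroup)),
                partition))
    return observed


def _residual_fn(graph: AdmixtureGraph, observed: Sequence[FStatResult]):
    """Build a residual closure over the graph's parameter vector."""
    work = graph.copy()
    obs = np.array([r.estimate for r in observed])
    se = np.array([max(r.se, SE_FLOOR) for r in observed])
    labels_probe, _ = work.expected_covariance()
    idx = {lbl: i for i, lbl in enumerate(labels_probe)}
    ids = [[idx[p] for p in r.config.populations] for r in observed]
    kinds = [r.config.kind for r in observed]

    def residuals(x: np.ndarray) -> np.ndarray:
        work.set_parameters(x)
        _, V = work.expected_covariance()
        pred = np.array([predict_from_covariance(V, i, k)
                         for i, k in zip(ids, kinds)])
        return (pred - obs) / se

    return residuals, work


def _pinned_root_edge(topology: AdmixtureGraph) -> int | None:
    """Index of the root-child edge frozen at zero during fitting.

    f-statistics depend only on covariances among leaves, which are
    invariant to sliding the root along its two child edges; only the sum of
    the two root-edge lengths is identifiable.  Pinning one of them (the
    second in sorted edge order) removes the flat direction — without it the
    root freedom leaks into other parameters, including mixing weights.
    """
    edges = topology.tree_edges()
    root = topology.root
    root_edges = [i for i, (u, _) in enumerate(edges) if u == root]
    return root_edges[1] if len(root_edges) == 2 else None


def fit_graph(topology: AdmixtureGraph, observed: Sequence[FStatResult],
              seed: int = 0, n_restarts: int = 20) -> GraphFit:
    """Bounded weighted least squares over drift lengths and mixing weights.

    Multi-start from seeded random initializations (plus the topology's own
    parameters as one start); deterministic given the seed.  One root-child
    edge is pinned at zero (the root's position is not identifiable from
    f-statistics).  Parameters whose profile score is flat within tolerance
    are flagged ``unconstrained``.
    """
    topology.validate()
    leaf_labels = set(topology.populations())
    for r in observed:
        missing = set(r.config.populations) - leaf_labels
        if missing:
            raise GraphError(f"observed {r.config} uses non-leaf populations "
                             f"{sorted(missing)}")
    residuals, work = _residual_fn(topology, observed)
    n_len = len(topology.tree_edges())
    n_alpha = len(topology.admixture_nodes())
    n_par = n_len + n_alpha
    pin = _pinned_root_edge(topology)
    free = np.array([i for i in range(n_par) if i != pin])

    def expand(xfree: np.ndarray) -> np.ndarray:
        x = np.zeros(n_par)
        x[free] = xfree
        return x

    def residuals_free(xfree: np.ndarray) -> np.ndarray:
        return residuals(expand(xfree))

    lo_full = np.zeros(n_par)
    hi_full = np.concatenate([np.full(n_len, MAX_DRIFT), np.ones(n_alpha)])
    lo, hi = lo_full[free], hi_full[free]

    rng = np.random.default_rng(seed)
    starts = [np.clip(topology.get_parameters()[free], lo + 1e-6, hi - 1e-6)]
    for _ in range(max(n_restarts - 1, 0)):
        x0 = np.concatenate([
            rng.uniform(1e-4, 0.1, size=n_len),
            rng.uniform(0.05, 0.95, size=n_alpha),
        ])
        starts.append(x0[free])

    best = None
    for x0 in starts:
        sol = least_squares(residuals_free, x0, bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    x_best = expand(best.x)
    work.set_parameters(x_best)
    score = float(2 * best.cost)  # sum of squared weighted residuals

    res_rows = []
    final = residuals(x_best)
    for r, z in zip(observed, final):
        res_rows.append({"config": str(r.config), "observed": r.estimate,
                         "predicted": r.estimate + z * max(r.se, SE_FLOOR),
                         "weighted_residual": z})
    names = np.array(topology.parameter_names())
    flat = _flat_parameters(residuals_free, best.x, lo, hi)
    unconstrained = [str(names[free][i]) for i in flat]
    work.set_parameters(x_best)   # the profile probes mutate the closure
    fitted = work.copy()
    return GraphFit(fitted, score, None, len(starts), seed,
                    pd.DataFrame(res_rows), unconstrained)


def _flat_parameters(residuals, x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                     delta: float = 0.01, tol: float = 1e-8) -> list[str]:
    base = float((residuals(x) ** 2).sum())
    flat = []
    for i in range(x.size):
        changes = []
        for sign in (-1, 1):
            xi = x.copy()
            xi[i] = min(max(xi[i] + sign * delta, lo[i]), hi[i])
            if xi[i] == x[i]:
                continue
            changes.append(abs(float((residuals(xi) ** 2).sum()) - base))
        if changes and max(changes) < tol:
            flat.append(i)
    return flat


def worst_residual(fit: GraphFit, table: AlleleCountTable,
                   partition: BlockPartition) -> tuple[str, float, float]:
    """The f4 configuration with the largest |Z| of observed − predicted.

    Enumerates every quadruple of graph populations present in the table and
    the three pairings of each; |Z| is invariant under orientation flips, so
    one orientation per pairing suffices.
    """
    labels, V = fit.graph.expected_covariance()
    idx = {lbl: i for i, lbl in enumerate(labels)}
    pops = [p for p in labels if p in table.populations]
    worst = ("", 0.0, 0.0)
    for quad in itertools.combinations(sorted(pops), 4):
        a, b, c, d = quad
        for pair in [(a, b, c, d), (a, c, b, d), (a, d, b, c)]:
            cfg = FStatConfig("f4", pair)
            obs = f_statistic(table, cfg, partition)
            pred = predict_from_covariance(V, [idx[p] for p in pair], "f4")
            se = max(obs.se, SE_FLOOR)
            z = (obs.estimate - pred) / se
            if abs(z) > abs(worst[2]):
                worst = (str(cfg), float(obs.estimate - pred), float(z))
    fit.worst_f4 = worst
    return worst


# ---------------------------------------------------------------------------
# greedy admixture-edge search
# ---------------------------------------------------------------------------

def _candidate_edges(graph: AdmixtureGraph) -> list[tuple[tuple, tuple]]:
    """(source edge, target edge) pairs whose connection keeps the DAG acyclic."""
    edges = graph.tree_edges()
    anc = {n: nx.ancestors(graph._g, n) for n in graph.nodes}
    out = []
    for src in edges:
        for tgt in edges:
            if src == tgt:
                continue
            u, _ = src
            _, y = tgt
            # a path m -> y -> ... -> u -> s -> m would close a cycle
            if y == u or y in anc[u]:
                continue
            out.append((src, tgt))
    return out


def _insert_admixture(graph: AdmixtureGraph, src: tuple, tgt: tuple,
                      tag: int) -> AdmixtureGraph:
    g = graph.copy()
    u, v = src
    x, y = tgt
    s, m = f"_src{tag}", f"_mix{tag}"
    len_src = g.edge_length(u, v)
    len_tgt = g.edge_length(x, y)
    g._g.remove_edge(u, v)
    g._g.remove_edge(x, y)
    g.add_edge(u, s, len_src / 2)
    g.add_edge(s, v, len_src / 2)
    g.add_admixture(m, x, s, alpha=0.9)   # start mostly tree-like
    g.add_edge(m, y, len_tgt)
    g.validate()
    return g


@dataclass
class GreedyStep:
    added: str
    worst_before: tuple[str, float, float]
    worst_after: tuple[str, float, float]
    score: float


def greedy_edge_addition(topology: AdmixtureGraph, table: AlleleCountTable,
                         partition: BlockPartition, max_edges: int = 2,
                         z_stop: float = 3.0, outgroup: str | None = None,
                         seed: int = 0, n_restarts: int = 20,
                         candidate_restarts: int = 6
                         ) -> tuple[GraphFit, list[GreedyStep]]:
    """Add admixture edges one by one to resolve the worst f4 incongruence.

    Each round fits every acyclic (source edge → target edge) insertion and
    keeps the one that most reduces the largest |Z| residual; the search
    stops when the worst |Z| falls below ``z_stop``, when ``max_edges`` is
    reached, or when no candidate improves.
    """
    observed = fit_basis(table, partition, outgroup)
    fit = fit_graph(topology, observed, seed=seed, n_restarts=n_restarts)
    worst_residual(fit, table, partition)
    log: list[GreedyStep] = []
    for round_no in range(max_edges):
        if abs(fit.worst_f4[2]) < z_stop:
            break
        best_fit, best_pair = None, None
        for k, (src, tgt) in enumerate(_candidate_edges(fit.graph)):
            try:
                cand = _insert_admixture(fit.graph, src, tgt,
                                         tag=round_no * 1000 + k)
            except GraphError:
                continue
            cfit = fit_graph(cand, observed, seed=seed + 1 + k,
                             n_restarts=candidate_restarts)
            worst_residual(cfit, table, partition)
            if best_fit is None or abs(cfit.worst_f4[2]) < abs(best_fit.worst_f4[2]):
                best_fit, best_pair = cfit, (src, tgt)
        if best_fit is None or \
                abs(best_fit.worst_f4[2]) >= abs(fit.worst_f4[2]):
            break  # no candidate improves
        refit = fit_graph(best_fit.graph, observed, seed=seed,
                          n_restarts=n_restarts)
        worst_residual(refit, table, partition)
        if abs(refit.worst_f4[2]) > abs(best_fit.worst_f4[2]):
            refit = best_fit
        log.append(GreedyStep(
            added=f"{best_pair[0]} -> {best_pair[1]}",
            worst_before=fit.worst_f4, worst_after=refit.worst_f4,
            score=refit.score))
        fit = refit
    return fit, log


# ---------------------------------------------------------------------------
# X-chromosome refit
# ---------------------------------------------------------------------------

def refit_admixture_on_x(fit: GraphFit, table_x: AlleleCountTable,
                         partition_x: BlockPartition,
                         mode: str = "alpha_and_scale",
                         outgroup: str | None = None, seed: int = 0,
                         n_restarts: int = 10) -> pd.DataFrame:
    """Refit mixing weights on X-chromosome statistics with fixed topology.

    Modes: ``alpha_only`` freezes drift at the autosomal values;
    ``alpha_and_scale`` (default) additionally fits one global drift rescale
    shared by all edges — the X has a smaller effective size (≈ 3/4 of the
    autosomal N at an even sex ratio), which shrinks or stretches all drift
    lengths together; ``alpha_and_drift`` frees every drift length, which
    requires enough populations for the X basis to determine them and raises
    otherwise.  Returns one row per admixture node with the autosomal and
    X-refitted mixing weights toward the node's first parent.
    """
    if mode not in ("alpha_only", "alpha_and_scale", "alpha_and_drift"):
        raise GraphError(f"unknown refit mode {mode!r}")
    graph = fit.graph.copy()
    admix = graph.admixture_nodes()
    if not admix:
        raise GraphError("graph has no admixture nodes to refit")
    observed = fit_basis(table_x, partition_x, outgroup)

    base_lengths = np.array([graph.edge_length(u, v)
                             for u, v in graph.tree_edges()])
    n_alpha = len(admix)
    if mode == "alpha_and_drift":
        n_params = len(base_lengths) + n_alpha
        if _pinned_root_edge(graph) is not None:
            n_params -= 1
        if len(observed) < n_params:
            raise GraphError(
                f"X basis underdetermined: {len(observed)} statistics for "
                f"{n_params} free parameters; use alpha_only or "
                f"alpha_and_scale")
        xfit = fit_graph(graph, observed, seed=seed, n_restarts=n_restarts)
        fitted_alphas = xfit.alphas()
        extra = {"score_x": xfit.score}
    else:
        residuals, work = _residual_fn(graph, observed)

        def packed(theta: np.ndarray) -> np.ndarray:
            alphas = theta[:n_alpha]
            scale = theta[n_alpha] if mode == "alpha_and_scale" else 1.0
            return residuals(np.concatenate([scale * base_lengths, alphas]))

        n_theta = n_alpha + (1 if mode == "alpha_and_scale" else 0)
        lo = np.zeros(n_theta)
        hi = np.ones(n_theta)
        if mode == "alpha_and_scale":
            hi[-1] = 5.0  # drift rescale
        rng = np.random.default_rng(seed)
        starts = [np.concatenate([
            [graph.alpha(n) for n in admix],
            [1.0] if mode == "alpha_and_scale" else [],
        ])]
        for _ in range(max(n_restarts - 1, 0)):
            t0 = rng.uniform(0.05, 0.95, size=n_alpha)
            if mode == "alpha_and_scale":
                t0 = np.concatenate([t0, rng.uniform(0.3, 2.0, size=1)])
            starts.append(t0)
        best = None
        for t0 in starts:
            sol = least_squares(packed, t0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
        fitted_alphas = dict(zip(admix, best.x[:n_alpha]))
        extra = {"score_x": float(2 * best.cost)}
        if mode == "alpha_and_scale":
            extra["drift_scale_x"] = float(best.x[n_alpha])

    rows = []
    for n in admix:
        rows.append({
            "admixture_node": n,
            "first_parent": fit.graph._g.nodes[n]["parents"][0],
            "alpha_autosome": fit.graph.alpha(n),
            "alpha_x": float(fitted_alphas[n]),
            **extra,
        })
    return pd.DataFrame(rows)
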