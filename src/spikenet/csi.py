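"""Causal Structure Inference (CSI) over transcription-factor time series.

For each child TF the algorithm places a posterior over candidate
parental sets (subsets of the other TFs up to size ``max_parents``,
including the empty set).  The transition from the parents' expression
at time t to the child's at t+1 is modelled as a Gaussian process with a
squared-exponential kernel plus observation noise.  EM alternates an
exact E step — q(Pa) proportional to prior(Pa) times the GP marginal
likelihood — with an M step that re-optimizes kernel hyperparameters
(length-scale, signal variance, noise variance), shared across parental
sets for the child, by L-BFGS on the q-weighted marginal log-likelihood.
The weight of a directed edge p -> c is the marginal posterior inclusion
probability sum over parental sets containing p, hence lies in [0, 1].

Replicate series are treated as independent realizations of the same
transition function (their likelihoods multiply).  Initialization is
deterministic (length-scale 1 on standardized inputs, signal variance 1,
noise variance 0.1), so inference is fully deterministic given the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = ["CsiConfig", "DirectedEdgeSet", "csi_infer", "filter_edges", "betweenness", "to_graph"]


@dataclass
class CsiConfig:
    """CSI settings: parental-set depth, kernel init, EM control, thresholds."""

    max_parents: int = 2
    length_scale: float = 1.0
    signal_var: float = 1.0
    noise_var: float = 0.1
    em_max_iter: int = 25
    em_tol: float = 1e-4
    theta_keep: float = 0.001
    theta_strong: float = 0.03

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.theta_keep > self.theta_strong:
            raise ValueError("theta_keep must not exceed theta_strong")


@dataclass
class DirectedEdgeSet:
    """Weighted TF -> TF edges with optional per-node annotations.

    ``edges`` has columns parent, child, weight.  ``posteriors`` maps each
    child to its full parental-set posterior (for diagnostics); edge
    weights are marginals of those per-child distributions.
    """

    edges: pd.DataFrame
    nodes: list[str]
    posteriors: dict = field(default_factory=dict)
    betweenness: pd.Series | None = None
    modules: pd.Series | None = None
    converged: bool = True
    objective_traces: dict = field(default_factory=dict)  # child -> evidence per EM iteration

    def weight(self, parent: str, child: str) -> float:
        sel = self.edges[(self.edges["parent"] == parent) & (self.edges["child"] == child)]
        return float(sel["weight"].iloc[0]) if len(sel) else 0.0


def _se_kernel(x: np.ndarray, ls: float, sf2: float) -> np.ndarray:
    """Squared-exponential kernel matrix over rows of x (n x d)."""
    if x.shape[1] == 0:
        return np.full((x.shape[0], x.shape[0]), sf2)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return sf2 * np.exp(-0.5 * d2 / (ls**2))


def _gp_loglik(x: np.ndarray, y: np.ndarray, ls: float, sf2: float, sn2: float) -> float:
    """GP marginal log-likelihood of y given inputs x."""
    n = y.size
    K = _se_kernel(x, ls, sf2) + (sn2 + 1e-9) * np.eye(n)
    try:
        c, low = cho_factor(K, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = cho_solve((c, low), y, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi))


def _transitions(series: list[pd.DataFrame]) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """(inputs at t, outputs at t+1) per replicate series (TF x time)."""
    out = []
    for s in series:
        out.append((s.iloc[:, :-1], s.iloc[:, 1:]))
    return out


def csi_infer(series, config: CsiConfig | None = None) -> DirectedEdgeSet:
    """Infer a directed TF network by CSI over one or more time series.

    ``series`` is a TF x time DataFrame, or a list of them (replicates).
    Expression is standardized per TF across all series before
    inference.  Children with zero variance are skipped (no incoming
    edges).  Edges with weight below ``config.theta_keep`` are dropped
    from the returned edge list.
    """
    config = config or CsiConfig()
    if isinstance(series, pd.DataFrame):
        series = [series]
    tfs = list(series[0].index)
    for s in series:
        if list(s.index) != tfs:
            raise ValueError("all replicate series must share the same TF rows")
        if s.shape[1] < 3:
            raise ValueError("CSI needs >= 3 time points per series")
    # per-TF standardization across the concatenated series
    concat = pd.concat(series, axis=1)
    mu = concat.mean(axis=1)
    sd = concat.std(axis=1).replace(0.0, 1.0)
    series = [s.sub(mu, axis=0).div(sd, axis=0) for s in series]
    zero_var = set(concat.index[concat.std(axis=1) == 0])

    trans = _transitions(series)
    weights: dict[tuple[str, str], float] = {}
    posteriors = {}
    traces: dict[str, list] = {}
    converged_all = True
    for child in tfs:
        if child in zero_var:
            continue
        parents_pool = [t for t in tfs if t != child]
        psets = [()]
        for d in range(1, config.max_parents + 1):
            psets.extend(itertools.combinations(parents_pool, d))
        y_parts = [np.asarray(out.loc[child], dtype=float) for _, out in trans]
        x_parts = {
            pa: [np.asarray(inp.loc[list(pa)], dtype=float).T for inp, _ in trans] for pa in psets
        }
        log_prior = -math.log(len(psets))  # uniform over candidate sets

        def loglik_all(theta_log):
            ls, sf2, sn2 = np.exp(theta_log)
            ll = np.empty(len(psets))
            for j, pa in enumerate(psets):
                tot = 0.0
                for xs, ys in zip(x_parts[pa], y_parts):
                    tot += _gp_loglik(xs, ys, ls, sf2, sn2)
                ll[j] = tot
            return ll

        theta = np.log([config.length_scale, config.signal_var, config.noise_var])
        ll = loglik_all(theta)
        obj_prev = -np.inf
        trace = []
        q = None
        converged = False
        for _ in range(config.em_max_iter):
            # E step: exact posterior over parental sets
            logq = ll + log_prior
            logq -= logsumexp(logq)
            q = np.exp(logq)
            # M step: shared hyperparameters maximize the q-weighted likelihood
            res = optimize.minimize(
                lambda th: -float(q @ loglik_all(th)),
                theta,
                method="L-BFGS-B",
                bounds=[(-4.0, 4.0), (-6.0, 4.0), (-9.0, 2.0)],
                options={"maxiter": 40},
            )
            if res.fun < -(q @ ll):  # accept only improvements
                theta = res.x
                ll = loglik_all(theta)
            obj = float(logsumexp(ll + log_prior))  # marginal evidence
            trace.append(obj)
            if abs(obj - obj_prev) < config.em_tol:
                converged = True
                break
            obj_prev = obj
        converged_all = converged_all and converged
        traces[child] = trace
        logq = ll + log_prior
        logq -= logsumexp(logq)
        q = np.exp(logq)
        posteriors[child] = {pa: float(qi) for pa, qi in zip(psets, q)}
        for p in parents_pool:
            w = float(sum(qi for pa, qi in zip(psets, q) if p in pa))
            if w >= config.theta_keep:
                weights[(p, child)] = min(1.0, w)

    edges = pd.DataFrame(
        [{"parent": p, "child": c, "weight": w} for (p, c), w in sorted(weights.items())],
        columns=["parent", "child", "weight"],
    )
    es = DirectedEdgeSet(edges, tfs, posteriors, converged=converged_all, objective_traces=traces)
    es.betweenness = betweenness(es)
    return es


def filter_edges(edge_set: DirectedEdgeSet, theta: float) -> DirectedEdgeSet:
    """Keep edges with weight >= theta; drop nodes left without any edge."""
    kept = edge_set.edges[edge_set.edges["weight"] >= theta].reset_index(drop=True)
    nodes = sorted(set(kept["parent"]) | set(kept["child"]))
    out = DirectedEdgeSet(kept, nodes, edge_set.posteriors, converged=edge_set.converged)
    out.betweenness = betweenness(out)
    if edge_set.modules is not None:
        out.modules = edge_set.modules.reindex(nodes)
    return out


def to_graph(edge_set: DirectedEdgeSet) -> nx.DiGraph:
    """networkx view of the edge set (weight attribute on edges)."""
    g = nx.DiGraph()
    g.add_nodes_from(edge_set.nodes)
    for _, row in edge_set.edges.iterrows():
        g.add_edge(row["parent"], row["child"], weight=float(row["weight"]))
    return g


def betweenness(edge_set: DirectedEdgeSet) -> pd.Series:
    """Directed shortest-path betweenness on edge presence (unweighted).

    Raw (unnormalized) counts: on the path a -> b -> c the middle node
    scores 1.
    """
    g = to_graph(edge_set)
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").reindex(edge_set.nodes).fillna(0.0)


def write_graphml(edge_set: DirectedEdgeSet, path) -> None:
    """GraphML export with betweenness/module node attributes (for Cytoscape)."""
    g = to_graph(edge_set)
    if edge_set.betweenness is not None:
        nx.set_node_attributes(g, edge_set.betweenness.to_dict(), "betweenness")
    if edge_set.modules is not None:
        nx.set_node_attributes(g, {k: int(v) for k, v in edge_set.modules.dropna().items()}, "module")
    nx.write_graphml(g, path)
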