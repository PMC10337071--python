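"""Network topology, robustness, and node-role analysis.

All metrics treat the network as an unsigned, unweighted simple graph.
Observed values are compared against Erdős–Rényi G(n, m) ensembles with the
same node and edge counts; a deviation beyond 1.96 ensemble standard
deviations is called significant (P < 0.05 under a normal reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .network import Network

__all__ = [
    "TopologySummary",
    "fit_degree_tail",
    "EnsembleStats",
    "TailFit",
    "natural_connectivity",
    "global_efficiency",
    "avg_path_length",
    "complexity_indices",
    "er_ensemble",
    "robustness_removal",
    "zi_pi",
    "tail_powerlaw",
]


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, Network) else net


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    pos_frac: float
    avgL: float
    global_efficiency: float
    natural_connectivity: float
    degree_centralization: float
    clustering_coefficient: float
    modularity: float


@dataclass
class EnsembleStats:
    metric: str
    mean: float
    sd: float
    n_rep: int
    observed: float
    significant: bool


@dataclass
class TailFit:
    x_min: int
    exponent: float
    ks_pvalue: float
    n_covered: int
    sf_class: str  # "not" | "weakest" | "weak"


def natural_connectivity(net) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    A spectral robustness measure: counts closed walks of all lengths,
    weighted by 1/k!.  Edgeless graphs score 0.
    """
    g = _graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("graph has no nodes")
    if g.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(g, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(special.logsumexp(lam) - np.log(n))


def global_efficiency(net) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    g = _graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    return float(nx.global_efficiency(g))


def avg_path_length(net) -> float:
    """Mean shortest-path distance over connected pairs only.

    Disagrees with ``global_efficiency`` on disconnected graphs by design:
    unreachable pairs are excluded here, counted as zero efficiency there.
    """
    g = _graph(net)
    total, pairs = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs == 0:
        warnings.warn("no reachable pairs: avgL undefined", stacklevel=2)
        return float("nan")
    return total / pairs


def degree_centralization(net) -> float:
    """Freeman degree centralization: sum(k_max - k_i) / ((N-1)(N-2))."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 3:
        warnings.warn("centralization undefined for N < 3; returning 0", stacklevel=2)
        return 0.0
    deg = np.array([d for _, d in g.degree()])
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def complexity_indices(net, partition) -> TopologySummary:
    """Bundle complexity/efficiency metrics for one network and partition."""
    g = _graph(net)
    communities = partition.communities() if hasattr(partition, "communities") else partition
    q = nx.community.modularity(g, communities) if g.number_of_edges() else float("nan")
    pos = net.positive_fraction() if isinstance(net, Network) else float("nan")
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        pos_frac=pos,
        avgL=avg_path_length(g),
        global_efficiency=global_efficiency(g),
        natural_connectivity=natural_connectivity(g),
        degree_centralization=degree_centralization(g),
        clustering_coefficient=float(nx.average_clustering(g)),
        modularity=float(q),
    )


def er_ensemble(
    n: int,
    m: int,
    metric,
    observed: float,
    n_rep: int = 100,
    seed: int = 0,
    name: str | None = None,
) -> EnsembleStats:
    """Distribution of a metric over G(n, m) graphs, plus the 1.96-SD test."""
    if m > n * (n - 1) // 2:
        raise ValueError("m exceeds the maximum number of edges")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_rep)
    for r in range(n_rep):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        vals[r] = metric(g)
    mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
    return EnsembleStats(
        metric=name or getattr(metric, "__name__", "metric"),
        mean=mean,
        sd=sd,
        n_rep=n_rep,
        observed=float(observed),
        significant=bool(abs(observed - mean) > 1.96 * sd),
    )


def robustness_removal(
    net,
    fractions: list[float] = (0.2, 0.3, 0.4),
    n_rep: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Natural connectivity after random removal of node fractions.

    Returns one row per fraction with the mean and SD of the remaining
    natural connectivity over ``n_rep`` uniform removals.
    """
    g = _graph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError("fractions must lie in (0, 1)")
        k = int(round(f * n))
        if k >= n:
            raise ValueError(f"fraction {f} removes every node")
        vals = np.empty(n_rep)
        for r in range(n_rep):
            keep = rng.permutation(n)[: n - k]
            sub = g.subgraph([nodes[i] for i in keep])
            vals[r] = natural_connectivity(sub) if sub.number_of_nodes() else 0.0
        rows.append(
            {"fraction": f, "mean": vals.mean(), "sd": vals.std(ddof=1), "n_rep": n_rep}
        )
    return pd.DataFrame(rows)


def zi_pi(net, partition) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Roles follow the (z = 2.5, P = 0.62) cuts: kinless hubs (z > 2.5,
    P > 0.62), provincial hubs (z > 2.5, P <= 0.62), connectors (z <= 2.5,
    P > 0.62), peripherals otherwise.  Kinless and provincial hubs together
    are the network's hub nodes.
    """
    g = _graph(net)
    node_to_module = (
        partition.node_to_module if hasattr(partition, "node_to_module") else partition
    )
    missing = [v for v in g.nodes if v not in node_to_module]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")

    kappa = {v: 0 for v in g.nodes}  # within-module degree
    part_sums = {v: {} for v in g.nodes}
    for u, v in g.edges:
        mu, mv = node_to_module[u], node_to_module[v]
        part_sums[u][mv] = part_sums[u].get(mv, 0) + 1
        part_sums[v][mu] = part_sums[v].get(mu, 0) + 1
        if mu == mv:
            kappa[u] += 1
            kappa[v] += 1

    by_module: dict = {}
    for v in g.nodes:
        by_module.setdefault(node_to_module[v], []).append(kappa[v])
    mstats = {
        m: (np.mean(ks), np.std(ks)) for m, ks in by_module.items()
    }

    rows = []
    for v in g.nodes:
        mean_k, sd_k = mstats[node_to_module[v]]
        z = (kappa[v] - mean_k) / sd_k if sd_k > 0 else 0.0
        k = g.degree(v)
        p = 1.0 - sum((c / k) ** 2 for c in part_sums[v].values()) if k > 0 else 0.0
        if z > 2.5:
            role = "kinless hub" if p > 0.62 else "provincial hub"
        else:
            role = "connector" if p > 0.62 else "peripheral"
        rows.append({"node": v, "z": z, "P": p, "role": role, "degree": k})
    return pd.DataFrame(rows).set_index("node")


def _powerlaw_cdf(x: np.ndarray, alpha: float, x_min: int) -> np.ndarray:
    """CDF of the discrete power law P(X = x) = x^-alpha / zeta(alpha, x_min)."""
    z = special.zeta(alpha, x_min)
    return 1.0 - special.zeta(alpha, np.asarray(x, dtype=float) + 1.0) / z


def tail_powerlaw(net) -> TailFit:
    """Discrete power-law fit to the upper degree tail (degree >= median).

    Maximum-likelihood exponent with x_min fixed at the median degree,
    followed by a one-sample KS test of the fitted tail.  Networks whose
    tail passes the KS test (P > 0.05) are called "weak" scale-free when
    the tail covers more than 50 nodes and "weakest" otherwise.
    """
    g = _graph(net)
    deg = np.array([d for _, d in g.degree()])
    if deg.size < 10:
        raise ValueError("need at least 10 nodes")
    return fit_degree_tail(deg)


def fit_degree_tail(deg: np.ndarray) -> TailFit:
    """Power-law tail fit on a raw degree sequence (see :func:`tail_powerlaw`)."""
    deg = np.asarray(deg, dtype=int)
    x_min = max(int(np.median(deg)), 1)
    tail = deg[deg >= x_min]
    n = tail.size
    if np.all(tail == tail[0]):
        return TailFit(x_min=x_min, exponent=np.nan, ks_pvalue=np.nan,
                       n_covered=n, sf_class="not")

    logsum = np.log(tail).sum()

    def nll(alpha):
        return n * np.log(special.zeta(alpha, x_min)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    alpha = float(res.x)

    # KS distance for a discrete model: both CDFs are step functions on the
    # integers, so compare right-continuous values at each support point and
    # the left limits (F evaluated at x - 1)
    xs, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / n
    ecdf_left = np.concatenate(([0.0], ecdf[:-1]))
    fitted = _powerlaw_cdf(xs, alpha, x_min)
    fitted_left = np.where(
        xs - 1 >= x_min, _powerlaw_cdf(np.maximum(xs - 1, x_min), alpha, x_min), 0.0
    )
    d = float(
        max(np.max(np.abs(ecdf - fitted)), np.max(np.abs(fitted_left - ecdf_left)))
    )
    ks_p = float(stats.kstwo.sf(d, n))

    if ks_p > 0.05:
        sf_class = "weak" if n > 50 else "weakest"
    else:
        sf_class = "not"
    return TailFit(x_min=x_min, exponent=alpha, ks_pvalue=ks_p,
                   n_covered=n, sf_class=sf_class)
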