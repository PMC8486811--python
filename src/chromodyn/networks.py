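"""Emergent regulatory-network inference from transcriptional activities.

Each replicate run contributes one observation per TU (its within-run mean
activity); the Pearson correlation of these per-run activities across the
run ensemble, thresholded on magnitude and Student-t significance, defines
the network.  The published edge rules -- |r| > 0.15 with p < 1e-6 at ~1000
runs, and r > 0.12 with p = 7e-4 at 800 runs -- are consistent with exactly
this construction (see the t-formula below with n = number of runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .params import ConfigurationError


@dataclass(frozen=True)
class CorrelationMatrix:
    """TU x TU Pearson coefficients with two-sided t-test p-values.

    Pairs involving a constant column are *missing* (NaN), never zero.
    """

    tu_indices: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n_samples: int


@dataclass(frozen=True)
class RegulatoryNetwork:
    tu_indices: np.ndarray
    edges: tuple  # (i, j, r, sign) with i, j TU bead indices
    r_min: float
    p_max: float
    sign_filter: str = "both"

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in self.tu_indices)
        for i, j, r, sign in self.edges:
            g.add_edge(int(i), int(j), r=float(r), sign=sign)
        return g

    def to_edge_table(self):
        import pandas as pd

        return pd.DataFrame(self.edges, columns=["i", "j", "r", "sign"])


def pearson_p_value(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), t(n-2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p if p.ndim else float(p)


def correlation_matrix(per_run_activities: np.ndarray,
                       tu_indices: np.ndarray | None = None) -> CorrelationMatrix:
    """Pearson correlations across runs of per-TU activities.

    Rows are runs (one observation per simulation), columns TUs.  Constant
    columns give undefined correlations, recorded as NaN.
    """
    x = np.asarray(per_run_activities, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ConfigurationError("need a (runs x TU) matrix with >= 3 runs")
    n_runs, n_tu = x.shape
    if tu_indices is None:
        tu_indices = np.arange(n_tu)
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float).reshape(n_tu, n_tu)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    p = pearson_p_value(np.where(np.isnan(r), 0.0, r), n_runs)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, np.nan)
    return CorrelationMatrix(np.asarray(tu_indices), r, p, n_runs)


def build_network(corr: CorrelationMatrix, r_min: float = 0.15,
                  p_max: float = 1e-6,
                  sign_filter: str = "both") -> RegulatoryNetwork:
    """Threshold the correlation matrix into a signed graph.

    Toy-model rule: |r| > 0.15, p < 1e-6, both signs.  The whole-chromosome
    variant uses r > 0.12, positive edges only (sign_filter='positive').
    Pure function of (corr, thresholds): no randomness.  NaN (missing)
    correlations never form edges.
    """
    if sign_filter not in ("both", "positive"):
        raise ConfigurationError(f"unknown sign_filter {sign_filter!r}")
    n = corr.r.shape[0]
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            r = corr.r[a, b]
            p = corr.p[a, b]
            if np.isnan(r) or np.isnan(p):
                continue
            if sign_filter == "positive" and r <= 0:
                continue
            if abs(r) > r_min and p < p_max:
                edges.append((int(corr.tu_indices[a]), int(corr.tu_indices[b]),
                              float(r), "+" if r > 0 else "-"))
    return RegulatoryNetwork(corr.tu_indices, tuple(edges), r_min, p_max,
                             sign_filter)


def largest_component_fraction(network: RegulatoryNetwork) -> float:
    """Fraction of nodes in the largest connected component (1 = percolating)."""
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        raise ConfigurationError("network has no nodes")
    biggest = max((len(c) for c in nx.connected_components(g)), default=1)
    return biggest / g.number_of_nodes()


def small_world_and_degree_stats(network: RegulatoryNetwork,
                                 activities: np.ndarray | None = None,
                                 n_null: int = 20,
                                 seed: int = 0) -> dict:
    """Clustering, path length, small-world coefficient, degree statistics.

    The small-world coefficient s = (C/C_rand)/(L/L_rand) uses
    degree-preserving double-edge-swap randomisations of the largest
    component.  The node-degree survival function is fitted by a
    maximum-likelihood exponential on nodes with degree >= 1 (shifted MLE:
    rate = 1/(mean degree - 1)), reported with a KS goodness-of-fit
    statistic.  Modularity uses greedy modularity maximisation
    (Clauset-Newman-Moore).
    """
    g = network.to_graph()
    out: dict = {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
    if g.number_of_edges() == 0:
        out.update({k: float("nan") for k in
                    ("clustering", "path_length", "small_world",
                     "degree_decay_rate", "degree_fit_ks",
                     "degree_activity_spearman", "modularity")})
        return out
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp).copy()
    C = nx.average_clustering(sub)
    L = nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    n_swap = max(10 * sub.number_of_edges(), 1)
    for _ in range(n_null):
        h = sub.copy()
        try:
            nx.double_edge_swap(h, nswap=n_swap, max_tries=50 * n_swap,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXException:
            pass  # too few swappable pairs (e.g. a star); keep partial rewiring
        if nx.is_connected(h) and h.number_of_nodes() > 1:
            l_rand.append(nx.average_shortest_path_length(h))
        c_rand.append(nx.average_clustering(h))
    out["clustering"] = C
    out["path_length"] = L
    if c_rand and l_rand and np.mean(c_rand) > 0 and np.mean(l_rand) > 0 and L > 0:
        out["small_world"] = (C / np.mean(c_rand)) / (L / np.mean(l_rand))
    else:
        out["small_world"] = float("nan")
    degrees = np.array([d for _, d in g.degree()])
    tail = degrees[degrees >= 1]
    if tail.size >= 3 and tail.mean() > 1:
        rate = 1.0 / (tail.mean() - 1.0)
        out["degree_decay_rate"] = rate
        ks = stats.kstest(tail - 1, "expon", args=(0, 1.0 / rate))
        out["degree_fit_ks"] = float(ks.statistic)
    else:
        out["degree_decay_rate"] = float("nan")
        out["degree_fit_ks"] = float("nan")
    if activities is not None:
        acts = np.asarray(activities, dtype=float)
        node_order = {int(t): q for q, t in enumerate(network.tu_indices)}
        deg = np.array([g.degree(int(t)) for t in network.tu_indices])
        if np.std(deg) > 0 and np.std(acts) > 0:
            rho, _ = stats.spearmanr(deg, acts)
            out["degree_activity_spearman"] = float(rho)
        else:
            out["degree_activity_spearman"] = float("nan")
    try:
        comms = nx.algorithms.community.greedy_modularity_communities(g)
        out["modularity"] = nx.algorithms.community.modularity(g, comms)
    except (ZeroDivisionError, nx.NetworkXError):
        out["modularity"] = float("nan")
    return out


def network_difference(corr_a: CorrelationMatrix,
                       corr_b: CorrelationMatrix) -> np.ndarray:
    """Elementwise change in Pearson correlation, r_b - r_a.

    NaN (missing) entries propagate.  Antisymmetric under argument swap.
    """
    if not np.array_equal(corr_a.tu_indices, corr_b.tu_indices):
        raise ConfigurationError("correlation matrices have mismatched TU sets")
    return corr_b.r - corr_a.r


# ---------------------------------------------------------------------------
# export

def write_edge_list(network: RegulatoryNetwork, corr: CorrelationMatrix, path):
    idx = {int(t): q for q, t in enumerate(corr.tu_indices)}
    with open(path, "w") as fh:
        fh.write("i\tj\tr\tp\tsign\n")
        for i, j, r, sign in network.edges:
            p = corr.p[idx[i], idx[j]]
            fh.write(f"{i}\t{j}\t{r:.6f}\t{p:.3e}\t{sign}\n")


def write_graphml(network: RegulatoryNetwork, path):
    nx.write_graphml(network.to_graph(), path)


def write_matrix_tsv(matrix: np.ndarray, tu_indices: np.ndarray, path):
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(f"TU{int(t)}" for t in tu_indices) + "\n")
        for q, t in enumerate(tu_indices):
            row = "\t".join("nan" if np.isnan(v) else f"{v:.6f}"
                            for v in matrix[q])
            fh.write(f"TU{int(t)}\t{row}\n")
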