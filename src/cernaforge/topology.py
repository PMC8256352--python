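"""Topology fitness assessment of a ceRNA graph.

Four per-node metrics are computed on the simple undirected network —
degree, topological coefficient, closeness centrality and normalized
betweenness centrality — and each is summarised as a series against
degree, to which a power law ``y = a · x^b`` is fitted by ordinary least
squares on (log10 x, log10 y). The coefficient of determination of each
fit (in log space) is the "fitness" score: a scale-free-like ceRNA
network yields high R² across the four panels.

Two series conventions are supported. ``per_node`` (default) fits the
raw (degree, metric) scatter for the three centrality-style metrics —
the convention of the Cytoscape NetworkAnalyzer plots this assessment
mirrors — while ``per_degree`` first averages the metric over nodes of
equal degree. The degree panel always uses the degree distribution
P(k) itself. Non-positive values are dropped before the log transform.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ValidationError

METRICS = ("degree", "topological_coefficient", "closeness", "betweenness")


@dataclass
class PowerLawFit:
    a: float
    b: float
    r_squared: float
    n_points: int


@dataclass
class TopologyReport:
    """Per-node metrics, per-metric series and power-law fit summaries."""

    node_metrics: dict[str, dict[str, float]]
    series: dict[str, tuple[np.ndarray, np.ndarray]]
    fits: dict[str, PowerLawFit]
    errors: dict[str, str] = field(default_factory=dict)
    mode: str = "per_node"

    def r_squared(self) -> dict[str, float]:
        return {m: f.r_squared for m, f in self.fits.items()}


def _require_simple(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if any(u == v for u, v in graph.edges()):
        raise ValidationError("graph has self-loops")
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("expected a simple undirected graph")


def check_tripartite(graph: nx.Graph) -> None:
    """Assert no direct mRNA–lncRNA edges (typed graphs only)."""
    for u, v in graph.edges():
        cu = graph.nodes[u].get("rna_class")
        cv = graph.nodes[v].get("rna_class")
        if {cu, cv} == {"mRNA", "lncRNA"}:
            raise ValidationError(f"direct mRNA–lncRNA edge {u!r}–{v!r}")


def node_degree(graph: nx.Graph) -> tuple[dict[str, int], dict[int, int]]:
    """Per-node degree and the degree distribution (k → node count)."""
    _require_simple(graph)
    deg = dict(graph.degree())
    dist: dict[int, int] = defaultdict(int)
    for k in deg.values():
        dist[k] += 1
    return deg, dict(dist)


def topological_coefficient(graph: nx.Graph) -> dict[str, float]:
    """Neighbour-sharing tendency per node.

    T(n) = mean_m J(n, m) / k(n) over all nodes m ≠ n sharing at least one
    neighbour with n, where J(n, m) is the number of shared neighbours
    plus one if n and m are adjacent. Nodes with degree <= 1 are assigned
    0 (and are excluded from fits by the non-positive drop rule).
    """
    _require_simple(graph)
    nbrs = {n: set(graph[n]) for n in graph}
    out: dict[str, float] = {}
    for n in graph:
        k = graph.degree(n)
        if k <= 1:
            out[n] = 0.0
            continue
        js = []
        for m in graph:
            if m == n:
                continue
            shared = len(nbrs[n] & nbrs[m])
            if shared == 0:
                continue
            js.append(shared + (1 if graph.has_edge(n, m) else 0))
        out[n] = float(np.mean(js)) / k if js else 0.0
    return out


def closeness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Component-local closeness: reachable count over summed distances
    (the reciprocal mean shortest-path distance); isolated nodes get 0."""
    _require_simple(graph)
    return nx.closeness_centrality(graph, wf_improved=False)


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Exact Brandes betweenness, endpoints excluded, normalized by the
    (V−1)(V−2)/2 node pairs."""
    _require_simple(graph)
    return nx.betweenness_centrality(graph, normalized=True)


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y = a·x^b by OLS on (log10 x, log10 y); R² in log space.

    Points with non-positive x or y are dropped (with fewer than 3 usable
    points the fit is refused). A constant-y series has zero residuals by
    construction and reports slope 0, R² = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x > 0) & (y > 0)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValidationError(f"power-law fit needs >= 3 positive points, got {len(x)}")
    lx, ly = np.log10(x), np.log10(y)
    b, la = np.polyfit(lx, ly, 1)
    resid = ly - (la + b * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(a=float(10**la), b=float(b), r_squared=float(r2), n_points=len(x))


def _per_degree_mean(deg: dict[str, int], values: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    acc: dict[int, list[float]] = defaultdict(list)
    for n, k in deg.items():
        acc[k].append(values[n])
    ks = sorted(acc)
    return np.array(ks, float), np.array([np.mean(acc[k]) for k in ks])


def _per_node(deg: dict[str, int], values: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    nodes = sorted(deg)
    return (
        np.array([deg[n] for n in nodes], float),
        np.array([values[n] for n in nodes], float),
    )


def fitness_report(graph: nx.Graph, mode: str = "per_node") -> TopologyReport:
    """Compute the four metric series on ``graph`` and fit power laws.

    The degree panel fits the degree distribution P(k) vs k; the other
    three fit metric-vs-degree series built per ``mode`` (``per_node``
    scatter or ``per_degree`` means). Zero-valued entries (k <= 1
    topological coefficients, non-mediating betweenness) drop out before
    the log transform. Series that end up with fewer than 3 usable points
    are recorded in ``errors`` rather than fitted.
    """
    if mode not in ("per_node", "per_degree"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    _require_simple(graph)
    if all("rna_class" in graph.nodes[n] for n in graph):
        check_tripartite(graph)

    deg, dist = node_degree(graph)
    tc = topological_coefficient(graph)
    clo = closeness_centrality(graph)
    bet = betweenness_centrality(graph)

    node_metrics = {
        n: {
            "degree": float(deg[n]),
            "topological_coefficient": tc[n],
            "closeness": clo[n],
            "betweenness": bet[n],
        }
        for n in graph
    }

    ks = sorted(dist)
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "degree": (np.array(ks, float), np.array([dist[k] for k in ks], float))
    }
    builder = _per_node if mode == "per_node" else _per_degree_mean
    for name, values in (
        ("topological_coefficient", tc),
        ("closeness", clo),
        ("betweenness", bet),
    ):
        series[name] = builder(deg, values)

    fits: dict[str, PowerLawFit] = {}
    errors: dict[str, str] = {}
    for name, (x, y) in series.items():
        try:
            fits[name] = fit_power_law(x, y)
        except ValidationError as exc:
            errors[name] = str(exc)
    return TopologyReport(
        node_metrics=node_metrics, series=series, fits=fits, errors=errors, mode=mode
    )
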