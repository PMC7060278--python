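"""Pathway-derived gene-gene networks and their topological characterization.

Pathways (SIF-style directed edge lists with node-type labels) are merged
into one directed simple graph, chemical-compound nodes are dropped, the
main (weakly) connected component is extracted, and the global topology
panel is computed: degrees, clustering, betweenness, shortest-path census,
and log-log power-law fits of the degree distribution and of C(k).

Conventions (documented, configurable where noted):

* "connected component" means *weakly* connected on the directed graph;
* clustering coefficients and neighbor counts are computed on the
  underlying undirected simple graph;
* betweenness is exact, unnormalized, on the directed graph;
* diameter / path census / characteristic path length are directed;
* the degree-distribution fit is an ordinary least-squares line through
  the raw (log10 k, log10 count) points, no binning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

GENE = "gene"
COMPOUND = "compound"

__all__ = [
    "Pathway",
    "PathwayCollection",
    "GeneNetwork",
    "FitResult",
    "TopologySummary",
    "MainComponentResult",
    "build_network",
    "main_component",
    "node_metrics",
    "topology_summary",
    "powerlaw_fit",
    "round_percent",
    "is_scale_free",
    "SCALE_FREE_R2_THRESHOLD",
]

#: minimum log-log degree-fit R^2 for a network to classify as scale-free
SCALE_FREE_R2_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Pathway:
    """One pathway: typed nodes plus directed labelled edges among them."""

    pathway_id: str
    name: str = ""
    #: node id -> node type ("gene" or "compound")
    nodes: dict[str, str] = field(default_factory=dict)
    #: (source, interaction label, target)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        for src, _label, dst in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                missing = src if src not in self.nodes else dst
                raise FormatError(
                    f"pathway {self.pathway_id!r}: edge endpoint {missing!r} "
                    "has no node-type label"
                )

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, t in self.nodes.items() if t != COMPOUND}


@dataclass
class PathwayCollection:
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)

    def subset(self, ids) -> "PathwayCollection":
        ids = set(ids)
        return PathwayCollection({k: v for k, v in self.pathways.items() if k in ids})

    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for pw in self:
            out |= pw.gene_nodes
        return out


class GeneNetwork:
    """A directed simple graph of typed nodes.

    Thin wrapper around :class:`networkx.DiGraph` that enforces the
    simple-graph invariants (no self-loops, no duplicate directed edges)
    and carries node-type labels.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(cls, edges, node_types: dict[str, str] | None = None) -> "GeneNetwork":
        g = nx.DiGraph()
        for edge in edges:
            if len(edge) == 3:
                src, label, dst = edge
            else:
                src, dst = edge
                label = "interacts"
            if src == dst:
                continue
            g.add_edge(src, dst, interaction=label)
        for n in g.nodes:
            g.nodes[n]["node_type"] = GENE
        if node_types:
            for n, t in node_types.items():
                if n in g.nodes:
                    g.nodes[n]["node_type"] = t
                else:
                    g.add_node(n, node_type=t)
        return cls(g)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, str]]:
        return [
            (u, d.get("interaction", "interacts"), v)
            for u, v, d in self.graph.edges(data=True)
        ]

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node].get("node_type", GENE)

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(reciprocal=False)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.graph.copy())


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """A log-log least-squares power-law fit y ~ a * x^gamma."""

    gamma: float
    r: float
    r_squared: float
    n_points: int
    valid: bool = True


@dataclass(frozen=True)
class MainComponentResult:
    network: GeneNetwork
    n_total: int
    n_retained: int
    percent_retained: float


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    mean_clustering_coefficient: float
    n_connected_components: int
    diameter: int
    n_shortest_paths: int
    percent_shortest_paths: float
    characteristic_path_length: float
    avg_neighbors: float
    degree_fit_in: FitResult
    degree_fit_out: FitResult
    ck_fit: FitResult

    def as_rows(self) -> list[tuple[str, object]]:
        """Key-value rows mirroring the global topology panel."""
        rows: list[tuple[str, object]] = [
            ("n_nodes", self.n_nodes),
            ("n_edges", self.n_edges),
            ("clustering_coefficient", self.mean_clustering_coefficient),
            ("connected_components", self.n_connected_components),
            ("network_diameter", self.diameter),
            ("shortest_paths", self.n_shortest_paths),
            ("shortest_paths_percent", self.percent_shortest_paths),
            ("characteristic_path_length", self.characteristic_path_length),
            ("avg_neighbors", self.avg_neighbors),
        ]
        for tag, fit in (
            ("in_degree", self.degree_fit_in),
            ("out_degree", self.degree_fit_out),
            ("ck", self.ck_fit),
        ):
            rows += [
                (f"{tag}_gamma", fit.gamma),
                (f"{tag}_R", fit.r),
                (f"{tag}_R2", fit.r_squared),
            ]
        return rows


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def round_percent(part: int, whole: int, ndigits: int = 1) -> float:
    """Percent of ``part`` in ``whole``, rounded half-up to ``ndigits``."""
    if whole == 0:
        return 0.0
    pct = Decimal(part) / Decimal(whole) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def build_network(pathways: PathwayCollection, drop_compounds: bool = True) -> GeneNetwork:
    """Merge all pathway graphs into one directed simple gene-gene graph.

    Duplicate directed edges across pathways collapse to one; when
    ``drop_compounds`` is set, compound-typed nodes and all their incident
    edges are removed.
    """
    g = nx.DiGraph()
    node_types: dict[str, str] = {}
    for pw in pathways:
        pw.validate()
        for node, ntype in pw.nodes.items():
            prev = node_types.setdefault(node, ntype)
            if prev != ntype:
                raise FormatError(
                    f"node {node!r} has conflicting types {prev!r}/{ntype!r} "
                    "across pathways"
                )
            g.add_node(node)
        for src, label, dst in pw.edges:
            if src != dst:
                g.add_edge(src, dst, interaction=label)
    for n, t in node_types.items():
        g.nodes[n]["node_type"] = t
    if drop_compounds:
        compounds = [n for n, t in node_types.items() if t == COMPOUND]
        if compounds:
            logger.info("dropping %d compound nodes", len(compounds))
        g.remove_nodes_from(compounds)
    return GeneNetwork(g)


def main_component(net: GeneNetwork) -> MainComponentResult:
    """Extract the largest weakly connected component.

    The retained fraction is reported as a percent rounded half-up to one
    decimal place.
    """
    n_total = net.n_nodes
    if n_total == 0:
        logger.warning("main_component called on an empty network")
        return MainComponentResult(GeneNetwork(), 0, 0, 0.0)
    biggest = max(nx.weakly_connected_components(net.graph), key=lambda c: (len(c), sorted(c)[0]))
    sub = GeneNetwork(net.graph.subgraph(biggest).copy())
    pct = round_percent(len(biggest), n_total)
    logger.info("main component retains %d/%d nodes (%.1f%%)", len(biggest), n_total, pct)
    return MainComponentResult(sub, n_total, len(biggest), pct)


def node_metrics(net: GeneNetwork) -> pd.DataFrame:
    """Per-node centrality table.

    Degrees on the directed graph; clustering coefficient and neighbor
    count on the underlying undirected simple graph; betweenness exact and
    unnormalized on the directed graph.
    """
    g = net.graph
    und = net.undirected()
    nodes = list(g.nodes)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(und)
    df = pd.DataFrame(
        {
            "in_degree": [g.in_degree(n) for n in nodes],
            "out_degree": [g.out_degree(n) for n in nodes],
            "total_degree": [g.in_degree(n) + g.out_degree(n) for n in nodes],
            "neighbor_count": [und.degree(n) for n in nodes],
            "clustering_coefficient": [clustering[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    return df


def powerlaw_fit(points) -> FitResult:
    """Least-squares line through (log10 x, log10 y).

    ``gamma`` is the slope, ``r`` the Pearson correlation of the log-log
    points, ``r_squared`` its square. Points with non-positive coordinates
    must be excluded by the caller; fewer than 3 usable points yields an
    invalid result rather than an exception.
    """
    pts = [(float(x), float(y)) for x, y in points if x > 0 and y > 0]
    n = len(pts)
    if n < 3:
        return FitResult(math.nan, math.nan, math.nan, n, valid=False)
    lx = np.log10([p[0] for p in pts])
    ly = np.log10([p[1] for p in pts])
    if np.ptp(lx) == 0:  # vertical stack: slope undefined
        return FitResult(math.nan, math.nan, math.nan, n, valid=False)
    if np.ptp(ly) == 0:  # constant y: flat line, zero correlation
        return FitResult(0.0, 0.0, 0.0, n, valid=True)
    res = stats.linregress(lx, ly)
    return FitResult(float(res.slope), float(res.rvalue), float(res.rvalue**2), n, valid=True)


def is_scale_free(fit: FitResult, r2_min: float = SCALE_FREE_R2_THRESHOLD) -> bool:
    """Classify a degree-distribution fit: decaying power law with good R^2."""
    return fit.valid and fit.gamma < 0 and fit.r_squared >= r2_min


def degree_distribution_fit(degrees) -> FitResult:
    """Power-law fit of raw (degree, count) frequency points, degree >= 1."""
    return _degree_fit(degrees)


def _degree_fit(degrees) -> FitResult:
    values, counts = np.unique(np.asarray(list(degrees), dtype=int), return_counts=True)
    pts = [(int(k), int(c)) for k, c in zip(values, counts) if k >= 1]
    return powerlaw_fit(pts)


def _ck_fit(metrics: pd.DataFrame) -> FitResult:
    """C(k): mean clustering among nodes of total degree k (mean > 0 only)."""
    grouped = metrics.groupby("total_degree")["clustering_coefficient"].mean()
    pts = [(int(k), float(c)) for k, c in grouped.items() if k >= 1 and c > 0]
    return powerlaw_fit(pts)


def topology_summary(net: GeneNetwork, metrics: pd.DataFrame | None = None) -> TopologySummary:
    """Global topology panel of the directed network."""
    if net.n_nodes == 0:
        raise InputError("topology_summary requires a nonempty network")
    g = net.graph
    if metrics is None:
        metrics = node_metrics(net)

    n = net.n_nodes
    reachable = 0
    total_len = 0
    diameter = 0
    for _source, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                reachable += 1
                total_len += dist
                if dist > diameter:
                    diameter = dist
    ordered_pairs = n * (n - 1)
    pct = round_percent(reachable, ordered_pairs) if ordered_pairs else 0.0
    cpl = total_len / reachable if reachable else math.nan

    return TopologySummary(
        n_nodes=n,
        n_edges=net.n_edges,
        mean_clustering_coefficient=float(metrics["clustering_coefficient"].mean()),
        n_connected_components=nx.number_weakly_connected_components(g),
        diameter=diameter,
        n_shortest_paths=reachable,
        percent_shortest_paths=pct,
        characteristic_path_length=cpl,
        avg_neighbors=float(metrics["neighbor_count"].mean()),
        degree_fit_in=_degree_fit(metrics["in_degree"]),
        degree_fit_out=_degree_fit(metrics["out_degree"]),
        ck_fit=_ck_fit(metrics),
    )
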