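"""Hub, bottleneck and KDE local-hub detection, and evidence integration.

Hubs are nodes whose degree is at least ``sd_multiplier`` population
standard deviations above the network mean. Bottlenecks are the top-k
nodes by betweenness (ties broken by total degree, then gene id). Local
hubs are hubs falling in a dense region of a 2-D Gaussian kernel-density
estimate over node-metric space; the feature pair and density quantile are
an explicit reconstruction — the original analysis does not state them —
and are therefore configuration, not fixed rules.

The integration stage combines the three topological gene sets with the
differential-expression table into one per-gene evidence table whose
``evidence_class`` concatenates the held flags in fixed order
(bottleneck, hub, DEG, KDE, exclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "HubRule",
    "KDEConfig",
    "ControllerResult",
    "find_hubs",
    "find_bottlenecks",
    "find_local_hubs",
    "integrate",
    "evidence_class",
]

_FLAG_ORDER = [
    ("is_bottleneck", "bottleneck"),
    ("is_hub", "hub"),
    ("is_deg", "DEG"),
    ("is_local_hub", "KDE"),
    ("is_exclusive", "exclusive"),
]


@dataclass(frozen=True)
class HubRule:
    sd_multiplier: float = 1.0
    degree_kind: str = "total"  # total | in | out
    #: behavior when sd == 0 (regular graph): empty set or all nodes
    degenerate_all: bool = False

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ConfigurationError("sd_multiplier must be positive")
        if self.degree_kind not in {"total", "in", "out"}:
            raise ConfigurationError(f"unknown degree_kind {self.degree_kind!r}")


@dataclass(frozen=True)
class KDEConfig:
    features: tuple[str, str] = ("log1p_total_degree", "clustering_coefficient")
    bandwidth_rule: str | float = "scott"  # scott | silverman | fixed float
    density_quantile: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.density_quantile < 1:
            raise ConfigurationError("density_quantile must lie in (0, 1)")


def find_hubs(metrics: pd.DataFrame, rule: HubRule = HubRule()) -> frozenset[str]:
    """Nodes with degree >= mean + sd_multiplier * population sd.

    With sd == 0 (regular graph) no node is strictly above the mean, so
    the hub set is empty unless ``rule.degenerate_all`` asks for all nodes.
    """
    if len(metrics) == 0:
        raise InputError("find_hubs requires a nonempty metrics table")
    col = {"total": "total_degree", "in": "in_degree", "out": "out_degree"}[rule.degree_kind]
    deg = metrics[col].to_numpy(dtype=float)
    sd = float(deg.std(ddof=0))
    if sd == 0.0:
        return frozenset(metrics.index) if rule.degenerate_all else frozenset()
    threshold = deg.mean() + rule.sd_multiplier * sd
    hubs = frozenset(metrics.index[deg >= threshold])
    logger.info("hubs: %d/%d nodes at degree >= %.3f", len(hubs), len(metrics), threshold)
    return hubs


def find_bottlenecks(metrics: pd.DataFrame, k: int = 200) -> frozenset[str]:
    """The k nodes with highest betweenness.

    Ties break by higher total degree, then lexicographic gene id; if the
    network has fewer than k nodes all of them are returned with a warning.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    if len(metrics) < k:
        logger.warning("only %d nodes for top-%d bottleneck request", len(metrics), k)
        return frozenset(metrics.index)
    # mergesort is stable, so pre-sorting by id makes the id tie-break explicit
    ranked = metrics.sort_index().sort_values(
        ["betweenness", "total_degree"], ascending=[False, False], kind="mergesort"
    )
    return frozenset(ranked.index[:k])


def _feature_matrix(metrics: pd.DataFrame, features) -> np.ndarray:
    cols = []
    for feat in features:
        if feat.startswith("log1p_"):
            cols.append(np.log1p(metrics[feat[len("log1p_"):]].to_numpy(dtype=float)))
        else:
            cols.append(metrics[feat].to_numpy(dtype=float))
    return np.vstack(cols)


def find_local_hubs(
    hubs,
    metrics: pd.DataFrame,
    cfg: KDEConfig = KDEConfig(),
) -> frozenset[str]:
    """Hubs lying in the dense region of a KDE over node-metric space.

    A Gaussian product-kernel density is estimated over the hub nodes'
    2-feature points; local hubs are hubs whose density is at or above the
    ``density_quantile`` quantile of hub densities. Degenerate geometries
    (all points coincident, or a constant feature) fall back gracefully:
    constant dimensions are dropped, and fully coincident points make
    every hub a local hub (uniform density).
    """
    hubs = sorted(hubs)
    if len(hubs) < 3:
        logger.warning("KDE needs >= 3 hubs, got %d; returning empty set", len(hubs))
        return frozenset()
    sub = metrics.loc[hubs]
    x = _feature_matrix(sub, cfg.features)
    # drop constant dimensions; KDE covariance would be singular
    keep = [i for i in range(x.shape[0]) if np.ptp(x[i]) > 0]
    if not keep:
        return frozenset(hubs)
    x = x[keep]
    bw = cfg.bandwidth_rule
    try:
        kde = stats.gaussian_kde(x, bw_method=bw)
    except np.linalg.LinAlgError:
        # perfectly correlated features: project onto principal components
        centered = x - x.mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        rank = int(np.sum(s > 1e-12 * s.max()))
        if rank == 0:
            return frozenset(hubs)
        proj = (u[:, :rank].T @ centered)
        kde = stats.gaussian_kde(proj, bw_method=bw)
        x = proj
    density = kde(x)
    threshold = np.quantile(density, cfg.density_quantile)
    out = frozenset(h for h, d in zip(hubs, density) if d >= threshold)
    logger.info("local hubs: %d/%d hubs at density >= quantile %.2f", len(out), len(hubs), cfg.density_quantile)
    return out


def evidence_class(flags: dict[str, bool]) -> str:
    parts = [label for key, label in _FLAG_ORDER if flags.get(key, False)]
    return "-".join(parts) if parts else "none"


@dataclass(frozen=True)
class ControllerResult:
    table: pd.DataFrame
    #: sizes of each pairwise / triple evidence intersection
    intersections: dict[str, int]


def integrate(
    degs: pd.DataFrame,
    hubs,
    bottlenecks,
    local_hubs,
) -> ControllerResult:
    """Combine topological and expression evidence into one table.

    One row per gene appearing in any evidence set; the returned summary
    counts every pairwise and triple intersection of
    {hub, bottleneck, DEG, local hub}.
    """
    hubs = frozenset(hubs)
    bottlenecks = frozenset(bottlenecks)
    local_hubs = frozenset(local_hubs)
    if not local_hubs <= hubs:
        raise InputError("local hubs must be a subset of hubs")
    deg_rows = degs[degs["is_deg"].astype(bool)]
    deg_set = frozenset(deg_rows["gene_id"])
    exclusive = frozenset(deg_rows.loc[deg_rows["is_exclusive"].astype(bool), "gene_id"])

    universe = sorted(hubs | bottlenecks | local_hubs | deg_set)
    records = []
    for gene in universe:
        flags = {
            "is_hub": gene in hubs,
            "is_bottleneck": gene in bottlenecks,
            "is_local_hub": gene in local_hubs,
            "is_deg": gene in deg_set,
            "is_exclusive": gene in exclusive,
        }
        records.append({"gene_id": gene, **flags, "evidence_class": evidence_class(flags)})
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "is_hub",
            "is_bottleneck",
            "is_local_hub",
            "is_deg",
            "is_exclusive",
            "evidence_class",
        ],
    )
    inter = {
        "hub&bottleneck": len(hubs & bottlenecks),
        "hub&deg": len(hubs & deg_set),
        "bottleneck&deg": len(bottlenecks & deg_set),
        "hub&kde": len(hubs & local_hubs),
        "hub&bottleneck&deg": len(hubs & bottlenecks & deg_set),
        "hub&bottleneck&kde": len(hubs & bottlenecks & local_hubs),
        "hub&deg&kde": len(hubs & deg_set & local_hubs),
        "hub&bottleneck&deg&kde": len(hubs & bottlenecks & deg_set & local_hubs),
    }
    return ControllerResult(table=table, intersections=inter)
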