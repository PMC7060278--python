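"""Over-representation analysis of gene lists against gene-set collections.

One exact-test kernel (the hypergeometric upper tail, identical to the
one-sided Fisher exact test on the induced 2x2 table) serves both
significance regimes used downstream: a strict GO-style cut (q <= 0.01)
and a pathway-style cut (q <= 0.05). Multiplicity adjustment defaults to
Benjamini-Hochberg and is configurable.

Graph-aware GO weighting (elim/weight-style algorithms) is deliberately
not implemented; this is "classic" over-representation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str = ""
    category: str = ""
    members: frozenset[str] = field(default_factory=frozenset)


@dataclass
class GeneSetCollection:
    """Gene sets restricted to a common universe.

    Members outside the universe are dropped at construction time with a
    logged count, so every downstream contingency table is consistent.
    """

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    def __init__(self, sets, universe):
        self.universe = frozenset(universe)
        clipped: dict[str, GeneSet] = {}
        n_dropped = 0
        for gs in (sets.values() if isinstance(sets, dict) else sets):
            kept = frozenset(gs.members) & self.universe
            n_dropped += len(gs.members) - len(kept)
            clipped[gs.set_id] = GeneSet(gs.set_id, gs.name, gs.category, kept)
        if n_dropped:
            logger.info("dropped %d set members outside the universe", n_dropped)
        self.sets = clipped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed in a sample of ``n`` from a universe of ``N``
    containing ``K`` successes. Computed with scipy's log-stable survival
    function; identical to the one-sided Fisher exact p-value of the
    corresponding 2x2 table.
    """
    for label, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise InputError(f"{label} must be a nonnegative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < K:
        raise InputError(f"violated N >= K ({N} < {K})")
    if N < n:
        raise InputError(f"violated N >= n ({N} < {n})")
    if k > min(K, n):
        raise InputError(f"violated k <= min(K, n) ({k} > {min(K, n)})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment; output order matches input order.

    ``method``: ``bh`` (Benjamini-Hochberg step-up, default), ``bonferroni``,
    or ``none``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(np.isnan(p))):
        raise InputError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method != "bh":
        raise InputError(f"unknown adjustment method {method!r}")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query,
    collection: GeneSetCollection,
    q_threshold: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Test every set of the collection for over-representation of ``query``.

    Returns one record per set with the contingency counts (k, K, n, N),
    raw p, adjusted q and an ``enriched`` flag (q <= q_threshold), sorted
    by (q, p, set_id).
    """
    if not collection.universe:
        raise InputError("enrichment requires a nonempty universe")
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.info("dropped %d query genes outside the universe", len(outside))
    query &= collection.universe

    N = len(collection.universe)
    n = len(query)
    records = []
    for gs in collection:
        K = len(gs.members)
        k = len(gs.members & query)
        records.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "category": gs.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_tail(k, K, n, N),
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=["set_id", "name", "category", "k", "K", "n", "N", "p_value"],
    )
    df["q_value"] = bh_adjust(df["p_value"], method=method) if len(df) else []
    df["enriched"] = df["q_value"] <= q_threshold if len(df) else []
    df = df.sort_values(["q_value", "p_value", "set_id"], kind="mergesort")
    return df.reset_index(drop=True)
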