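"""Expression filtering, Venn classification, and DEG calling.

Implements the filtering funnel: define the expressed loci per condition,
partition genes into common / condition-specific / excluded, run a simple
two-sample stand-in differential test on log2(FPKM + pseudocount), and
call DEGs at the q <= 0.05, |log2FC| >= 1 thresholds (both configurable,
boundary values retained).

The stand-in test is an equal-variance two-sample t-test; it replaces the
original count-model tooling, whose internals are out of scope here. Genes
whose raw mean is zero in exactly one condition carry an infinite-fold-
change *flag* (never a sentinel float) and are always called DEGs of the
expressing condition.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import ConfigurationError, DesignError, GeneLookupError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "VennPartition",
    "is_expressed",
    "venn_partition",
    "simple_de_test",
    "call_degs",
    "DE_COLUMNS",
    "DEG_COLUMNS",
]

#: stable column orders for the differential tables
DE_COLUMNS = ["gene_id", "mean_a", "mean_b", "log2fc", "inf_fold_change", "p_value", "q_value"]
DEG_COLUMNS = DE_COLUMNS + ["is_deg", "direction", "is_exclusive", "exclusive_condition"]


@dataclass
class ExpressionStudy:
    """Gene x sample FPKM-scale abundance matrix with a two-condition design.

    ``values`` is indexed by gene id; columns are sample ids. ``design``
    maps each sample id to its (condition, replicate) labels.
    """

    values: pd.DataFrame
    design: pd.DataFrame  # index: sample id; columns: condition, replicate
    conditions: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise DesignError("a study needs exactly two distinct conditions")
        if list(self.values.columns) != list(self.design.index):
            raise InputError("sample columns do not match the design table")
        if (np.asarray(self.values) < 0).any():
            raise InputError("abundances must be nonnegative")
        for cond in self.conditions:
            if self.n_replicates(cond) < 2:
                raise DesignError(f"condition {cond!r} has fewer than 2 replicates")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise GeneLookupError(f"unknown condition {condition!r}")
        return list(self.design.index[self.design["condition"] == condition])

    def n_replicates(self, condition: str) -> int:
        if condition not in self.conditions:
            raise GeneLookupError(f"unknown condition {condition!r}")
        return int((self.design["condition"] == condition).sum())

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint classification of the gene universe by expression status."""

    common: frozenset[str]
    specific_a: frozenset[str]
    specific_b: frozenset[str]
    excluded: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "specific_a": len(self.specific_a),
            "specific_b": len(self.specific_b),
            "excluded": len(self.excluded),
        }


def _required_replicates(n_replicates: int, min_replicate_fraction: float) -> int:
    if not 0 < min_replicate_fraction <= 1:
        raise ConfigurationError(
            f"min_replicate_fraction must lie in (0, 1], got {min_replicate_fraction}"
        )
    return math.ceil(min_replicate_fraction * n_replicates)


def is_expressed(
    study: ExpressionStudy,
    gene: str,
    condition: str,
    min_fpkm: float = 0.1,
    min_replicate_fraction: float = 1.0,
) -> bool:
    """True iff the gene exceeds ``min_fpkm`` in enough replicates.

    "Enough" is ``ceil(min_replicate_fraction * n_replicates)``; the
    comparison is strict (value > min_fpkm).
    """
    if gene not in study.values.index:
        raise GeneLookupError(f"unknown gene {gene!r}")
    vals = study.condition_values(condition).loc[gene]
    need = _required_replicates(len(vals), min_replicate_fraction)
    return int((vals > min_fpkm).sum()) >= need


def venn_partition(
    study: ExpressionStudy,
    min_fpkm: float = 0.1,
    min_replicate_fraction: float = 1.0,
) -> VennPartition:
    """Partition all genes into common / a-only / b-only / excluded."""
    cond_a, cond_b = study.conditions
    flags = {}
    for cond in study.conditions:
        vals = study.condition_values(cond)
        need = _required_replicates(vals.shape[1], min_replicate_fraction)
        flags[cond] = (vals > min_fpkm).sum(axis=1) >= need
    in_a, in_b = flags[cond_a], flags[cond_b]
    genes = study.values.index
    part = VennPartition(
        common=frozenset(genes[in_a & in_b]),
        specific_a=frozenset(genes[in_a & ~in_b]),
        specific_b=frozenset(genes[~in_a & in_b]),
        excluded=frozenset(genes[~in_a & ~in_b]),
    )
    logger.info(
        "expression partition: common=%d specific_a=%d specific_b=%d excluded=%d",
        *part.sizes().values(),
    )
    return part


def simple_de_test(study: ExpressionStudy, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene equal-variance two-sample t-test on log2(FPKM + pseudocount).

    Returns a table with columns ``DE_COLUMNS``. ``log2fc`` is
    log2((mean_b + pc) / (mean_a + pc)); ``inf_fold_change`` flags genes
    where exactly one raw condition mean is zero. q-values are
    Benjamini-Hochberg over all genes. Degenerate zero-variance genes get
    p = 1 when the group means agree and p = 0 otherwise.
    """
    cond_a, cond_b = study.conditions
    a = study.condition_values(cond_a).to_numpy(dtype=float)
    b = study.condition_values(cond_b).to_numpy(dtype=float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's precision-loss warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: t is 0/0; decide by the mean difference
    diff = la.mean(axis=1) - lb.mean(axis=1)
    bad = ~np.isfinite(p)
    p[bad & (np.abs(diff) <= 1e-12)] = 1.0
    p[bad & (np.abs(diff) > 1e-12)] = 0.0
    p = np.clip(p, 0.0, 1.0)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    if pseudocount > 0:
        log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(mean_b / mean_a)
        log2fc[(mean_a == 0) & (mean_b == 0)] = 0.0
    inf_flag = ((mean_a == 0) & (mean_b > 0)) | ((mean_b == 0) & (mean_a > 0))
    log2fc = np.where(np.isfinite(log2fc), log2fc, 0.0)

    return pd.DataFrame(
        {
            "gene_id": study.genes,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "inf_fold_change": inf_flag,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        columns=DE_COLUMNS,
    )


def call_degs(det: pd.DataFrame, q_max: float = 0.05, fc_min: float = 1.0) -> pd.DataFrame:
    """Flag DEGs at q <= q_max and (|log2fc| >= fc_min or infinite fold change).

    Boundary values are retained (<= / >= exactly as printed). Exclusive
    genes — infinite-flagged, expressed in one condition only — are always
    DEGs of the owning condition regardless of q.
    """
    if not 0 < q_max <= 1:
        raise ConfigurationError(f"q_max must lie in (0, 1], got {q_max}")
    if fc_min < 0:
        raise ConfigurationError(f"fc_min must be nonnegative, got {fc_min}")
    out = det.copy()
    inf_flag = out["inf_fold_change"].astype(bool)
    passes = (out["q_value"] <= q_max) & ((out["log2fc"].abs() >= fc_min) | inf_flag)
    out["is_deg"] = passes | inf_flag
    up_in_b = np.where(inf_flag, out["mean_a"] == 0, out["log2fc"] > 0)
    out["direction"] = np.where(up_in_b, "up_in_b", "up_in_a")
    out["is_exclusive"] = inf_flag
    out["exclusive_condition"] = np.where(
        inf_flag, np.where(out["mean_a"] == 0, "b", "a"), ""
    )
    n_up_a = int((out["is_deg"] & (out["direction"] == "up_in_a")).sum())
    n_up_b = int((out["is_deg"] & (out["direction"] == "up_in_b")).sum())
    logger.info("DEGs: %d up_in_a + %d up_in_b = %d", n_up_a, n_up_b, n_up_a + n_up_b)
    return out[DEG_COLUMNS]
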