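"""Readers and writers for the pipeline's text formats.

Formats: expression TSV (gene_id + one column per <condition>_<replicate>
sample), GMT gene sets, per-pathway SIF edge lists with a node-type TSV,
Cuffdiff-style ``gene_exp.diff`` differential tables, GraphML, and the
plain TSV outputs of every stage. All readers round-trip losslessly with
the matching writer on the in-memory data model.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .deg import DEG_COLUMNS, DE_COLUMNS, ExpressionStudy, VennPartition
from .enrichment import GeneSet, GeneSetCollection
from .errors import ParseError
from .network import GENE, GeneNetwork, Pathway, PathwayCollection, TopologySummary

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_sif", "write_sif", "read_pathway_dir", "write_pathway_dir",
    "read_diff", "write_de_table", "write_deg_table",
    "write_venn", "write_network_sif", "write_network_graphml",
    "write_topology", "write_controllers",
]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def write_expression(study: ExpressionStudy, path) -> None:
    study.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path, conditions: tuple[str, str] | None = None) -> ExpressionStudy:
    """Read an expression TSV whose sample columns are <condition>_<replicate>."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    design_rows = []
    for col in df.columns:
        cond, _, rep = col.rpartition("_")
        if not cond or not rep.isdigit():
            raise ParseError(f"sample column {col!r} is not <condition>_<replicate>", str(path))
        design_rows.append((col, cond, int(rep)))
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")
    if conditions is None:
        seen = list(dict.fromkeys(design["condition"]))
        if len(seen) != 2:
            raise ParseError(
                f"expected exactly 2 conditions, found {len(seen)}: {seen}", str(path)
            )
        conditions = (seen[0], seen[1])
    return ExpressionStudy(df, design, conditions)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, universe=None, category: str = "") -> GeneSetCollection:
    """Read a GMT file (set-id <tab> description <tab> members...).

    When ``universe`` is None it defaults to the union of all members.
    Sets with zero members are retained with a warning.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("GMT line needs at least id and description", str(path), lineno)
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                logger.warning("GMT set %r has 0 members (%s:%d)", fields[0], path, lineno)
            sets.append(GeneSet(fields[0], fields[1], category, members))
    if universe is None:
        universe = frozenset().union(*(s.members for s in sets)) if sets else frozenset()
    return GeneSetCollection(sets, universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name or gs.set_id, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# SIF pathways
# ---------------------------------------------------------------------------

def read_sif(path, node_types: dict[str, str] | None = None, pathway_id: str | None = None) -> Pathway:
    """Read one SIF file (source <tab> interaction <tab> target per line)."""
    path = Path(path)
    pid = pathway_id or path.stem
    edges: list[tuple[str, str, str]] = []
    nodes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # isolated node
                nodes.setdefault(fields[0], GENE)
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"SIF line has {len(fields)} fields, expected 1 or 3", str(path), lineno
                )
            src, label, dst = fields
            edges.append((src, label, dst))
            nodes.setdefault(src, GENE)
            nodes.setdefault(dst, GENE)
    if node_types:
        for n in nodes:
            if n in node_types:
                nodes[n] = node_types[n]
    pw = Pathway(pid, name=pid, nodes=nodes, edges=edges)
    pw.validate()
    return pw


def write_sif(pathway: Pathway, path) -> None:
    connected = {e[0] for e in pathway.edges} | {e[2] for e in pathway.edges}
    with open(path, "w") as fh:
        for src, label, dst in pathway.edges:
            fh.write(f"{src}\t{label}\t{dst}\n")
        for node in sorted(set(pathway.nodes) - connected):
            fh.write(f"{node}\n")


def _read_node_types(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"node_id", "node_type"} <= set(df.columns):
        raise ParseError("node-type table needs node_id and node_type columns", str(path))
    return dict(zip(df["node_id"], df["node_type"]))


def read_pathway_dir(directory) -> PathwayCollection:
    """Read a directory of ``<pathway>.sif`` files plus ``node_types.tsv``."""
    directory = Path(directory)
    types_path = directory / "node_types.tsv"
    node_types = _read_node_types(types_path) if types_path.exists() else {}
    pathways: dict[str, Pathway] = {}
    for sif in sorted(directory.glob("*.sif")):
        pw = read_sif(sif, node_types=node_types)
        pathways[pw.pathway_id] = pw
    return PathwayCollection(pathways)


def write_pathway_dir(collection: PathwayCollection, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_types: dict[str, str] = {}
    for pw in collection:
        write_sif(pw, directory / f"{pw.pathway_id}.sif")
        node_types.update(pw.nodes)
    with open(directory / "node_types.tsv", "w") as fh:
        fh.write("node_id\tnode_type\n")
        for node in sorted(node_types):
            fh.write(f"{node}\t{node_types[node]}\n")


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

_DIFF_REQUIRED = {"value_1", "value_2", "log2(fold_change)", "p_value", "q_value"}


def read_diff(path) -> pd.DataFrame:
    """Read a Cuffdiff ``gene_exp.diff``-dialect table into a DE table.

    Required columns: an id column (``gene`` preferred, else ``test_id``),
    ``value_1``, ``value_2``, ``log2(fold_change)``, ``p_value``,
    ``q_value``. Extra columns are tolerated with a warning. ``inf`` /
    ``-inf`` fold changes become the infinite-fold-change flag.
    """
    df = pd.read_csv(path, sep="\t")
    missing = _DIFF_REQUIRED - set(df.columns)
    if missing:
        raise ParseError(f"diff table missing columns: {sorted(missing)}", str(path))
    id_col = "gene" if "gene" in df.columns else "test_id"
    if id_col not in df.columns:
        raise ParseError("diff table needs a 'gene' or 'test_id' column", str(path))
    known = _DIFF_REQUIRED | {"test_id", "gene", "gene_id", "locus", "sample_1", "sample_2", "status", "significant"}
    extras = set(df.columns) - known
    if extras:
        logger.warning("ignoring %d unknown diff columns: %s", len(extras), sorted(extras))
    lfc = pd.to_numeric(df["log2(fold_change)"], errors="coerce")
    mean_a = df["value_1"].astype(float)
    mean_b = df["value_2"].astype(float)
    inf_flag = ((mean_a == 0) & (mean_b > 0)) | ((mean_b == 0) & (mean_a > 0))
    lfc = lfc.where(np.isfinite(lfc), 0.0).fillna(0.0)
    out = pd.DataFrame(
        {
            "gene_id": df[id_col].astype(str),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": lfc,
            "inf_fold_change": inf_flag,
            "p_value": df["p_value"].astype(float),
            "q_value": df["q_value"].astype(float),
        },
        columns=DE_COLUMNS,
    )
    return out


def write_de_table(det: pd.DataFrame, path) -> None:
    det[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs[DEG_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def write_venn(part: VennPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for label, genes in (
            ("common", part.common),
            ("specific_a", part.specific_a),
            ("specific_b", part.specific_b),
            ("excluded", part.excluded),
        ):
            for g in sorted(genes):
                fh.write(f"{g}\t{label}\n")


def write_network_sif(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for src, label, dst in sorted(net.edges()):
            fh.write(f"{src}\t{label}\t{dst}\n")
        connected = {u for u, _, _ in net.edges()} | {v for _, _, v in net.edges()}
        for node in sorted(set(net.nodes()) - connected):
            fh.write(f"{node}\n")


def write_network_graphml(net: GeneNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_topology(summary: TopologySummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\n")
        for key, value in summary.as_rows():
            if isinstance(value, float) and math.isnan(value):
                value = "NA"
            fh.write(f"{key}\t{value}\n")


def write_controllers(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
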