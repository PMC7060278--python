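"""End-to-end orchestration: configuration, stage chaining, run manifest.

A run takes either a synthetic-study configuration or real input paths
(expression TSV or a Cuffdiff-style diff table, a pathway SIF directory,
optionally a GMT), chains the stages

    expression filter -> Venn partition -> DE test -> DEG call
    -> over-representation -> network build -> main component
    -> topology panel -> hubs / bottlenecks / local hubs -> integration

and writes every stage output plus a manifest of per-stage record counts.
Identical configuration and seed produce byte-identical outputs (wall-clock
fields aside). Every filtering stage logs its in/out counts so the full
funnel is reconstructable from the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import controllers as ctrl
from . import deg as degmod
from . import enrichment as enr
from . import io as pio
from . import network as netmod
from . import synthetic as synth
from .errors import ConfigurationError, EmtNetCtrlError, InputError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "deg_counts", "load_config"]

try:
    _VERSION = version("emtnetctrl")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; exactly one input source must be given."""

    # synthetic source
    synth_config: synth.SynthConfig | None = None
    n_controllers: int = 8
    n_pathways: int = 12
    pathway_mean_size: float = 25.0
    # real-input source
    expression_path: str | None = None
    diff_path: str | None = None
    pathway_dir: str | None = None
    gmt_path: str | None = None
    # thresholds
    min_fpkm: float = 0.1
    min_replicate_fraction: float = 1.0
    q_max: float = 0.05
    fc_min: float = 1.0
    go_q: float = 0.01
    kegg_q: float = 0.05
    bottleneck_k: int = 200
    hub_rule: ctrl.HubRule = field(default_factory=ctrl.HubRule)
    kde: ctrl.KDEConfig = field(default_factory=ctrl.KDEConfig)
    # run plumbing
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_synth = self.synth_config is not None
        has_real = self.expression_path is not None or self.diff_path is not None
        if has_synth == has_real:
            raise ConfigurationError(
                "exactly one of a synthetic configuration or real input paths "
                "must be provided"
            )
        if has_real and self.pathway_dir is None:
            raise ConfigurationError("real-input runs need a pathway SIF directory")


@dataclass
class RunManifest:
    config: dict
    counts: dict
    tool_version: str
    wall_clock: dict

    def validate(self) -> None:
        c = self.counts
        checks = [
            ("mc_nodes <= network_nodes", c["mc_nodes"] <= c["network_nodes"]),
            ("degs_total <= genes_in", c["degs_total"] <= c["genes_in"]),
            ("expressed <= genes_in", c["expressed"] <= c["genes_in"]),
            ("hubs <= mc_nodes", c["hubs"] <= c["mc_nodes"]),
            ("bottlenecks <= mc_nodes", c["bottlenecks"] <= c["mc_nodes"]),
            ("local_hubs <= hubs", c["local_hubs"] <= c["hubs"]),
            ("deg sum consistent", c["degs_total"] == c["degs_up_a"] + c["degs_up_b"]),
        ]
        for name, ok in checks:
            if not ok:
                raise InputError(f"manifest consistency violated: {name}")

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "counts": self.counts,
            "tool_version": self.tool_version,
            "wall_clock": self.wall_clock,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def deg_counts(degs: pd.DataFrame) -> dict[str, int]:
    """Per-direction and combined DEG counts; total is the direction sum."""
    flagged = degs[degs["is_deg"].astype(bool)]
    up_a = int((flagged["direction"] == "up_in_a").sum())
    up_b = int((flagged["direction"] == "up_in_b").sum())
    return {"up_in_a": up_a, "up_in_b": up_b, "total": up_a + up_b}


def _config_echo(cfg: PipelineConfig) -> dict:
    def unpack(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (frozenset, set, tuple)):
            return sorted(str(x) for x in obj) if isinstance(obj, (frozenset, set)) else list(obj)
        return obj

    return unpack(cfg)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage and write all outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clock: dict[str, float] = {}
    counts: dict[str, object] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                clock[name] = round(time.perf_counter() - self_.t0, 4)
                if exc_type is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    if issubclass(exc_type, (EmtNetCtrlError, OSError)):
                        return False  # propagate with its type intact
                    raise EmtNetCtrlError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, clock[name])

        return _Timer()

    # ----------------------------------------------------------------- input
    study = det = truth = None
    with stage("input"):
        if cfg.synth_config is not None:
            sc = dataclasses.replace(cfg.synth_config, seed=cfg.seed)
            bundle = synth.generate_study(
                sc,
                n_controllers=cfg.n_controllers,
                n_pathways=cfg.n_pathways,
                pathway_mean_size=cfg.pathway_mean_size,
            )
            study, pathways, truth = bundle.study, bundle.pathways, bundle.truth
            pio.write_expression(study, out / "expression.tsv")
            pio.write_pathway_dir(pathways, out / "pathways")
        else:
            if cfg.expression_path is not None:
                study = pio.read_expression(cfg.expression_path)
            if cfg.diff_path is not None:
                det = pio.read_diff(cfg.diff_path)
            pathways = pio.read_pathway_dir(cfg.pathway_dir)
        counts["pathways_in"] = len(pathways)

    # ------------------------------------------------------------------- deg
    with stage("deg"):
        if study is not None:
            counts["genes_in"] = len(study.genes)
            part = degmod.venn_partition(study, cfg.min_fpkm, cfg.min_replicate_fraction)
            pio.write_venn(part, out / "venn.tsv")
            expressed = part.common | part.specific_a | part.specific_b
            if det is None:
                det = degmod.simple_de_test(study)
        else:
            counts["genes_in"] = len(det)
            part = None
            expressed = frozenset(det["gene_id"])
        counts["expressed"] = len(expressed)
        degs = degmod.call_degs(det, q_max=cfg.q_max, fc_min=cfg.fc_min)
        pio.write_deg_table(degs, out / "degs.tsv")
        dc = deg_counts(degs)
        counts["degs_up_a"], counts["degs_up_b"] = dc["up_in_a"], dc["up_in_b"]
        counts["degs_total"] = dc["total"]

    # ------------------------------------------------------------ enrichment
    with stage("enrichment"):
        deg_set = set(degs.loc[degs["is_deg"].astype(bool), "gene_id"])
        pathway_sets = [
            enr.GeneSet(pw.pathway_id, pw.name, "pathway", frozenset(pw.gene_nodes))
            for pw in pathways
        ]
        universe = frozenset(expressed) | frozenset().union(
            *(s.members for s in pathway_sets), deg_set
        )
        collection = enr.GeneSetCollection(pathway_sets, universe)
        table = enr.enrich(deg_set, collection, q_threshold=cfg.kegg_q)
        table.to_csv(out / "enrichment_pathways.tsv", sep="\t", index=False)
        enriched_ids = list(table.loc[table["enriched"], "set_id"])
        counts["enriched_pathways"] = len(enriched_ids)
        if cfg.gmt_path is not None:
            go_coll = pio.read_gmt(cfg.gmt_path, universe=universe)
            go_table = enr.enrich(deg_set, go_coll, q_threshold=cfg.go_q)
            go_table.to_csv(out / "enrichment_go.tsv", sep="\t", index=False)
            counts["enriched_go_terms"] = int(go_table["enriched"].sum())
        if not enriched_ids:
            logger.warning("no pathway passed q <= %g; building network from all pathways", cfg.kegg_q)
            enriched_ids = [pw.pathway_id for pw in pathways]
        network_source = pathways.subset(enriched_ids)

    # --------------------------------------------------------------- network
    with stage("network"):
        net = netmod.build_network(network_source, drop_compounds=True)
        counts["network_nodes"], counts["network_edges"] = net.n_nodes, net.n_edges
        mc = netmod.main_component(net)
        counts["mc_nodes"] = mc.n_retained
        counts["mc_percent"] = mc.percent_retained
        metrics = netmod.node_metrics(mc.network)
        summary = netmod.topology_summary(mc.network, metrics)
        pio.write_network_sif(mc.network, out / "network.sif")
        pio.write_network_graphml(mc.network, out / "network.graphml")
        pio.write_topology(summary, out / "topology.tsv")

    # ----------------------------------------------------------- controllers
    with stage("controllers"):
        hubs = ctrl.find_hubs(metrics, cfg.hub_rule)
        bottlenecks = ctrl.find_bottlenecks(metrics, cfg.bottleneck_k)
        local_hubs = ctrl.find_local_hubs(hubs, metrics, cfg.kde)
        result = ctrl.integrate(degs, hubs, bottlenecks, local_hubs)
        pio.write_controllers(result.table, out / "controllers.tsv")
        counts["hubs"] = len(hubs)
        counts["bottlenecks"] = len(bottlenecks)
        counts["local_hubs"] = len(local_hubs)
        t = result.table
        counts["controller_candidates"] = int(
            (t["is_hub"] & t["is_bottleneck"] & t["is_deg"]).sum()
        )
        counts["intersections"] = result.intersections
        if truth is not None:
            counts["planted_controllers"] = len(truth.controller_genes)

    manifest = RunManifest(
        config=_config_echo(cfg),
        counts=counts,
        tool_version=_VERSION,
        wall_clock=clock,
    )
    manifest.validate()
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus CLI overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    overrides = overrides or {}

    kwargs: dict = {}
    if "synthetic" in raw:
        synth_keys = {f.name for f in dataclasses.fields(synth.SynthConfig)}
        sblock = dict(raw["synthetic"] or {})
        for key in ("n_controllers", "n_pathways", "pathway_mean_size"):
            if key in sblock:
                kwargs[key] = sblock.pop(key)
        unknown = set(sblock) - synth_keys
        if unknown:
            raise ConfigurationError(f"unknown synthetic keys: {sorted(unknown)}")
        kwargs["synth_config"] = synth.SynthConfig(**sblock)
    inputs = raw.get("inputs") or {}
    mapping = {
        "expression": "expression_path",
        "diff": "diff_path",
        "pathways": "pathway_dir",
        "gmt": "gmt_path",
    }
    for key, attr in mapping.items():
        if key in inputs:
            kwargs[attr] = inputs[key]
    thr = raw.get("thresholds") or {}
    for key in (
        "min_fpkm", "min_replicate_fraction", "q_max", "fc_min",
        "go_q", "kegg_q", "bottleneck_k",
    ):
        if key in thr:
            kwargs[key] = thr[key]
    if "hub_sd_multiplier" in thr:
        kwargs["hub_rule"] = ctrl.HubRule(sd_multiplier=thr["hub_sd_multiplier"])
    if "kde" in raw and raw["kde"]:
        kde_raw = dict(raw["kde"])
        if "features" in kde_raw:
            kde_raw["features"] = tuple(kde_raw["features"])
        kwargs["kde"] = ctrl.KDEConfig(**kde_raw)
    for key in ("seed", "out_dir", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    kwargs.update(overrides)
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
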