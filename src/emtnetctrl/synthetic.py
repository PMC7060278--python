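"""Seeded generators for every input the pipeline consumes.

The study's RNA-seq matrices are not public, so this module emulates their
statistical structure: two-condition negative-binomial expression with
planted fold changes, condition-exclusive genes (hard zeros on the other
side), pathway collections whose merged graph is heavy-tailed, and planted
"controller" genes — differentially expressed genes wired as preferential-
attachment targets so they acquire high degree and betweenness and can be
recovered by the downstream hub/bottleneck/DEG integration.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .deg import ExpressionStudy
from .errors import ConfigurationError, InputError
from .network import COMPOUND, GENE, GeneNetwork, Pathway, PathwayCollection

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_expression",
    "generate_pathway_collection",
    "generate_controller_pathways",
    "generate_reference_network",
    "generate_study",
    "SyntheticStudy",
    "reference_config",
]

CONDITION_A = "condA"
CONDITION_B = "condB"


def reference_config(seed: int = 0) -> "SynthConfig":
    """The documented reference configuration for end-to-end recovery runs.

    Strong planted effects (|log2FC| = 2.5, dispersion 0.1, 5 replicates)
    so that planted controller genes are recoverable by the full
    hub/bottleneck/DEG integration with high precision and recall.
    """
    return SynthConfig(
        n_genes=1000,
        n_replicates=5,
        de_fraction=0.1,
        effect_log2fc=2.5,
        dispersion=0.1,
        exclusive_per_condition=5,
        baseline_mean=50.0,
        seed=seed,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic two-condition expression study."""

    n_genes: int
    n_replicates: int = 3
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    exclusive_per_condition: int = 0
    dispersion: float = 0.1
    baseline_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be nonnegative")
        if self.exclusive_per_condition < 0:
            raise ConfigurationError("exclusive_per_condition must be nonnegative")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        claimed = self.de_fraction * self.n_genes + 2 * self.exclusive_per_condition
        if claimed > self.n_genes:
            raise ConfigurationError(
                "violated bound de_fraction*n_genes + 2*exclusive_per_condition "
                f"<= n_genes ({claimed:g} > {self.n_genes})"
            )

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_genes)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic study."""

    #: gene id -> planted direction ("up_in_a" | "up_in_b")
    de_direction: dict[str, str]
    #: condition label -> genes expressed exclusively there
    exclusive_genes: dict[str, frozenset[str]]
    controller_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.de_direction)

    def validate(self) -> None:
        excl_sets = list(self.exclusive_genes.values())
        if len(excl_sets) == 2 and excl_sets[0] & excl_sets[1]:
            raise InputError("exclusive sets of the two conditions overlap")
        all_excl = frozenset().union(*excl_sets) if excl_sets else frozenset()
        if not self.controller_genes <= (self.de_genes | all_excl):
            raise InputError("controller genes must be planted DE or exclusive genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2, elementwise."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def generate_expression(config: SynthConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate a two-condition FPKM-scale study with planted effects.

    DE genes get condition-B mean = condition-A mean * 2^(+-effect_log2fc)
    with random sign; exclusive genes are hard zeros in every replicate of
    the other condition. Per-gene baselines are lognormal around
    ``baseline_mean``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=0.6, size=n)
    order = rng.permutation(n)
    n_de = config.n_de
    de_idx = order[:n_de]
    excl_a_idx = order[n_de : n_de + config.exclusive_per_condition]
    excl_b_idx = order[
        n_de + config.exclusive_per_condition : n_de + 2 * config.exclusive_per_condition
    ]

    mean_a = base.copy()
    mean_b = base.copy()
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mean_b[de_idx] = mean_a[de_idx] * 2.0 ** (signs * config.effect_log2fc)
    # exclusive genes: solidly expressed on their own side, hard zero on the other
    floor = config.baseline_mean
    mean_a[excl_a_idx] = np.maximum(mean_a[excl_a_idx], floor)
    mean_b[excl_a_idx] = 0.0
    mean_b[excl_b_idx] = np.maximum(base[excl_b_idx], floor)
    mean_a[excl_b_idx] = 0.0

    reps = config.n_replicates
    cols_a = [f"{CONDITION_A}_{r + 1}" for r in range(reps)]
    cols_b = [f"{CONDITION_B}_{r + 1}" for r in range(reps)]
    mat = np.empty((n, 2 * reps))
    for j in range(reps):
        mat[:, j] = _nb_draw(rng, mean_a, config.dispersion)
        mat[:, reps + j] = _nb_draw(rng, mean_b, config.dispersion)
    mat[excl_a_idx, reps:] = 0.0
    mat[excl_b_idx, :reps] = 0.0
    # guarantee exclusives are detectable on their own side
    mat[excl_a_idx, :reps] = np.maximum(mat[excl_a_idx, :reps], 1.0)
    mat[excl_b_idx, reps:] = np.maximum(mat[excl_b_idx, reps:], 1.0)

    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=cols_a + cols_b)
    design = pd.DataFrame(
        {
            "condition": [CONDITION_A] * reps + [CONDITION_B] * reps,
            "replicate": list(range(1, reps + 1)) * 2,
        },
        index=pd.Index(cols_a + cols_b, name="sample_id"),
    )
    study = ExpressionStudy(values, design, (CONDITION_A, CONDITION_B))

    truth = GroundTruth(
        de_direction={
            genes[i]: ("up_in_b" if s > 0 else "up_in_a")
            for i, s in zip(de_idx, signs)
        },
        exclusive_genes={
            CONDITION_A: frozenset(genes[i] for i in excl_a_idx),
            CONDITION_B: frozenset(genes[i] for i in excl_b_idx),
        },
    )
    truth.validate()
    return study, truth


def _wire_members(rng: np.random.Generator, members: list[str], extra_edge_prob: float = 0.15):
    """Random connected wiring: a random tree plus a few chords."""
    edges: list[tuple[str, str, str]] = []
    for i in range(1, len(members)):
        j = int(rng.integers(0, i))
        a, b = members[j], members[i]
        if rng.random() < 0.5:
            a, b = b, a
        edges.append((a, "interacts", b))
    n_extra = rng.binomial(max(len(members) - 1, 0), extra_edge_prob)
    for _ in range(n_extra):
        i, j = rng.choice(len(members), size=2, replace=False)
        edges.append((members[int(i)], "interacts", members[int(j)]))
    return edges


def generate_pathway_collection(
    n_pathways: int,
    genes,
    mean_size: float,
    compound_fraction: float = 0.0,
    seed: int = 0,
) -> PathwayCollection:
    """Random pathways over a gene universe.

    Each pathway samples roughly ``mean_size`` members (Poisson, floor 3),
    a ``compound_fraction`` of which are compound-typed nodes drawn from a
    shared compound pool; edges connect only the pathway's own members.
    """
    genes = list(genes)
    if not genes:
        raise InputError("gene universe must be nonempty")
    if n_pathways <= 0:
        raise InputError("n_pathways must be positive")
    if not 0 <= compound_fraction <= 1:
        raise InputError("compound_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    compound_pool = [f"cpd{i:04d}" for i in range(max(20, int(mean_size)))]
    pathways: dict[str, Pathway] = {}
    for pi in range(n_pathways):
        size = max(3, int(rng.poisson(mean_size)))
        size = min(size, len(genes) + len(compound_pool))
        n_cpd = int(round(compound_fraction * size))
        n_gene = min(size - n_cpd, len(genes))
        members = [genes[i] for i in rng.choice(len(genes), size=n_gene, replace=False)]
        cpds = [
            compound_pool[i]
            for i in rng.choice(len(compound_pool), size=min(n_cpd, len(compound_pool)), replace=False)
        ]
        nodes = {g: GENE for g in members} | {c: COMPOUND for c in cpds}
        all_members = members + cpds
        edges = _wire_members(rng, all_members)
        pid = f"pw{pi:03d}"
        pathways[pid] = Pathway(pid, name=f"synthetic pathway {pi}", nodes=nodes, edges=edges)
    return PathwayCollection(pathways)


def generate_controller_pathways(
    de_genes,
    background_genes,
    n_controllers: int,
    n_pathways: int,
    mean_size: float,
    seed: int = 0,
    attach_prob: float = 0.6,
    de_member_fraction: float = 0.3,
) -> tuple[PathwayCollection, frozenset[str]]:
    """Pathways with controller genes wired as preferential-attachment targets.

    Controllers are drawn from the planted DE genes, joined to every
    pathway, and attached to each non-controller member with probability
    ``attach_prob`` — giving them far higher degree and betweenness than
    any other differentially expressed member. A ``de_member_fraction`` of
    ordinary members are DE genes so that controller-bearing pathways are
    recoverable by over-representation testing.
    """
    de_genes = sorted(set(de_genes))
    background_genes = sorted(set(background_genes) - set(de_genes))
    if n_controllers > len(de_genes):
        raise InputError("not enough DE genes to plant the requested controllers")
    rng = np.random.default_rng(seed)
    controllers = [de_genes[i] for i in rng.choice(len(de_genes), size=n_controllers, replace=False)]
    other_de = [g for g in de_genes if g not in set(controllers)]

    pathways: dict[str, Pathway] = {}
    for pi in range(n_pathways):
        size = max(4, int(rng.poisson(mean_size)))
        n_de_members = min(int(round(de_member_fraction * size)), len(other_de))
        n_bg = min(size - n_de_members, len(background_genes))
        members = [other_de[i] for i in rng.choice(len(other_de), size=n_de_members, replace=False)]
        members += [
            background_genes[i] for i in rng.choice(len(background_genes), size=n_bg, replace=False)
        ]
        edges = _wire_members(rng, members)
        for ctrl in controllers:
            for m in members:
                if rng.random() < attach_prob:
                    edge = (ctrl, "interacts", m) if rng.random() < 0.5 else (m, "interacts", ctrl)
                    edges.append(edge)
        nodes = {g: GENE for g in members} | {c: GENE for c in controllers}
        pid = f"pw{pi:03d}"
        pathways[pid] = Pathway(pid, name=f"controller pathway {pi}", nodes=nodes, edges=edges)
    return PathwayCollection(pathways), frozenset(controllers)


def generate_reference_network(model: str, n: int, param, seed: int = 0) -> GeneNetwork:
    """Reference graphs for degree-distribution classification tests.

    ``scale_free`` grows by preferential attachment (each of the n - m
    newcomers attaches m edges, so the undirected edge count is m*(n - m));
    ``random`` draws each ordered pair independently with probability
    ``param``. Edge directions of the scale-free graph are assigned
    uniformly at random.
    """
    if n < 3:
        raise InputError("n must be at least 3")
    rng = np.random.default_rng(seed)
    if model == "scale_free":
        m = int(param)
        if m >= n:
            raise InputError(f"attachment count m={m} must be below n={n}")
        und = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**32)))
        g = nx.DiGraph()
        g.add_nodes_from(und.nodes)
        for u, v in und.edges:
            if rng.random() < 0.5:
                u, v = v, u
            g.add_edge(u, v, interaction="interacts")
    elif model == "random":
        p = float(param)
        if not 0 <= p <= 1:
            raise InputError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**32)), directed=True)
        nx.set_edge_attributes(g, "interacts", "interaction")
    else:
        raise InputError(f"unknown model {model!r}; expected 'scale_free' or 'random'")
    g = nx.relabel_nodes(g, {i: f"g{i:05d}" for i in g.nodes})
    nx.set_node_attributes(g, GENE, "node_type")
    return GeneNetwork(g)


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete synthetic input bundle for an end-to-end run."""

    study: ExpressionStudy
    pathways: PathwayCollection
    truth: GroundTruth


def generate_study(
    config: SynthConfig,
    n_controllers: int = 8,
    n_pathways: int = 12,
    pathway_mean_size: float = 25.0,
    attach_prob: float = 0.6,
) -> SyntheticStudy:
    """Expression + controller-planted pathways + ground truth, one seed."""
    study, truth = generate_expression(config)
    n_controllers = min(n_controllers, len(truth.de_genes))
    if n_controllers == 0:
        pathways = generate_pathway_collection(
            n_pathways, study.genes, pathway_mean_size, seed=config.seed + 1
        )
        controllers: frozenset[str] = frozenset()
    else:
        background = [g for g in study.genes if g not in truth.de_genes]
        pathways, controllers = generate_controller_pathways(
            truth.de_genes,
            background,
            n_controllers=n_controllers,
            n_pathways=n_pathways,
            mean_size=pathway_mean_size,
            seed=config.seed + 1,
            attach_prob=attach_prob,
        )
    truth = replace(truth, controller_genes=controllers)
    truth.validate()
    return SyntheticStudy(study=study, pathways=pathways, truth=truth)
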