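import numpy as np
import pandas as pd
import pytest

from emtnetctrl.deg import call_degs, simple_de_test
from emtnetctrl.errors import ConfigurationError, InputError
from emtnetctrl.network import COMPOUND, degree_distribution_fit, is_scale_free
from emtnetctrl.synthetic import (
    SynthConfig,
    generate_controller_pathways,
    generate_expression,
    generate_pathway_collection,
    generate_reference_network,
    generate_study,
)


class TestSynthConfig:
    def test_invalid_fraction_bound_names_it(self):
        with pytest.raises(ConfigurationError, match="de_fraction"):
            SynthConfig(n_genes=100, de_fraction=0.9, exclusive_per_condition=10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_genes": 10, "n_replicates": 0},
            {"n_genes": 10, "de_fraction": 1.5},
            {"n_genes": 10, "dispersion": 0.0},
            {"n_genes": 10, "baseline_mean": -1.0},
            {"n_genes": 10, "effect_log2fc": -0.5},
        ],
    )
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ConfigurationError):
            SynthConfig(**kwargs)


class TestGenerateExpression:
    def test_seeded_determinism(self):
        cfg = SynthConfig(n_genes=200, de_fraction=0.2, exclusive_per_condition=4, seed=7)
        s1, t1 = generate_expression(cfg)
        s2, t2 = generate_expression(cfg)
        pd.testing.assert_frame_equal(s1.values, s2.values)
        assert t1 == t2

    def test_null_config_empty_truth(self):
        cfg = SynthConfig(n_genes=100, de_fraction=0.0, exclusive_per_condition=0, seed=1)
        _, truth = generate_expression(cfg)
        assert truth.de_genes == frozenset()
        assert all(not s for s in truth.exclusive_genes.values())

    def test_shapes_and_nonnegativity(self):
        cfg = SynthConfig(n_genes=150, n_replicates=4, seed=3)
        study, _ = generate_expression(cfg)
        assert study.values.shape == (150, 8)
        assert (study.values.to_numpy() >= 0).all()

    def test_exclusive_genes_hard_zero_on_other_side(self):
        cfg = SynthConfig(n_genes=100, de_fraction=0.1, exclusive_per_condition=5, seed=11)
        study, truth = generate_expression(cfg)
        a_cols = study.samples_of("condA")
        b_cols = study.samples_of("condB")
        for g in truth.exclusive_genes["condA"]:
            assert (study.values.loc[g, b_cols] == 0).all()
            assert (study.values.loc[g, a_cols] > 0).all()
        for g in truth.exclusive_genes["condB"]:
            assert (study.values.loc[g, a_cols] == 0).all()

    def test_frozen_downstream_recall_reference_example(self):
        """Mean planted-DEG recall of the stand-in test + filter at the pinned
        config (2000 genes, |log2FC| = 2, dispersion 0.1, 3 replicates).

        The frozen value 0.055 was measured by a 20-seed Monte-Carlo oracle
        run before the build; asserted within +-0.05 thereafter.
        """
        recalls = []
        for seed in range(20):
            cfg = SynthConfig(
                n_genes=2000, de_fraction=0.1, effect_log2fc=2.0,
                dispersion=0.1, n_replicates=3, seed=seed,
            )
            study, truth = generate_expression(cfg)
            degs = call_degs(simple_de_test(study))
            called = set(degs.loc[degs["is_deg"], "gene_id"])
            recalls.append(len(called & truth.de_genes) / len(truth.de_genes))
        assert abs(np.mean(recalls) - 0.055) <= 0.05

    def test_log2_ratio_converges_to_planted_effect(self):
        cfg = SynthConfig(
            n_genes=400, de_fraction=0.3, effect_log2fc=2.0, n_replicates=50, seed=5
        )
        study, truth = generate_expression(cfg)
        ma = study.condition_values("condA").mean(axis=1)
        mb = study.condition_values("condB").mean(axis=1)
        errors = []
        for g, direction in truth.de_direction.items():
            ratio = np.log2(mb[g] / ma[g])
            planted = 2.0 if direction == "up_in_b" else -2.0
            errors.append(ratio - planted)
        assert abs(np.mean(errors)) < 0.1

    def test_ground_truth_invariants_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 80))
            excl = int(rng.integers(0, 4))
            de_max = max(0.0, (n - 2 * excl) / n)
            cfg = SynthConfig(
                n_genes=n,
                de_fraction=float(rng.uniform(0, de_max)),
                exclusive_per_condition=excl,
                seed=int(rng.integers(0, 2**31)),
            )
            _, truth = generate_expression(cfg)
            truth.validate()
            assert not (truth.exclusive_genes["condA"] & truth.exclusive_genes["condB"])


class TestGeneratePathways:
    def test_pathway_count(self):
        genes = [f"g{i}" for i in range(50)]
        coll = generate_pathway_collection(5, genes, mean_size=8, seed=0)
        assert len(coll) == 5

    def test_zero_compound_fraction(self):
        genes = [f"g{i}" for i in range(50)]
        coll = generate_pathway_collection(6, genes, mean_size=10, compound_fraction=0.0, seed=1)
        for pw in coll:
            assert COMPOUND not in set(pw.nodes.values())

    def test_compound_fraction_produces_compounds(self):
        genes = [f"g{i}" for i in range(50)]
        coll = generate_pathway_collection(4, genes, mean_size=12, compound_fraction=0.3, seed=2)
        assert any(COMPOUND in set(pw.nodes.values()) for pw in coll)

    def test_edges_connect_only_members(self):
        genes = [f"g{i}" for i in range(40)]
        coll = generate_pathway_collection(8, genes, mean_size=9, compound_fraction=0.2, seed=3)
        for pw in coll:
            for src, _, dst in pw.edges:
                assert src in pw.nodes and dst in pw.nodes

    def test_union_matches_brute_force_set_union(self):
        genes = [f"g{i}" for i in range(30)]
        coll = generate_pathway_collection(2, genes, mean_size=15, seed=4)
        pws = list(coll)
        expected = set()
        for pw in pws:  # brute-force enumeration
            for node in pw.nodes:
                if pw.nodes[node] != COMPOUND:
                    expected.add(node)
        assert coll.gene_union() == expected
        assert len(coll.gene_union()) == len(pws[0].gene_nodes | pws[1].gene_nodes)

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            generate_pathway_collection(3, [], mean_size=5, seed=0)

    def test_controller_pathways_plant_among_de_genes(self):
        de = [f"de{i}" for i in range(30)]
        bg = [f"bg{i}" for i in range(100)]
        coll, controllers = generate_controller_pathways(
            de, bg, n_controllers=5, n_pathways=6, mean_size=15, seed=9
        )
        assert len(controllers) == 5
        assert controllers <= set(de)
        for pw in coll:  # controllers joined to every pathway
            assert controllers <= set(pw.nodes)


class TestReferenceNetwork:
    def test_node_count(self):
        net = generate_reference_network("scale_free", 100, 3, seed=0)
        assert net.n_nodes == 100

    def test_scale_free_edge_count_by_construction_rule(self):
        # each of the n - m newcomers attaches m edges: m * (n - m) total
        for n, m, seed in [(100, 2, 0), (60, 3, 1), (200, 1, 2)]:
            net = generate_reference_network("scale_free", n, m, seed=seed)
            assert net.n_edges == m * (n - m)

    def test_param_bound_error(self):
        with pytest.raises(InputError):
            generate_reference_network("scale_free", 10, 10, seed=0)
        with pytest.raises(InputError):
            generate_reference_network("scale_free", 2, 1, seed=0)
        with pytest.raises(InputError):
            generate_reference_network("nonsense", 10, 1, seed=0)

    def test_scale_free_vs_random_discrimination(self):
        """20-seed Monte-Carlo: BA fits decay with high R^2, ER fits do not."""
        sf_gamma_neg = 0
        random_below_threshold = 0
        for seed in range(20):
            sf = generate_reference_network("scale_free", 500, 2, seed=seed)
            rd = generate_reference_network("random", 500, 0.05, seed=seed)
            fit_sf = degree_distribution_fit(
                [sf.graph.in_degree(v) + sf.graph.out_degree(v) for v in sf.graph]
            )
            fit_rd = degree_distribution_fit(
                [rd.graph.in_degree(v) + rd.graph.out_degree(v) for v in rd.graph]
            )
            if fit_sf.gamma < 0:
                sf_gamma_neg += 1
            if not is_scale_free(fit_rd):
                random_below_threshold += 1
        assert sf_gamma_neg == 20
        assert random_below_threshold >= 18


class TestGenerateStudy:
    def test_bundle_determinism_and_controller_containment(self):
        cfg = SynthConfig(n_genes=300, de_fraction=0.15, exclusive_per_condition=3, seed=21)
        b1 = generate_study(cfg, n_controllers=4, n_pathways=6)
        b2 = generate_study(cfg, n_controllers=4, n_pathways=6)
        pd.testing.assert_frame_equal(b1.study.values, b2.study.values)
        assert b1.truth.controller_genes == b2.truth.controller_genes
        assert len(b1.truth.controller_genes) == 4
        assert b1.truth.controller_genes <= b1.truth.de_genes
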