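import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from emtnetctrl.controllers import (
    HubRule,
    KDEConfig,
    evidence_class,
    find_bottlenecks,
    find_hubs,
    find_local_hubs,
    integrate,
)
from emtnetctrl.errors import ConfigurationError, InputError
from emtnetctrl.network import build_network, node_metrics, Pathway, PathwayCollection, GENE


def metrics_from_degrees(degrees, betweenness=None, clustering=None):
    n = len(degrees)
    return pd.DataFrame(
        {
            "in_degree": degrees,
            "out_degree": [0] * n,
            "total_degree": degrees,
            "neighbor_count": degrees,
            "clustering_coefficient": clustering if clustering is not None else [0.0] * n,
            "betweenness": betweenness if betweenness is not None else [0.0] * n,
        },
        index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene_id"),
    )


def net_from_edges(edges):
    nodes = {n for e in edges for n in e}
    pw = Pathway("p", nodes={n: GENE for n in nodes},
                 edges=[(a, "interacts", b) for a, b in edges])
    return build_network(PathwayCollection({"p": pw}))


class TestFindHubs:
    def test_regular_graph_has_no_hubs(self):
        m = metrics_from_degrees([4, 4, 4, 4])
        assert find_hubs(m) == frozenset()

    def test_degenerate_all_option(self):
        m = metrics_from_degrees([4, 4, 4, 4])
        assert find_hubs(m, HubRule(degenerate_all=True)) == frozenset(m.index)

    def test_hand_arithmetic_case(self):
        # degrees (1,1,1,1,16): mean 4, population sd 6 -> threshold 10
        m = metrics_from_degrees([1, 1, 1, 1, 16])
        assert find_hubs(m) == frozenset({"g004"})

    def test_matches_brute_force_threshold_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            degs = rng.integers(0, 30, size=int(rng.integers(3, 40))).tolist()
            m = metrics_from_degrees(degs)
            arr = np.array(degs, dtype=float)
            sd = arr.std()
            expected = (
                frozenset()
                if sd == 0
                else frozenset(m.index[i] for i, d in enumerate(degs) if d >= arr.mean() + sd)
            )
            assert find_hubs(m) == expected

    def test_hub_set_shrinks_with_multiplier(self):
        rng = np.random.default_rng(17)
        m = metrics_from_degrees(rng.integers(0, 50, size=60).tolist())
        sets = [find_hubs(m, HubRule(sd_multiplier=s)) for s in (0.5, 1.0, 1.5, 2.0)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_empty_metrics_rejected(self):
        with pytest.raises(InputError):
            find_hubs(metrics_from_degrees([]))

    def test_degree_kind_selection(self):
        m = metrics_from_degrees([1, 1, 10])
        m["out_degree"] = [10, 1, 1]
        assert find_hubs(m, HubRule(degree_kind="in")) == frozenset({"g002"})
        assert find_hubs(m, HubRule(degree_kind="out")) == frozenset({"g000"})


class TestFindBottlenecks:
    def test_directed_path_middle_node(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        m = node_metrics(net)
        assert find_bottlenecks(m, k=1) == frozenset({"b"})

    def test_k_equals_node_count_returns_all(self):
        m = metrics_from_degrees([1, 2, 3], betweenness=[0.0, 5.0, 2.0])
        assert find_bottlenecks(m, k=3) == frozenset(m.index)

    def test_fewer_nodes_than_k_warns_and_returns_all(self, caplog):
        m = metrics_from_degrees([1, 2], betweenness=[1.0, 2.0])
        assert find_bottlenecks(m, k=200) == frozenset(m.index)

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            find_bottlenecks(metrics_from_degrees([1]), k=0)

    def test_matches_oracle_betweenness_sort(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            n = int(rng.integers(6, 31))
            nodes = [f"n{i:02d}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < 0.12
            ]
            net = net_from_edges(edges) if edges else None
            if net is None or net.n_nodes < 4:
                continue
            m = node_metrics(net)
            k = max(1, net.n_nodes // 2)
            got = find_bottlenecks(m, k=k)
            bw = oracle.brute_betweenness(net.nodes(), [(u, v) for u, _, v in net.edges()])
            ranked = sorted(
                net.nodes(),
                key=lambda g: (-bw[g], -int(m.loc[g, "total_degree"]), g),
            )
            assert got == frozenset(ranked[:k])

    def test_tie_break_by_degree_then_id(self):
        m = metrics_from_degrees([5, 9, 9, 9], betweenness=[3.0, 1.0, 1.0, 1.0])
        # all of g001..g003 tie on betweenness and degree; ids break the tie
        assert find_bottlenecks(m, k=2) == frozenset({"g000", "g001"})


class TestFindLocalHubs:
    def test_identical_points_all_local_hubs(self):
        m = metrics_from_degrees([7, 7, 7, 7], clustering=[0.5] * 4)
        hubs = set(m.index)
        assert find_local_hubs(hubs, m) == frozenset(hubs)

    def test_too_few_hubs_empty(self):
        m = metrics_from_degrees([7, 8])
        assert find_local_hubs(set(m.index), m) == frozenset()

    def test_outliers_excluded_from_dense_clusters(self):
        rng = np.random.default_rng(29)
        deg = np.concatenate(
            [
                rng.normal(20, 1, size=20),  # cluster 1
                rng.normal(60, 1, size=20),  # cluster 2
                [400.0, 900.0],              # isolated outliers
            ]
        ).round().astype(int)
        clus = np.concatenate(
            [rng.normal(0.5, 0.02, 20), rng.normal(0.2, 0.02, 20), [0.95, 0.05]]
        ).clip(0, 1)
        m = metrics_from_degrees(deg.tolist(), clustering=clus.tolist())
        hubs = set(m.index)
        local = find_local_hubs(hubs, m, KDEConfig(density_quantile=0.5))
        outliers = {m.index[-2], m.index[-1]}
        assert not (local & outliers)
        assert len(local) >= 20

    def test_scale_invariance_under_affine_rescale(self):
        rng = np.random.default_rng(37)
        deg = rng.integers(5, 80, size=30).tolist()
        clus = rng.uniform(0, 1, size=30).tolist()
        m = metrics_from_degrees(deg, clustering=clus)
        hubs = set(m.index)
        cfg = KDEConfig(features=("total_degree", "clustering_coefficient"))
        base = find_local_hubs(hubs, m, cfg)
        m2 = m.copy()
        m2["total_degree"] = m2["total_degree"] * 1000.0 + 5.0
        m2["clustering_coefficient"] = m2["clustering_coefficient"] * 0.01 - 3.0
        assert find_local_hubs(hubs, m2, cfg) == base

    def test_perfectly_correlated_features_fall_back(self):
        deg = [1, 2, 3, 4, 5, 6]
        m = metrics_from_degrees(deg, clustering=[d / 10 for d in deg])
        cfg = KDEConfig(features=("total_degree", "clustering_coefficient"))
        out = find_local_hubs(set(m.index), m, cfg)
        assert isinstance(out, frozenset) and out

    def test_invalid_quantile(self):
        with pytest.raises(ConfigurationError):
            KDEConfig(density_quantile=1.0)


def deg_table(genes, exclusive=()):
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "mean_a": 1.0,
            "mean_b": 2.0,
            "log2fc": 1.5,
            "inf_fold_change": [g in exclusive for g in genes],
            "p_value": 0.001,
            "q_value": 0.01,
            "is_deg": True,
            "direction": "up_in_b",
            "is_exclusive": [g in exclusive for g in genes],
            "exclusive_condition": ["b" if g in exclusive else "" for g in genes],
        }
    )


class TestIntegrate:
    def test_all_four_evidence_flags(self):
        res = integrate(deg_table(["x"]), hubs={"x"}, bottlenecks={"x"}, local_hubs={"x"})
        row = res.table.set_index("gene_id").loc["x"]
        assert row["evidence_class"] == "bottleneck-hub-DEG-KDE"

    def test_empty_deg_table_no_deg_flags(self):
        empty = deg_table([]).iloc[0:0]
        res = integrate(empty, hubs={"a"}, bottlenecks={"b"}, local_hubs=set())
        assert not res.table["is_deg"].any()

    def test_toy_set_algebra(self):
        res = integrate(
            deg_table(["c", "d", "e"]),
            hubs={"a", "b", "c"},
            bottlenecks={"b", "c", "d"},
            local_hubs={"c"},
        )
        assert res.intersections["hub&bottleneck"] == 2  # {b, c}
        assert res.intersections["hub&bottleneck&deg"] == 1  # {c}
        t = res.table.set_index("gene_id")
        assert set(t.index) == {"a", "b", "c", "d", "e"}
        assert t.loc["c", "evidence_class"] == "bottleneck-hub-DEG-KDE"
        assert t.loc["e", "evidence_class"] == "DEG"

    def test_local_hub_must_be_hub(self):
        with pytest.raises(InputError):
            integrate(deg_table([]), hubs={"a"}, bottlenecks=set(), local_hubs={"z"})

    def test_exclusive_flag_carried(self):
        res = integrate(deg_table(["x"], exclusive={"x"}), hubs=set(), bottlenecks=set(), local_hubs=set())
        row = res.table.set_index("gene_id").loc["x"]
        assert row["evidence_class"] == "DEG-exclusive"

    def test_evidence_class_pure_function_of_flags(self):
        flags = {"is_bottleneck": True, "is_hub": False, "is_deg": True,
                 "is_local_hub": False, "is_exclusive": False}
        assert evidence_class(flags) == "bottleneck-DEG"
        assert evidence_class({}) == "none"
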