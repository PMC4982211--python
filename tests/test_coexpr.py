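import igraph as ig
import numpy as np
import pandas as pd
import pytest

from metacoman.coexpr import (
    RESIDUAL_LABEL,
    CoexprNetwork,
    build_network,
    detect_communities,
    find_hubs,
    network_tables,
)
from metacoman.io_tab import SampleMetadata
from metacoman.profiling import AbundanceProfile

N_SAMPLES = 9
SAMPLES = [f"a{i}" for i in range(N_SAMPLES)]

# three rank patterns over 9 samples, pairwise Spearman |rho| < 0.7
RANKS_1 = [1, 2, 3, 4, 5, 6, 7, 8, 9]
RANKS_2 = [2, 4, 6, 8, 1, 3, 5, 7, 9]
RANKS_3 = [5, 9, 2, 7, 4, 1, 8, 3, 6]


@pytest.fixture
def meta():
    mapping = {s: "A" for s in SAMPLES}
    mapping.update({f"b{i}": "B" for i in range(N_SAMPLES)})
    return SampleMetadata(mapping)


def profile_from_rows(rows):
    """Build a valid profile preserving each row's values exactly (scaled).

    Columns are padded to sum 1 with a ballast feature, so the listed
    features keep their within-row sample rankings untouched. Returns
    (profile, feature names without the ballast).
    """
    data = pd.DataFrame(
        {feat: vals for feat, vals in rows}, index=SAMPLES
    ).T
    data.index.name = "feature"
    data = data / (data.to_numpy().max() * (len(rows) + 1))
    data.loc["zz_ballast"] = 1.0 - data.sum(axis=0)
    return AbundanceProfile(system="KO", data=data), [feat for feat, _ in rows]


def net_from_rows(rows, meta, condition="A", **kwargs):
    prof, feats = profile_from_rows(rows)
    return build_network(prof, meta, condition, features=feats, **kwargs)


def clique_rows(prefix, n, ranks, scale=1.0):
    """n features sharing the same sample ranking (pairwise rho = 1)."""
    rows = []
    for i in range(n):
        rows.append((f"{prefix}{i}", [scale * (r + 10 * (i + 1)) for r in ranks]))
    return rows


def all_partitions(items):
    """Every set partition of ``items`` (Bell number of them)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield partition + [[first]]


def best_modularity(net):
    """Oracle: maximum weighted modularity over all node partitions."""
    index = {n: i for i, n in enumerate(net.nodes)}
    g = ig.Graph(len(net.nodes))
    g.add_edges([(index[u], index[v]) for u, v in zip(net.edges["u"], net.edges["v"])])
    g.es["weight"] = [abs(r) for r in net.edges["rho"]]
    best = -np.inf
    for partition in all_partitions(net.nodes):
        membership = [0] * len(net.nodes)
        for lab, block in enumerate(partition):
            for node in block:
                membership[index[node]] = lab
        best = max(best, g.modularity(membership, weights=g.es["weight"]))
    return best


class TestBuildNetwork:
    def test_perfect_correlation_makes_edge(self, meta):
        net = net_from_rows(
            [("f1", RANKS_1), ("f2", [r * 2 for r in RANKS_1])], meta
        )
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["rho"] == pytest.approx(1.0)

    def test_anticorrelation_also_makes_edge(self, meta):
        net = net_from_rows(
            [("f1", RANKS_1), ("f2", [10 - r for r in RANKS_1])], meta
        )
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_weak_correlation_makes_no_edge(self, meta):
        net = net_from_rows([("f1", RANKS_1), ("f2", RANKS_2)], meta)
        assert len(net.edges) == 0
        assert net.nodes == ["f1", "f2"]  # isolated nodes retained

    def test_four_or_fewer_samples_rejected(self):
        meta = SampleMetadata({f"a{i}": "A" for i in range(4)} | {"b0": "B"})
        data = pd.DataFrame(
            np.full((2, 4), 0.5), index=pd.Index(["f1", "f2"], name="feature"),
            columns=[f"a{i}" for i in range(4)],
        )
        prof = AbundanceProfile(system="KO", data=data)
        with pytest.raises(ValueError, match="more than 4 samples"):
            build_network(prof, meta, "A")

    def test_few_samples_warns(self):
        meta = SampleMetadata({f"a{i}": "A" for i in range(6)} | {"b0": "B"})
        cols = [f"a{i}" for i in range(6)]
        data = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]],
            index=pd.Index(["f1", "f2"], name="feature"),
            columns=cols,
        )
        data = data / data.sum(axis=0)
        prof = AbundanceProfile(system="KO", data=data)
        with pytest.warns(UserWarning, match="recommended"):
            build_network(prof, meta, "A")

    def test_unknown_condition_errors(self, meta):
        with pytest.raises(ValueError, match="unknown condition"):
            net_from_rows([("f1", RANKS_1), ("f2", RANKS_2)], meta, "C")

    def test_constant_feature_has_no_edges(self, meta):
        net = net_from_rows(
            [("f1", RANKS_1), ("f2", [r * 3 for r in RANKS_1]), ("fc", [1.0] * 9)], meta
        )
        assert "fc" not in set(net.edges["u"]) | set(net.edges["v"])
        assert len(net.edges) == 1

    def test_monotone_transform_invariance(self, meta, rng):
        vals = rng.random((5, 9))
        rows_a = [(f"f{i}", list(vals[i])) for i in range(5)]
        rows_b = [(f"f{i}", list(np.exp(3 * vals[i]))) for i in range(5)]
        net_a = net_from_rows(rows_a, meta, rho_threshold=0.5)
        net_b = net_from_rows(rows_b, meta, rho_threshold=0.5)
        pd.testing.assert_frame_equal(net_a.edges, net_b.edges)


class TestDetectCommunities:
    def _two_cliques(self, meta):
        rows = clique_rows("x", 3, RANKS_1) + clique_rows("y", 3, RANKS_2)
        return net_from_rows(rows, meta)

    def test_two_cliques_recovered(self, meta):
        net = detect_communities(self._two_cliques(meta))
        labels = net.community_of
        assert labels["x0"] == labels["x1"] == labels["x2"]
        assert labels["y0"] == labels["y1"] == labels["y2"]
        assert labels["x0"] != labels["y0"]
        assert RESIDUAL_LABEL not in labels.values()

    def test_modularity_attains_exhaustive_maximum(self, meta):
        net = detect_communities(self._two_cliques(meta))
        assert net.modularity() == pytest.approx(best_modularity(net))

    def test_small_communities_merged_to_residual(self, meta):
        rows = (
            clique_rows("x", 3, RANKS_1)
            + clique_rows("y", 3, RANKS_2)
            + [("iso1", list(RANKS_3)), ("iso2", [1.0] * 9)]
        )
        net = detect_communities(net_from_rows(rows, meta))
        assert net.community_of["iso1"] == RESIDUAL_LABEL
        assert net.community_of["iso2"] == RESIDUAL_LABEL
        assert net.community_of["x0"] != RESIDUAL_LABEL

    def test_residual_pools_sizes_below_three(self, meta):
        rows = (
            clique_rows("x", 5, RANKS_1)
            + clique_rows("y", 4, RANKS_2)
            + clique_rows("z", 2, RANKS_3)
            + [("iso", [1.0] * 9)]
        )
        net = detect_communities(net_from_rows(rows, meta))
        sizes = pd.Series(net.community_of).value_counts()
        assert sizes[RESIDUAL_LABEL] == 3  # the 2-clique plus the isolated node
        assert sorted(sizes[sizes.index != RESIDUAL_LABEL]) == [4, 5]

    def test_edgeless_network_is_all_residual(self, meta):
        rows = [("f1", RANKS_1), ("f2", RANKS_2), ("f3", RANKS_3)]
        net = detect_communities(net_from_rows(rows, meta))
        assert set(net.community_of.values()) == {RESIDUAL_LABEL}

    def test_partition_is_valid(self, meta):
        net = detect_communities(self._two_cliques(meta))
        assert set(net.community_of) == set(net.nodes)

    def test_modularity_beats_singletons(self, meta):
        net = detect_communities(self._two_cliques(meta))
        singles = CoexprNetwork(
            nodes=net.nodes,
            edges=net.edges,
            community_of={n: i for i, n in enumerate(net.nodes)},
        )
        assert net.modularity() >= singles.modularity()


def star_network(n_leaves):
    edges = pd.DataFrame(
        {"u": ["hub"] * n_leaves, "v": [f"l{i}" for i in range(n_leaves)], "rho": 0.9}
    )
    return CoexprNetwork(nodes=["hub"] + [f"l{i}" for i in range(n_leaves)], edges=edges)


class TestFindHubs:
    def test_star_centre_is_the_hub(self):
        # 16 nodes: ceil(0.05 * 16) = 1, so only the centre qualifies
        net = find_hubs(star_network(15))
        assert net.hubs == {"hub"}
        assert not net.hub_degenerate

    def test_regular_graph_is_degenerate(self):
        # a triangle: every node has degree 2
        edges = pd.DataFrame(
            {"u": ["a", "a", "b"], "v": ["b", "c", "c"], "rho": [0.8, 0.8, 0.8]}
        )
        net = find_hubs(CoexprNetwork(nodes=["a", "b", "c"], edges=edges))
        assert net.hubs == {"a", "b", "c"}
        assert net.hub_degenerate

    def test_top_five_percent_of_hundred_nodes(self):
        nodes = [f"n{i:03d}" for i in range(100)]
        rows = []
        for i in range(99):  # chain: interior degree 2, two high-degree anchors added
            rows.append((nodes[i], nodes[i + 1], 0.9))
        for j in range(1, 11):  # n000 gains 10 extra edges
            rows.append((nodes[0], nodes[40 + j], 0.9))
        edges = pd.DataFrame(rows, columns=["u", "v", "rho"])
        net = find_hubs(CoexprNetwork(nodes=nodes, edges=edges))
        # k = ceil(0.05 * 100) = 5 nodes at minimum
        assert len(net.hubs) >= 5
        assert "n000" in net.hubs

    def test_edgeless_network_has_no_hubs(self):
        net = find_hubs(CoexprNetwork(nodes=["a", "b"], edges=pd.DataFrame(columns=["u", "v", "rho"])))
        assert net.hubs == set()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="top_fraction"):
            find_hubs(star_network(3), top_fraction=0.0)


class TestNetworkTables:
    def test_tables_consistent(self, meta):
        rows = clique_rows("x", 3, RANKS_1) + clique_rows("y", 3, RANKS_2)
        net = find_hubs(detect_communities(net_from_rows(rows, meta)))
        node_table, edge_table = network_tables(net)
        assert list(node_table.index) == net.nodes
        assert node_table["degree"].sum() == 2 * len(edge_table)
        assert node_table["hub"].sum() == len(net.hubs)
        assert (edge_table["u"] < edge_table["v"]).all()
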