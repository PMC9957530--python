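"""Degrees, hubs, union network, differential-connectivity z-scores."""

import numpy as np
import pandas as pd
import pytest

import pcitnet as pn
from pcitnet.network import EDGE_COLUMNS, GroupNetwork


def net_from_pairs(group, pairs, genes=None):
    rows = [
        {
            "gene_a": min(a, b), "gene_b": max(a, b),
            "r": 0.99, "p_value": 0.001,
            "pcit_significant": True, "deg_anchored": True,
        }
        for a, b in pairs
    ]
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    gene_index = pd.Index(
        sorted(genes or {g for p in pairs for g in p})
    )
    return GroupNetwork(group=group, edges=edges, genes=gene_index, n_samples=8)


class TestDegrees:
    def test_empty_network_all_degrees_zero(self):
        net = net_from_pairs("FH", [], genes={"a", "b"})
        assert pn.degree_table(net).empty
        filled = pn.degree_table(net, universe=["a", "b"])
        assert (filled == 0).all()

    def test_triangle(self):
        net = net_from_pairs("FH", [("a", "b"), ("b", "c"), ("a", "c")])
        assert (pn.degree_table(net) == 2).all()

    def test_star_handshake_identity(self):
        leaves = [f"l{i}" for i in range(5)]
        net = net_from_pairs("FH", [("h", leaf) for leaf in leaves])
        deg = pn.degree_table(net)
        assert deg["h"] == 5
        assert all(deg[leaf] == 1 for leaf in leaves)
        assert deg.sum() == 2 * net.n_edges


class TestHubs:
    def test_population_sd_convention_reproduces_threshold_arithmetic(self):
        """Degrees [1,1,1,1,20]: mean 4.8, population SD 7.6, threshold
        exactly 20.0 -> the degree-20 gene is an inclusive-boundary hub."""
        deg = pd.Series({"a": 1, "b": 1, "c": 1, "d": 1, "e": 20})
        assert pn.find_hubs(deg, ddof=0) == {"e"}

    def test_sample_sd_is_stricter(self):
        """The same degrees under the sample-SD default (ddof=1) give
        threshold 4.8 + 2 * 8.497 = 21.79 and no hub."""
        deg = pd.Series({"a": 1, "b": 1, "c": 1, "d": 1, "e": 20})
        assert pn.find_hubs(deg) == set()

    def test_single_extreme_hub_among_many(self):
        deg = pd.Series({f"g{i}": 1 for i in range(100)} | {"hub": 30})
        values = deg.to_numpy(dtype=float)
        threshold = values.mean() + 2 * values.std(ddof=1)
        brute = set(deg.index[values >= threshold])
        assert pn.find_hubs(deg) == brute == {"hub"}

    def test_degenerate_equal_degrees_warns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert pn.find_hubs(pd.Series({"a": 3, "b": 3, "c": 3})) == set()

    def test_classification_set_algebra(self):
        cls = pn.classify_hubs({"a", "b", "c"}, {"b", "c", "d", "e"})
        assert cls["a"] == "FH_exclusive"
        assert cls["b"] == cls["c"] == "shared"
        assert cls["d"] == cls["e"] == "SFH_exclusive"
        # |exclusive_FH| + |shared| = |hubs_FH|
        assert (cls == "FH_exclusive").sum() + (cls == "shared").sum() == 3

    def test_disjoint_and_identical_sets(self):
        assert set(pn.classify_hubs({"a"}, {"b"}).index) == {"a", "b"}
        assert (pn.classify_hubs({"a", "b"}, {"a", "b"}) == "shared").all()


class TestUnionNetwork:
    def test_identical_networks_all_both(self):
        pairs = [("a", "b"), ("b", "c")]
        union = pn.union_network(
            net_from_pairs("FH", pairs), net_from_pairs("SFH", pairs)
        )
        assert union.n_edges == 2
        assert (union.edges["origin"] == "both").all()
        assert (union.nodes["origin"] == "both").all()

    def test_disjoint_networks_sum(self):
        union = pn.union_network(
            net_from_pairs("FH", [("a", "b")]),
            net_from_pairs("SFH", [("c", "d"), ("d", "e")]),
        )
        assert union.n_edges == 3
        assert union.n_nodes == 5
        assert set(union.edges["origin"]) == {"FH_only", "SFH_only"}

    def test_inclusion_exclusion_overlap(self):
        """12 FH edges and 9 SFH edges sharing 5 -> union of 16."""
        fh_pairs = [(f"a{i}", f"b{i}") for i in range(12)]
        sfh_pairs = fh_pairs[:5] + [(f"c{i}", f"d{i}") for i in range(4)]
        union = pn.union_network(
            net_from_pairs("FH", fh_pairs), net_from_pairs("SFH", sfh_pairs)
        )
        assert union.n_edges == 16
        assert (union.edges["origin"] == "both").sum() == 5

    def test_same_group_rejected(self):
        with pytest.raises(pn.ValidationError):
            pn.union_network(
                net_from_pairs("FH", [("a", "b")]),
                net_from_pairs("FH", [("a", "b")]),
            )


class TestDifferentialConnectivity:
    def test_identical_networks_nothing_significant(self):
        deg = pd.Series({"a": 2, "b": 1, "c": 1})
        with pytest.warns(UserWarning, match="SD\\(DK\\) = 0"):
            table = pn.differential_connectivity(deg, deg)
        assert (table["DK"] == 0).all()
        assert not table["dk_significant"].any()

    def test_hand_computed_star_vs_single_edge(self):
        """FH star (hub degree 5), SFH one edge elsewhere: K_FH = 1 for the
        hub and 0.2 for leaves; K_SFH = 1 for u, v. DK mean is exactly 0
        and SD = sqrt(3.2/7), so z = DK / 0.6761."""
        leaves = [f"l{i}" for i in range(5)]
        deg_fh = pd.Series({"h": 5} | {leaf: 1 for leaf in leaves})
        deg_sfh = pd.Series({"u": 1, "v": 1})
        table = pn.differential_connectivity(deg_fh, deg_sfh)
        assert len(table) == 8
        sd = np.sqrt(3.2 / 7)
        assert table.loc["h", "DK"] == -1.0
        assert table.loc["h", "z"] == pytest.approx(-1.0 / sd)
        for leaf in leaves:
            assert table.loc[leaf, "DK"] == pytest.approx(-0.2)
            assert table.loc[leaf, "z"] == pytest.approx(-0.2 / sd)
        for g in ("u", "v"):
            assert table.loc[g, "DK"] == 1.0
            assert table.loc[g, "z"] == pytest.approx(1.0 / sd)
        assert not table["dk_significant"].any()  # max |z| = 1.479

    def test_group_swap_antisymmetry_exact(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        deg_a = pd.Series(rng.integers(1, 20, 40), index=genes)
        deg_b = pd.Series(rng.integers(1, 20, 30), index=genes[5:35])
        t1 = pn.differential_connectivity(deg_a, deg_b)
        t2 = pn.differential_connectivity(deg_b, deg_a)
        np.testing.assert_array_equal(t1["DK"].to_numpy(), -t2["DK"].to_numpy())
        np.testing.assert_array_equal(t1["z"].to_numpy(), -t2["z"].to_numpy())
        np.testing.assert_array_equal(
            t1["dk_significant"].to_numpy(), t2["dk_significant"].to_numpy()
        )
        np.testing.assert_array_equal(
            t1["hub_FH"].to_numpy(), t2["hub_SFH"].to_numpy()
        )

    def test_z_is_standardized(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        deg_a = pd.Series(rng.integers(1, 30, 50), index=genes)
        deg_b = pd.Series(rng.integers(1, 30, 50), index=genes)
        table = pn.differential_connectivity(deg_a, deg_b)
        assert table["DK"].between(-1, 1).all()
        assert table["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_hub_class_consistency(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(60)]
        deg_a = pd.Series(rng.poisson(3, 60) + 1, index=genes)
        deg_a["g0"] = 40
        deg_b = pd.Series(rng.poisson(3, 60) + 1, index=genes)
        deg_b["g1"] = 45
        table = pn.differential_connectivity(deg_a, deg_b)
        for gene, row in table.iterrows():
            if row["hub_FH"] and row["hub_SFH"]:
                assert row["hub_class"] == "shared"
            elif row["hub_FH"]:
                assert row["hub_class"] == "FH_exclusive"
            elif row["hub_SFH"]:
                assert row["hub_class"] == "SFH_exclusive"
            else:
                assert row["hub_class"] == "none"
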