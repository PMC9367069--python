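import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import tissuegraph as tg
from tissuegraph.errors import ConfigError, ValidationError
from oracle_utils import flood_fill_clusters, hull_peel_bruteforce


def _triangle(side=1.0):
    g = nx.Graph()
    pts = {1: (0.0, 0.0), 2: (side, 0.0), 3: (side / 2, side * math.sqrt(3) / 2)}
    for n, (x, y) in pts.items():
        g.add_node(n, x=x, y=y)
    for u, v in [(1, 2), (2, 3), (1, 3)]:
        g.add_edge(u, v, distance=side)
    return g


class TestDegreeDistribution:
    def test_triangle(self):
        stats = tg.degree_distribution(_triangle())
        assert set(stats.degrees.values()) == {2}
        assert stats.mean == 2.0 and stats.std == 0.0
        assert stats.histogram == {2: 3}

    def test_star(self):
        g = nx.star_graph(4)
        stats = tg.degree_distribution(g)
        assert sorted(stats.degrees.values()) == [1, 1, 1, 1, 4]
        assert stats.mean == pytest.approx(1.6)

    def test_empty_graph_has_no_mean(self):
        stats = tg.degree_distribution(nx.Graph())
        assert stats.mean is None and stats.degrees == {}

    def test_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 1, size=(40, 2))
        df = pd.DataFrame({"label": np.arange(1, 41), "x": pts[:, 0], "y": pts[:, 1]})
        g = tg.build_geometric_graph(tg.CellTable(df, ndim=2), dmax=0.25)
        stats = tg.degree_distribution(g)
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        for k, n in enumerate(sorted(g.nodes)):
            assert stats.degrees[n] == adj[k].sum()


class TestLinkLengthDistribution:
    def test_equilateral_triangle(self):
        stats = tg.link_length_distribution(_triangle(side=1.0))
        assert stats.mean == pytest.approx(1.0) and stats.std == pytest.approx(0.0)

    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge(1, 2, distance=5.0)
        assert tg.link_length_distribution(g).mean == pytest.approx(5.0)

    def test_missing_distance_rejected(self):
        g = nx.Graph()
        g.add_edge(1, 2)
        with pytest.raises(ValidationError):
            tg.link_length_distribution(g)

    def test_lengths_match_recomputed_centroid_distances(self):
        cloud = tg.generate_spheroid_cloud(n_cells=100, radius=60, seed=5)
        g = tg.build_delaunay_graph(cloud, dmax=1e6)
        stats = tg.link_length_distribution(g)
        pos = {int(l): p for l, p in zip(cloud.labels, cloud.positions())}
        for (u, v), length in stats.lengths.items():
            assert length == pytest.approx(math.dist(pos[u], pos[v]), abs=1e-9)


class TestAssignLayers:
    def test_single_cell_is_layer_zero(self):
        g = nx.Graph()
        g.add_node(1, x=0.0, y=0.0)
        layers = tg.assign_layers(g)
        assert layers.layers == {1: 0}

    def test_circle_plus_center(self):
        g = nx.Graph()
        for k in range(8):
            ang = 2 * math.pi * k / 8
            g.add_node(k + 1, x=math.cos(ang), y=math.sin(ang))
        g.add_node(9, x=0.0, y=0.0)
        layers = tg.assign_layers(g, "hull-peeling")
        assert all(layers.layers[k] == 0 for k in range(1, 9))
        assert layers.layers[9] == 1

    def test_matches_naive_peeling_oracle(self):
        cloud = tg.generate_spheroid_cloud(n_cells=500, radius=70, seed=17, min_separation=5.0)
        g = tg.build_delaunay_graph(cloud, dmax=1e6)
        tg.attach_node_attributes(g, cloud)
        layers = tg.assign_layers(g, "hull-peeling")
        oracle = hull_peel_bruteforce(cloud.positions())
        for idx, layer in oracle.items():
            assert layers.layers[idx + 1] == layer

    def test_peeling_consistency_after_removing_layer0(self):
        cloud = tg.generate_spheroid_cloud(n_cells=300, radius=60, seed=23, min_separation=6.0)
        g = tg.build_delaunay_graph(cloud, dmax=1e6)
        tg.attach_node_attributes(g, cloud)
        layers = tg.assign_layers(g, "hull-peeling")
        inner = g.subgraph([n for n, l in layers.layers.items() if l > 0])
        relayers = tg.assign_layers(inner, "hull-peeling")
        for n, l in relayers.layers.items():
            assert l == layers.layers[n] - 1

    def test_layer_indices_are_contiguous(self):
        cloud = tg.generate_spheroid_cloud(n_cells=200, radius=50, seed=31, min_separation=5.0)
        g = tg.build_delaunay_graph(cloud, dmax=1e6)
        tg.attach_node_attributes(g, cloud)
        layers = tg.assign_layers(g, "hull-peeling")
        used = sorted(set(layers.layers.values()))
        assert used == list(range(len(used)))
        assert 0 in used

    def test_background_contact_layers(self, voronoi_tissue):
        g, _ = tg.build_contact_graph(voronoi_tissue.image)
        layers = tg.assign_layers(g, "background-contact", image=voronoi_tissue.image)
        # a tiling touches background only at the image border
        assert set(layers.layers.values()) >= {0}
        # no layer skipping: every layer-k node has a neighbor in layer k-1
        for n, l in layers.layers.items():
            if l > 0:
                assert any(layers.layers[m] == l - 1 for m in g.neighbors(n))

    def test_background_contact_needs_image(self, voronoi_tissue):
        g, _ = tg.build_contact_graph(voronoi_tissue.image)
        with pytest.raises(ConfigError):
            tg.assign_layers(g, "background-contact")

    def test_unknown_method_rejected(self):
        g = nx.Graph()
        g.add_node(1, x=0.0, y=0.0)
        with pytest.raises(ConfigError):
            tg.assign_layers(g, "onion")


class TestPerLayerProfile:
    def test_single_layer_triangle(self):
        g = _triangle(side=2.0)
        layers = tg.LayerAssignment({1: 0, 2: 0, 3: 0}, "hull-peeling")
        prof = tg.per_layer_profile(g, layers)
        assert prof.loc[0, "mean_degree"] == pytest.approx(2.0)
        assert prof.loc[0, "mean_link_length"] == pytest.approx(2.0)

    def test_disconnected_layers_are_independent(self):
        g = nx.Graph()
        g.add_node(1, x=0.0, y=0.0)
        g.add_node(2, x=1.0, y=0.0)
        g.add_edge(1, 2, distance=1.0)
        g.add_node(3, x=10.0, y=0.0)
        g.add_node(4, x=13.0, y=0.0)
        g.add_edge(3, 4, distance=3.0)
        layers = tg.LayerAssignment({1: 0, 2: 0, 3: 1, 4: 1}, "hull-peeling")
        prof = tg.per_layer_profile(g, layers)
        assert prof.loc[0, "mean_link_length"] == pytest.approx(1.0)
        assert prof.loc[1, "mean_link_length"] == pytest.approx(3.0)

    def test_matches_group_by_oracle(self):
        cloud = tg.generate_spheroid_cloud(n_cells=250, radius=60, seed=41, min_separation=6.0)
        g = tg.build_delaunay_graph(cloud, dmax=40.0)
        tg.attach_node_attributes(g, cloud)
        layers = tg.assign_layers(g, "hull-peeling")
        prof = tg.per_layer_profile(g, layers, mode="incident")
        for layer in range(layers.n_layers):
            members = {n for n, l in layers.layers.items() if l == layer}
            degs = [g.degree(n) for n in members]
            dists = [
                d["distance"]
                for u, v, d in g.edges(data=True)
                if u in members or v in members
            ]
            assert prof.loc[layer, "mean_degree"] == pytest.approx(np.mean(degs))
            if dists:
                assert prof.loc[layer, "mean_link_length"] == pytest.approx(np.mean(dists))

    def test_intra_mode_restricts_to_within_layer_edges(self):
        g = nx.Graph()
        g.add_edge(1, 2, distance=1.0)
        g.add_edge(2, 3, distance=9.0)
        layers = tg.LayerAssignment({1: 0, 2: 0, 3: 1}, "hull-peeling")
        prof = tg.per_layer_profile(g, layers, mode="intra")
        assert prof.loc[0, "mean_link_length"] == pytest.approx(1.0)
        assert math.isnan(prof.loc[1, "mean_link_length"])

    def test_uncovered_node_rejected(self):
        g = nx.Graph()
        g.add_node(1)
        with pytest.raises(ValidationError):
            tg.per_layer_profile(g, tg.LayerAssignment({}, "hull-peeling"))


class TestTypeClusters:
    def test_path_hand_count(self):
        g = nx.path_graph(4)
        types = {0: "A", 1: "A", 2: "B", 3: "A"}
        nx.set_node_attributes(g, types, "cell_type")
        report = tg.find_type_clusters(g)
        sizes = report.sizes_by_type()
        assert sizes["A"] == [2, 1] and sizes["B"] == [1]
        assert report.fraction_clustered()["A"] == pytest.approx(2 / 3)
        assert report.fraction_clustered()["B"] == 0.0

    def test_uniform_type_connected_graph_is_one_cluster(self):
        g = nx.cycle_graph(6)
        nx.set_node_attributes(g, "A", "cell_type")
        report = tg.find_type_clusters(g)
        assert report.sizes_by_type() == {"A": [6]}
        assert report.fraction_clustered() == {"A": 1.0}

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(19)
        g = nx.gnp_random_graph(60, 0.06, seed=7)
        types = {n: ("A" if rng.uniform() < 0.5 else "B") for n in g.nodes}
        nx.set_node_attributes(g, types, "cell_type")
        report = tg.find_type_clusters(g)
        oracle = flood_fill_clusters(list(g.nodes), list(g.edges), types)
        assert {(t, m) for t, m in report.clusters} == {(t, m) for t, m in oracle}

    def test_cluster_sizes_partition_type_counts(self):
        rng = np.random.default_rng(29)
        g = nx.gnp_random_graph(80, 0.05, seed=3)
        types = {n: rng.choice(["A", "B", "C"]) for n in g.nodes}
        nx.set_node_attributes(g, types, "cell_type")
        sizes = tg.find_type_clusters(g).sizes_by_type()
        from collections import Counter

        counts = Counter(types.values())
        for t, ss in sizes.items():
            assert sum(ss) == counts[t]

    def test_missing_type_rejected(self):
        g = nx.Graph()
        g.add_node(1)
        with pytest.raises(ValidationError, match="1"):
            tg.find_type_clusters(g)


class TestTypeComposition:
    @staticmethod
    def _table(types):
        df = pd.DataFrame(
            {"label": np.arange(1, len(types) + 1), "x": 0.0, "y": 0.0, "cell_type": types}
        )
        return tg.CellTable(df, ndim=2)

    def test_three_to_one(self):
        comp = tg.type_composition(self._table(["X", "X", "X", "Y"]))
        assert comp == {"X": 0.75, "Y": 0.25}

    def test_single_cell(self):
        assert tg.type_composition(self._table(["Q"])) == {"Q": 1.0}

    def test_random_assignment_matches_tally(self):
        rng = np.random.default_rng(37)
        types = list(rng.choice(["A", "B", "C"], size=1000, p=[0.6, 0.3, 0.1]))
        comp = tg.type_composition(self._table(types))
        assert sum(comp.values()) == pytest.approx(1.0)
        for t in set(types):
            assert comp[t] == pytest.approx(types.count(t) / 1000)
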