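"""Graph thresholding, centralities, parcel aggregation, laterality, contrasts."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from meghubs.connectivity import AdjacencyMatrix
from meghubs.network import (
    BinaryGraph,
    CentralityMap,
    betweenness_centrality,
    binarize_by_max_fraction,
    centrality_map,
    degree_centrality,
    eigenvector_centrality,
    group_contrast,
    laterality_index,
    parcellate_and_scale,
)
from meghubs.synthetic import ParcelAtlas


def _adj(values):
    V = np.asarray(values, dtype=float)
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 0.0)
    return AdjacencyMatrix(values=V)


def _graph_from_edges(n, edges):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return BinaryGraph(adjacency=A, threshold_fraction=0.7)


def _random_graph(rng, n, p):
    A = rng.uniform(size=(n, n)) < p
    A = np.triu(A, 1)
    A = A | A.T
    return BinaryGraph(adjacency=A, threshold_fraction=0.7)


class TestBinarize:
    def test_threshold_is_fraction_of_max(self, rng):
        V = rng.uniform(0, 0.40, (10, 10))
        V = 0.5 * (V + V.T)
        np.fill_diagonal(V, 0)
        i, j = np.unravel_index(np.argmax(V), V.shape)
        V[i, j] = V[j, i] = 0.40
        g = binarize_by_max_fraction(_adj(V), 0.7)
        expected = (V >= 0.7 * 0.40) & (V > 0)
        np.fill_diagonal(expected, False)
        assert np.array_equal(g.adjacency, expected)

    def test_uniform_positive_gives_complete_graph(self):
        V = np.full((6, 6), 0.3)
        g = binarize_by_max_fraction(_adj(V), 0.7)
        expected = ~np.eye(6, dtype=bool)
        assert np.array_equal(g.adjacency, expected)

    def test_threshold_sweep_is_nested(self, rng):
        V = rng.uniform(-0.2, 0.5, (15, 15))
        adj = _adj(V)
        e50 = binarize_by_max_fraction(adj, 0.5).adjacency
        e70 = binarize_by_max_fraction(adj, 0.7).adjacency
        e90 = binarize_by_max_fraction(adj, 0.9).adjacency
        assert np.all(e90 <= e70) and np.all(e70 <= e50)

    def test_negative_entries_never_edges(self, rng):
        V = rng.uniform(-1, 1, (8, 8))
        g = binarize_by_max_fraction(_adj(V), 0.1)
        sym = 0.5 * (V + V.T)
        assert not np.any(g.adjacency & (sym < 0))

    def test_no_positive_entries_warns_empty(self):
        V = -np.ones((4, 4))
        with pytest.warns(UserWarning):
            g = binarize_by_max_fraction(_adj(V), 0.7)
        assert not g.adjacency.any()


class TestDegree:
    def test_star_graph(self):
        g = _graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert degree_centrality(g).tolist() == [3, 1, 1, 1]

    def test_empty_graph(self):
        g = _graph_from_edges(5, [])
        assert degree_centrality(g).tolist() == [0] * 5

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            g = _random_graph(rng, 20, 0.3)
            deg = degree_centrality(g)
            brute = [sum(g.adjacency[i, j] for j in range(20)) for i in range(20)]
            assert deg.tolist() == brute


class TestEigenvectorCentrality:
    def test_complete_graph_all_ones(self):
        g = _graph_from_edges(5, list(itertools.combinations(range(5), 2)))
        assert np.allclose(eigenvector_centrality(g), 1.0)

    def test_star_leaves_at_inverse_sqrt(self):
        """K1,4: leading eigenvector ratio leaf/center = 1/√4."""
        g = _graph_from_edges(5, [(0, i) for i in range(1, 5)])
        evc = eigenvector_centrality(g)
        assert np.isclose(evc[0], 1.0)
        assert np.allclose(evc[1:], 0.5, atol=1e-10)

    def test_matches_networkx_oracle_on_random_graphs(self, rng):
        import networkx as nx

        checked = 0
        for _ in range(50):
            g = _random_graph(rng, 15, 0.25)
            if not g.adjacency.any():
                continue
            evc = eigenvector_centrality(g)
            G = nx.from_numpy_array(g.adjacency.astype(int))
            comps = sorted(nx.connected_components(G), key=len)
            largest = comps[-1]
            ref = nx.eigenvector_centrality_numpy(G.subgraph(largest))
            ref_vec = np.zeros(15)
            for k, v in ref.items():
                ref_vec[k] = abs(v)
            ref_vec /= ref_vec.max()
            assert np.allclose(evc, ref_vec, atol=1e-8)
            checked += 1
        assert checked >= 30

    def test_empty_graph_warns_zero(self):
        g = _graph_from_edges(4, [])
        with pytest.warns(UserWarning):
            assert not eigenvector_centrality(g).any()

    def test_component_tie_break_prefers_lowest_index(self):
        # two same-size components: scores live on the one containing node 0
        g = _graph_from_edges(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        evc = eigenvector_centrality(g)
        assert evc[:3].max() > 0 and not evc[3:].any()


def _betweenness_oracle(A):
    """Exhaustive shortest-path enumeration (undirected, pairs once)."""
    import networkx as nx

    n = len(A)
    G = nx.from_numpy_array(A.astype(int))
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not nx.has_path(G, s, t):
            continue
        paths = list(nx.all_shortest_paths(G, s, t))
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


class TestBetweenness:
    def test_path_graph(self):
        g = _graph_from_edges(3, [(0, 1), (1, 2)])
        assert betweenness_centrality(g).tolist() == [0.0, 1.0, 0.0]

    def test_complete_graph_all_zero(self):
        g = _graph_from_edges(5, list(itertools.combinations(range(5), 2)))
        assert np.allclose(betweenness_centrality(g), 0.0)

    def test_matches_exhaustive_path_oracle(self, rng):
        for _ in range(30):
            g = _random_graph(rng, 12, 0.3)
            ours = betweenness_centrality(g)
            oracle = _betweenness_oracle(g.adjacency)
            assert np.allclose(ours, oracle, atol=1e-10)


def _toy_atlas(labels, hemis=None, lobes=None):
    labels = np.asarray(labels)
    ids = sorted(set(labels.tolist()))
    hemis = hemis or {i: ("L" if k % 2 == 0 else "R") for k, i in enumerate(ids)}
    lobes = lobes or {i: "frontal" for i in ids}
    names = {i: f"p{i}" for i in ids}
    return ParcelAtlas(labels=labels, names=names, hemisphere=hemis, lobe=lobes)


class TestParcellation:
    def test_constant_metric_constant_parcels(self):
        atlas = _toy_atlas([0, 0, 1, 1, 2, 2])
        cm = CentralityMap(
            degree=np.full(6, 4), evc=np.full(6, 0.5), betweenness=np.full(6, 2.0)
        )
        df = parcellate_and_scale(cm, atlas)
        assert np.allclose(df["evc"], 0.5)
        assert np.allclose(df["degree"], 4)

    def test_single_voxel_parcels_identity(self, rng):
        atlas = _toy_atlas([0, 1, 2, 3])
        evc = rng.uniform(size=4)
        cm = CentralityMap(degree=np.arange(4), evc=evc, betweenness=np.zeros(4))
        df = parcellate_and_scale(cm, atlas)
        assert np.allclose(df.sort_values("parcel")["evc"].to_numpy(), evc)

    def test_matches_grouped_mean_oracle(self, rng):
        labels = rng.integers(0, 5, 60)
        atlas = _toy_atlas(labels)
        vals = rng.standard_normal(60)
        cm = CentralityMap(degree=vals, evc=vals, betweenness=vals)
        df = parcellate_and_scale(cm, atlas).set_index("parcel")
        for p in np.unique(labels):
            assert np.isclose(df.loc[p, "evc"], vals[labels == p].mean())

    def test_scaling_to_unit_max(self, rng):
        labels = rng.integers(0, 4, 40)
        atlas = _toy_atlas(labels)
        cm = CentralityMap(
            degree=rng.uniform(1, 9, 40), evc=rng.uniform(size=40),
            betweenness=rng.uniform(0, 5, 40),
        )
        df = parcellate_and_scale(cm, atlas, scale=True)
        for col in ("degree", "evc", "betweenness"):
            assert np.isclose(df[col].max(), 1.0)


class TestLaterality:
    def _parcels(self, lvals, rvals):
        rows = []
        for k, v in enumerate(lvals):
            rows.append({"parcel": k, "hemisphere": "L", "lobe": "frontal", "evc": v})
        for k, v in enumerate(rvals):
            rows.append({"parcel": 100 + k, "hemisphere": "R", "lobe": "temporal", "evc": v})
        return pd.DataFrame(rows)

    def test_pure_left_dominance(self):
        res = laterality_index(self._parcels([1.0], [0.0]))
        assert res.li == 1.0 and res.category == "left"

    def test_symmetric_is_bilateral(self):
        res = laterality_index(self._parcels([0.5], [0.5]))
        assert res.li == 0.0 and res.category == "bilateral"

    @pytest.mark.parametrize(
        "L,R,expected",
        [
            (1.30, 0.70, "left"),  # li = 0.30
            (0.70, 1.30, "right"),  # li = −0.30
            (1.25, 0.75, "bilateral"),  # li = 0.25 exactly: strict inequality
        ],
    )
    def test_cutoff_rule_strict(self, L, R, expected):
        res = laterality_index(self._parcels([L], [R]))
        assert res.category == expected

    def test_missing_hemisphere_rejected(self):
        df = self._parcels([1.0], [1.0])
        df = df[df["hemisphere"] == "L"]
        with pytest.raises(ValueError):
            laterality_index(df)


class TestGroupContrast:
    def _subject(self, rng, shift=None):
        evc = rng.uniform(0.2, 0.8, 40)
        if shift is not None:
            evc = evc + shift
        return pd.DataFrame(
            {
                "parcel": np.arange(40),
                "name": [f"p{i}" for i in range(40)],
                "hemisphere": ["L"] * 20 + ["R"] * 20,
                "lobe": ["frontal"] * 40,
                "evc": evc,
            }
        )

    def test_swapping_groups_negates_t(self, rng):
        a = [self._subject(rng) for _ in range(5)]
        b = [self._subject(rng) for _ in range(5)]
        ab = group_contrast(a, b)
        ba = group_contrast(b, a)
        assert np.allclose(ab["t"], -ba["t"], equal_nan=True)

    def test_null_family_wise_survival_rate(self):
        """Identical populations rarely produce FDR survivors."""
        rng = np.random.default_rng(11)
        n_with_survivor = 0
        for _ in range(100):
            a = [self._subject(rng) for _ in range(8)]
            b = [self._subject(rng) for _ in range(8)]
            res = group_contrast(a, b)
            n_with_survivor += int(res["fdr_significant"].any())
        assert n_with_survivor / 100 <= 0.05 + 0.03

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(21)
        shift = np.zeros(40)
        shift[:5] = 3 * 0.17  # ≈3 SD of the uniform(0.2, 0.8) subject noise
        a = [self._subject(rng, shift) for _ in range(15)]
        b = [self._subject(rng) for _ in range(15)]
        res = group_contrast(a, b)
        assert res["fdr_significant"][:5].sum() >= 4

    def test_single_subject_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_contrast([self._subject(rng)], [self._subject(rng)] * 3)


class TestHubMetricAgreement:
    def test_degree_evc_rank_agreement_on_dense_graphs(self, rng):
        """Hub rankings by degree and EVC nearly coincide on dense graphs."""
        from scipy.stats import spearmanr

        rhos = []
        for _ in range(10):
            g = _random_graph(rng, 30, 0.4)
            deg = degree_centrality(g)
            evc = eigenvector_centrality(g)
            rhos.append(spearmanr(deg, evc).statistic)
        assert np.mean(rhos) > 0.8
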