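"""Network construction, Infomap communities, closeness, scores, census."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cofuncnet.io import EffectMatrix
from cofuncnet.network import (
    CommunityPartition,
    build_network,
    census_enrichment,
    community_closeness,
    community_scores,
    community_summary,
    detect_communities,
)


def _edges(rows):
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    df["significant"] = True
    return df


class TestBuildNetwork:
    def test_weight_and_distance(self):
        net = build_network(_edges([("A", "B", 0.8)]), ["A", "B", "C"])
        assert net.graph.es[0]["weight"] == pytest.approx(0.8)
        assert net.graph.es[0]["distance"] == pytest.approx(0.2)
        assert net.n_nodes == 3  # isolate C included

    def test_negative_r_kept_as_sign(self):
        net = build_network(_edges([("A", "B", -0.8)]), ["A", "B"])
        assert net.graph.es[0]["weight"] == pytest.approx(0.8)
        assert net.graph.es[0]["sign"] == "-"

    def test_edge_conservation_and_significance_filter(self):
        df = _edges([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.3)])
        df.loc[2, "significant"] = False
        net = build_network(df, ["A", "B", "C"])
        assert net.n_edges == 2

    def test_unknown_gene_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            build_network(_edges([("A", "Z", 0.5)]), ["A", "B"])


def _clique_edges(members, r=0.9):
    rows = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            rows.append((min(a, b), max(a, b), r))
    return rows


class TestDetectCommunities:
    def test_disconnected_cliques_recovered(self):
        c1 = [f"A{i}" for i in range(6)]
        c2 = [f"B{i}" for i in range(6)]
        genes = c1 + c2 + ["LONER"]
        net = build_network(_edges(_clique_edges(c1) + _clique_edges(c2)), genes)
        part = detect_communities(net, seed=0)
        assert len({part.assignment[g] for g in c1}) == 1
        assert len({part.assignment[g] for g in c2}) == 1
        assert part.assignment[c1[0]] != part.assignment[c2[0]]
        # isolated gene forms its own singleton community
        assert part.sizes[part.assignment["LONER"]] == 1

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(0)
        blocks = [[f"C{b}_{i}" for i in range(25)] for b in range(4)]
        genes = [g for block in blocks for g in block]
        truth = {g: b for b, block in enumerate(blocks) for g in block}
        aris = []
        for seed in range(10):
            rows = []
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    p = 0.5 if truth[a] == truth[b] else 0.01
                    if rng.uniform() < p:
                        rows.append((min(a, b), max(a, b), rng.uniform(0.3, 0.9)))
            net = build_network(_edges(rows), genes)
            part = detect_communities(net, seed=seed)
            labels = [part.assignment[g] for g in genes]
            aris.append(adjusted_rand_score([truth[g] for g in genes], labels))
        assert np.mean(aris) > 0.9

    def test_seed_reproducible(self):
        genes = [f"G{i}" for i in range(30)]
        rng = np.random.default_rng(1)
        rows = [
            (genes[i], genes[j], float(rng.uniform(0.2, 0.9)))
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.uniform() < 0.2
        ]
        net = build_network(_edges(rows), genes)
        p1 = detect_communities(net, seed=7)
        p2 = detect_communities(net, seed=7)
        assert p1.assignment == p2.assignment


class TestCommunityCloseness:
    def test_path_hand_example(self):
        # a - b - c with both distances 0.5 (|r| = 0.5)
        net = build_network(_edges([("A", "B", 0.5), ("B", "C", 0.5)]), ["A", "B", "C"])
        part = CommunityPartition({"A": 0, "B": 0, "C": 0})
        close = community_closeness(net, part)
        assert close["A"] == pytest.approx(1 / 1.5)
        assert close["B"] == pytest.approx(1 / 1.0)

    def test_uniform_clique_symmetry(self):
        members = [f"G{i}" for i in range(5)]
        net = build_network(_edges(_clique_edges(members, r=0.6)), members)
        part = CommunityPartition({g: 0 for g in members})
        close = community_closeness(net, part)
        # complete k-community, uniform distance d: closeness = 1 / ((k-1) d)
        np.testing.assert_allclose(close.to_numpy(), 1 / (4 * 0.4))

    def test_matches_dijkstra_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        members = [f"G{i}" for i in range(10)]
        rows = [
            (members[i], members[j], float(rng.uniform(0.1, 0.95)))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.uniform() < 0.4
        ]
        net = build_network(_edges(rows), members)
        part = CommunityPartition({g: 0 for g in members})
        close = community_closeness(net, part)

        g = nx.Graph()
        g.add_nodes_from(members)
        for a, b, r in rows:
            g.add_edge(a, b, distance=1 - abs(r))
        for gene in members:
            lengths = nx.single_source_dijkstra_path_length(g, gene, weight="distance")
            total = sum(v for k, v in lengths.items() if k != gene)
            if total:
                assert close[gene] == pytest.approx(1 / total)
            else:
                assert np.isnan(close[gene])

    def test_isolates_reported_missing(self):
        net = build_network(_edges([("A", "B", 0.5)]), ["A", "B", "LONE"])
        part = CommunityPartition({"A": 0, "B": 0, "LONE": 1})
        close = community_closeness(net, part)
        assert np.isnan(close["LONE"])

    def test_partition_covers_all_nodes(self, called_pipeline, default_sim):
        matrix, _ = default_sim
        genes = sorted(set(called_pipeline.edges["gene_a"]) | set(called_pipeline.edges["gene_b"]))
        net = build_network(called_pipeline.edges, genes)
        part = detect_communities(net, seed=1)
        assert set(part.assignment) == set(genes)
        assert sum(part.sizes.values()) == net.n_nodes


class TestCommunitySummary:
    def test_clique_density_and_zero_inter_frequency(self):
        c1 = [f"A{i}" for i in range(4)]
        c2 = [f"B{i}" for i in range(4)]
        net = build_network(_edges(_clique_edges(c1) + _clique_edges(c2)), c1 + c2)
        part = CommunityPartition({**{g: 0 for g in c1}, **{g: 1 for g in c2}})
        per_comm, inter = community_summary(net, part, min_size=4)
        assert (per_comm["density"] == 1.0).all()
        assert inter["frequency"].iloc[0] == 0.0
        assert not inter["flagged"].iloc[0]

    def test_chromosome_flag_for_large_colocalized_community(self):
        members = [f"G{i:03d}" for i in range(120)]
        net = build_network(_edges(_clique_edges(members[:5])), members)
        part = CommunityPartition({g: 0 for g in members})
        ann = pd.DataFrame(
            {"chromosome": ["chr17"] * 72 + ["chr1"] * 48}, index=members
        )
        per_comm, _ = community_summary(net, part, annotations=ann, min_size=8)
        assert bool(per_comm["chromosome_flagged"].iloc[0])

    def test_missing_chromosome_column_warns(self):
        members = [f"G{i}" for i in range(8)]
        net = build_network(_edges(_clique_edges(members)), members)
        part = CommunityPartition({g: 0 for g in members})
        ann = pd.DataFrame({"census": ["none"] * 8}, index=members)
        with pytest.warns(UserWarning, match="chromosome"):
            community_summary(net, part, annotations=ann, min_size=8)


class TestCommunityScores:
    @staticmethod
    def _matrix_from(values, genes):
        return EffectMatrix(
            pd.DataFrame(
                values, index=genes, columns=[f"CL{j}" for j in range(np.shape(values)[1])]
            ),
            is_corrected=True,
        )

    def test_identical_profiles_are_rank_one(self):
        z = np.array([1.0, -0.5, 2.0, 0.0, -1.0, 0.5, 1.5, -2.0])
        genes = [f"G{i}" for i in range(3)]
        m = self._matrix_from(np.vstack([z, z, z]), genes)
        part = CommunityPartition({g: 0 for g in genes})
        scores = community_scores(m, part, min_size=2)[0]
        assert scores.variance_explained_pc1 == pytest.approx(1.0)
        zc = z - z.mean()
        r = np.corrcoef(scores.scores.to_numpy(), zc)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_loadings_unit_norm_and_mean_nonnegative(self, rng):
        genes = [f"G{i}" for i in range(6)]
        m = self._matrix_from(rng.standard_normal((6, 20)), genes)
        part = CommunityPartition({g: 0 for g in genes})
        cs = community_scores(m, part, min_size=2)[0]
        assert np.linalg.norm(cs.loadings) == pytest.approx(1.0)
        assert cs.loadings.mean() >= 0

    def test_mean_shift_invariance_and_sign_equivariance(self, rng):
        genes = [f"G{i}" for i in range(5)]
        X = rng.standard_normal((5, 30))
        part = CommunityPartition({g: 0 for g in genes})
        base = community_scores(self._matrix_from(X, genes), part, min_size=2)[0]
        shifted = community_scores(
            self._matrix_from(X + rng.normal(size=(5, 1)), genes), part, min_size=2
        )[0]
        np.testing.assert_allclose(
            shifted.scores.to_numpy(), base.scores.to_numpy(), atol=1e-8
        )
        flipped = community_scores(self._matrix_from(-X, genes), part, min_size=2)[0]
        np.testing.assert_allclose(
            np.abs(flipped.scores.to_numpy()), np.abs(base.scores.to_numpy()), atol=1e-8
        )

    def test_recovers_planted_factor(self, rng):
        factor = rng.standard_normal(100)
        genes = [f"G{i}" for i in range(10)]
        X = np.outer(rng.uniform(0.8, 1.2, 10), factor) + 0.3 * rng.standard_normal((10, 100))
        m = self._matrix_from(X, genes)
        part = CommunityPartition({g: 0 for g in genes})
        cs = community_scores(m, part, min_size=2)[0]
        r = np.corrcoef(cs.scores.to_numpy(), factor)[0, 1]
        assert abs(r) > 0.95

    def test_separates_planted_mutational_subgroups(self, rng):
        # two cell-line subgroups drive the module: scores must separate them
        n_cells = 60
        status = np.zeros(n_cells, dtype=bool)
        status[:25] = True
        factor = np.where(status, 2.0, 0.0) + 0.5 * rng.standard_normal(n_cells)
        genes = [f"G{i}" for i in range(8)]
        X = np.outer(np.ones(8), factor) + 1.0 * rng.standard_normal((8, n_cells))
        m = self._matrix_from(X, genes)
        part = CommunityPartition({g: 0 for g in genes})
        cs = community_scores(m, part, min_size=2)[0]
        s = cs.scores.to_numpy()
        p = stats.mannwhitneyu(s[status], s[~status], alternative="two-sided").pvalue
        assert p < 0.05


class TestCensusEnrichment:
    @staticmethod
    def _annotations(census_map):
        return pd.DataFrame({"census": pd.Series(census_map)})

    def test_binomial_tail_hand_value(self):
        # community of 10 with 3 census genes at p0 = 0.1: P(X >= 3) ~ 0.0702
        genes = {f"G{i}": 0 for i in range(10)}
        others = {f"H{i}": 1 for i in range(90)}
        part = CommunityPartition({**genes, **others})
        census = {g: "somatic" if i < 3 else "none" for i, g in enumerate(genes)}
        census.update({h: "somatic" if i < 7 else "none" for i, h in enumerate(others)})
        ann = self._annotations(census)  # 10 census genes of 100 -> p0 = 0.1
        out = census_enrichment(part, ann).set_index("community")
        assert out.loc[0, "p"] == pytest.approx(
            float(stats.binom.sf(2, 10, 0.1)), abs=1e-10
        )
        assert out.loc[0, "p"] == pytest.approx(0.0702, abs=1e-4)

    def test_zero_census_gives_p_one(self):
        part = CommunityPartition({"A": 0, "B": 0, "C": 1})
        ann = self._annotations({"A": "none", "B": "none", "C": "germline"})
        out = census_enrichment(part, ann).set_index("community")
        assert out.loc[0, "p"] == 1.0

    def test_all_census_degenerate(self):
        part = CommunityPartition({"A": 0, "B": 0})
        ann = self._annotations({"A": "both", "B": "somatic"})
        out = census_enrichment(part, ann)
        assert (out["p"] == 1.0).all()
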