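"""Variable embedding, k-means/BIC selection, index votes, hierarchical
clustering, silhouettes, and representative selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from dietcluster import (
    bic_scan,
    embed_variables,
    hierarchical_cluster,
    index_vote,
    kmeans_fit,
    select_representatives,
    selected_exposures,
    silhouette_values,
)
from dietcluster.clustering import ClusterSolution, kmeans_bic
from dietcluster.exceptions import ConfigurationError, InputError


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def planted_blocks(n=500, sizes=(3, 3, 4), rho=0.9, seed=0):
    """z-scaled variables in compound-symmetric blocks; returns (df, truth)."""
    rng = np.random.default_rng(seed)
    cols, truth = {}, {}
    for b, size in enumerate(sizes):
        t = rng.standard_normal(n)
        for j in range(size):
            name = f"v{b}_{j}"
            cols[name] = np.sqrt(rho) * t + np.sqrt(1 - rho) * rng.standard_normal(n)
            truth[name] = b
    return zscore(pd.DataFrame(cols)), pd.Series(truth)


class TestEmbedding:
    def test_perfectly_correlated_variables_coincide(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        df = zscore(pd.DataFrame({"a": x, "b": 3 * x + 7, "c": rng.standard_normal(200)}))
        emb = embed_variables(df)
        d = emb.distance_matrix()
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_uncorrelated_distance_identity(self):
        # squared distance between z-scaled columns is 2 n (1 - r)
        rng = np.random.default_rng(2)
        n = 300
        df = zscore(pd.DataFrame(rng.standard_normal((n, 6)), columns=list("abcdef")))
        emb = embed_variables(df)
        d2 = emb.distance_matrix() ** 2
        r = df.corr().to_numpy()
        expected = 2 * n * (1 - r)
        assert np.allclose(d2, expected, atol=1e-6)

    def test_distances_match_direct_column_distances(self):
        rng = np.random.default_rng(3)
        df = zscore(pd.DataFrame(rng.standard_normal((150, 10))))
        df.columns = [f"v{i}" for i in range(10)]
        emb = embed_variables(df)
        direct = cdist(df.to_numpy().T, df.to_numpy().T)
        assert np.allclose(emb.distance_matrix(), direct, rtol=1e-8, atol=1e-8)
        assert emb.coords.shape[1] <= 9  # centred configuration drops a dimension

    def test_too_few_variables_rejected(self):
        df = zscore(pd.DataFrame({"a": np.random.default_rng(0).standard_normal(50)}))
        with pytest.raises(InputError):
            embed_variables(df)


class TestKMeans:
    def test_k_equals_p_gives_zero_wcss(self):
        df, _ = planted_blocks(sizes=(2, 2), n=100)
        emb = embed_variables(df)
        sol = kmeans_fit(emb, k=4, n_restarts=10, seed=0)
        assert sol.wcss == pytest.approx(0.0, abs=1e-6)

    def test_two_planted_blocks_recovered_exactly(self):
        df, truth = planted_blocks(sizes=(4, 4), rho=0.9, seed=5)
        emb = embed_variables(df)
        sol = kmeans_fit(emb, k=2, n_restarts=20, seed=0)
        assert adjusted_rand_score(truth[sol.assignment.index], sol.assignment) == 1.0

    def test_wcss_monotone_in_k(self):
        df, _ = planted_blocks(sizes=(3, 3, 4), seed=7)
        emb = embed_variables(df)
        scan = bic_scan(emb, k_range=(1, 8), n_restarts=20, seed=0)
        w = scan.table["wcss"].to_numpy()
        assert (np.diff(w) <= 1e-6).all()

    def test_invalid_k_rejected(self):
        df, _ = planted_blocks(sizes=(2, 2), n=100)
        emb = embed_variables(df)
        with pytest.raises(ConfigurationError):
            kmeans_fit(emb, k=5)

    def test_deterministic_given_seed(self):
        df, _ = planted_blocks(sizes=(3, 3, 4), seed=9)
        emb = embed_variables(df)
        a = kmeans_fit(emb, 3, n_restarts=10, seed=42)
        b = kmeans_fit(emb, 3, n_restarts=10, seed=42)
        assert (a.assignment == b.assignment).all()
        assert a.wcss == b.wcss


class TestBICScan:
    def test_four_separated_blocks_choose_four(self):
        df, _ = planted_blocks(n=800, sizes=(5, 5, 5, 5), rho=0.85, seed=1)
        scan = bic_scan(embed_variables(df), k_range=(1, 8), n_restarts=20, seed=0)
        assert scan.chosen_k == 4

    def test_single_blob_chooses_one(self):
        rng = np.random.default_rng(4)
        df = zscore(pd.DataFrame(rng.standard_normal((800, 12))))
        df.columns = [f"v{i}" for i in range(12)]
        scan = bic_scan(embed_variables(df), k_range=(1, 6), n_restarts=20, seed=0)
        assert scan.chosen_k == 1

    def test_chosen_attains_minimum_and_ties_go_low(self):
        df, _ = planted_blocks(sizes=(3, 3), seed=2)
        scan = bic_scan(embed_variables(df), k_range=(1, 6), n_restarts=20, seed=0)
        t = scan.table.set_index("k")["bic"]
        assert t[scan.chosen_k] == t.min()
        # tie rule directly on the formula: identical BICs -> first (smallest) k
        assert kmeans_bic(10.0, 8, 3, 2) == kmeans_bic(10.0, 8, 3, 2)
        tied = pd.DataFrame({"k": [2, 3], "bic": [1.0, 1.0]})
        assert int(tied.loc[tied["bic"].idxmin(), "k"]) == 2


class TestIndexVote:
    def test_four_planted_blocks_majority_votes_four(self):
        df, _ = planted_blocks(n=800, sizes=(5, 5, 5, 5), rho=0.85, seed=3)
        votes = index_vote(embed_variables(df), k_range=(2, 8), seed=0)
        assert (votes["optimal_k"] == 4).mean() > 0.5

    def test_duplicate_variables_two_groups_unanimous(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(400), rng.standard_normal(400)
        df = zscore(pd.DataFrame({f"a{i}": a for i in range(4)} | {f"b{i}": b for i in range(4)}))
        # exact duplicates: add microscopic jitter so silhouette is defined
        df += 1e-6 * rng.standard_normal(df.shape)
        votes = index_vote(embed_variables(zscore(df)), k_range=(2, 6), seed=0)
        assert (votes["optimal_k"] == 2).all()

    def test_empty_index_list(self):
        df, _ = planted_blocks(sizes=(3, 3))
        votes = index_vote(embed_variables(df), index_names=())
        assert votes.empty

    def test_unknown_index_rejected(self):
        df, _ = planted_blocks(sizes=(3, 3))
        with pytest.raises(ConfigurationError):
            index_vote(embed_variables(df), index_names=("nonsense",))


class TestHierarchical:
    def test_identical_pair_merges_first_at_zero(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(200)
        df = zscore(pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.standard_normal(200)}))
        dendro = hierarchical_cluster(df)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-6)
        cut = dendro.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_planted_blocks_recovered_by_cut(self):
        df, truth = planted_blocks(n=800, sizes=(5, 5, 5, 5), rho=0.85, seed=12)
        dendro = hierarchical_cluster(df)
        cut = dendro.cut(4)
        assert adjusted_rand_score(truth[cut.index], cut) == 1.0

    def test_newick_round_trip(self):
        import skbio

        df, _ = planted_blocks(sizes=(3, 3, 4), seed=13)
        dendro = hierarchical_cluster(df)
        newick = dendro.to_newick()
        tree = skbio.TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == set(dendro.names)
        # topology survives a parse -> re-read cycle
        again = skbio.TreeNode.read([str(tree)])
        assert tree.compare_rfd(again) == 0.0

    def test_merge_heights_nondecreasing(self):
        df, _ = planted_blocks(sizes=(4, 3, 3), seed=14)
        dendro = hierarchical_cluster(df)
        heights = dendro.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-9).all()


class TestSilhouettes:
    def test_two_far_tight_pairs(self):
        coords = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        from dietcluster.clustering import VariableEmbedding

        emb = VariableEmbedding(names=list("abcd"), coords=coords, n_participants=10)
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        s = silhouette_values(emb, labels)
        assert (s > 0.9).all()

    def test_equidistant_point_scores_near_zero(self):
        coords = np.array([[0.0, 0], [1, 0], [5, 0], [9, 0], [10, 0]])
        from dietcluster.clustering import VariableEmbedding

        emb = VariableEmbedding(names=list("abcde"), coords=coords, n_participants=10)
        labels = pd.Series([0, 0, 0, 1, 1], index=list("abcde"))
        s = silhouette_values(emb, labels)
        assert abs(s["c"]) < 0.2

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(21)
        coords = rng.standard_normal((10, 4))
        from dietcluster.clustering import VariableEmbedding

        names = [f"v{i}" for i in range(10)]
        emb = VariableEmbedding(names=names, coords=coords, n_participants=50)
        labels = pd.Series(rng.integers(0, 3, 10), index=names)
        s = silhouette_values(emb, labels)

        # brute force straight from the definition
        D = cdist(coords, coords)
        for i in range(10):
            own = labels.to_numpy() == labels.iloc[i]
            if own.sum() == 1:
                assert s.iloc[i] == 0.0
                continue
            a = D[i, own].sum() / (own.sum() - 1)
            b = min(
                D[i, labels.to_numpy() == c].mean()
                for c in set(labels) if c != labels.iloc[i]
            )
            assert s.iloc[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)
        ref = silhouette_samples(coords, labels.to_numpy())
        assert np.allclose(s.to_numpy(), ref, atol=1e-9)

    def test_single_cluster_rejected(self):
        from dietcluster.clustering import VariableEmbedding

        emb = VariableEmbedding(names=list("ab"), coords=np.eye(2), n_participants=5)
        with pytest.raises(InputError):
            silhouette_values(emb, pd.Series([0, 0], index=list("ab")))


class TestRepresentatives:
    def _solution(self, sils, assignment):
        names = list(sils)
        sol = ClusterSolution(
            k=len(set(assignment.values())),
            assignment=pd.Series(assignment),
            centroids=np.zeros((2, 2)),
            wcss=1.0,
            bic=0.0,
            silhouettes=pd.Series(sils),
        )
        return sol

    def test_max_silhouette_wins_and_low_correlation_second_hit_retained(self):
        sol = self._solution(
            {"A": 0.32, "B": 0.18, "C": 0.5, "D": 0.2},
            {"A": 0, "B": 0, "C": 1, "D": 1},
        )
        corr = pd.DataFrame(
            [[1, 0.3, 0, 0], [0.3, 1, 0, 0], [0, 0, 1, 0.8], [0, 0, 0.8, 1]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        sol = select_representatives(sol, corr, correlation_cutoff=0.50)
        assert sol.representatives == {0: "A", 1: "C"}
        hits = sol.second_hits.set_index("cluster")
        assert bool(hits.loc[0, "retained"])       # r = 0.3 < 0.50
        assert not bool(hits.loc[1, "retained"])   # r = 0.8 >= 0.50
        assert selected_exposures(sol) == ["A", "B", "C"]

    def test_negative_correlation_uses_absolute_value(self):
        sol = self._solution({"A": 0.4, "B": 0.3}, {"A": 0, "B": 0})
        corr = pd.DataFrame([[1, -0.7], [-0.7, 1]], index=list("AB"), columns=list("AB"))
        sol = select_representatives(sol, corr)
        assert not bool(sol.second_hits.loc[0, "retained"])

    def test_silhouette_tie_breaks_lexicographically(self):
        sol = self._solution({"b": 0.3, "a": 0.3, "c": 0.1}, {"b": 0, "a": 0, "c": 0})
        corr = pd.DataFrame(np.eye(3), index=list("bac"), columns=list("bac"))
        sol = select_representatives(sol, corr)
        assert sol.representatives[0] == "a"

    def test_singleton_cluster_has_no_second_hit(self):
        sol = self._solution({"A": 0.4, "B": 0.2}, {"A": 0, "B": 1})
        corr = pd.DataFrame(np.eye(2), index=list("AB"), columns=list("AB"))
        sol = select_representatives(sol, corr)
        assert sol.representatives == {0: "A", 1: "B"}
        assert sol.second_hits.empty
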