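import numpy as np
import pytest

from playseq.io_model import PipelineConfig
from playseq.similarity_clustering import (
    TransitionProfileMatrix,
    consensus_clusters,
    dendrogram_to_newick,
    embed_2d,
    hierarchical_dendrogram,
    optimal_k,
    transition_profile_matrix,
)
from playseq.transition_stats import TransitionProbabilities


def probs_from_matrix(elements, mat):
    table = {}
    for i, a in enumerate(elements):
        row = {elements[j]: mat[i][j] for j in range(len(elements)) if mat[i][j] > 0}
        if row:
            table[(a,)] = row
    return TransitionProbabilities(order=1, table=table)


class TestProfileMatrix:
    def test_matrix_matches_inputs(self):
        els = ["A", "B", "C"]
        mat = [[0.0, 0.7, 0.3], [0.5, 0.0, 0.5], [1.0, 0.0, 0.0]]
        profile = transition_profile_matrix(probs_from_matrix(els, mat))
        assert profile.elements == ("A", "B", "C")
        np.testing.assert_allclose(profile.rows, mat)
        assert profile.zero_rows == ()

    def test_zero_row_flagged(self):
        els = ["A", "B", "C"]
        mat = [[0.0, 1.0, 0.0], [0.5, 0.0, 0.5], [0.0, 0.0, 0.0]]
        profile = transition_profile_matrix(probs_from_matrix(els, mat), vocabulary=els)
        assert profile.zero_rows == ("C",)

    def test_identical_rows_zero_distance(self):
        els = ["A", "B", "C"]
        mat = [[0.0, 0.5, 0.5], [0.0, 0.5, 0.5], [1.0, 0.0, 0.0]]
        profile = transition_profile_matrix(probs_from_matrix(els, mat))
        assert np.linalg.norm(profile.rows[0] - profile.rows[1]) == 0.0


def _planted_profile(n_groups=2, per_group=6, noise=0.0, seed=0):
    """Duplicate transition rows per group: groups are perfectly separable."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    rows = np.zeros((n, n))
    for g in range(n_groups):
        proto = rng.dirichlet(np.ones(n))
        for i in range(g * per_group, (g + 1) * per_group):
            rows[i] = proto
    if noise:
        rows += rng.uniform(0, noise, size=rows.shape)
        rows /= rows.sum(axis=1, keepdims=True)
    elements = tuple(f"e{i:02d}" for i in range(n))
    return TransitionProfileMatrix(elements=elements, rows=rows)


class TestEmbedding:
    def test_separated_groups_stay_separated(self):
        profile = _planted_profile(2, 6, noise=0.01)
        pts = embed_2d(profile, epochs=300, rng=np.random.default_rng(0), n_neighbors=4)
        X = np.array([pts[e] for e in profile.elements])
        a, b = X[:6], X[6:]
        within = max(
            np.linalg.norm(a - a.mean(0), axis=1).max(),
            np.linalg.norm(b - b.mean(0), axis=1).max(),
        )
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > within

    def test_reproducible_given_rng_state(self):
        profile = _planted_profile(2, 4, noise=0.02)
        p1 = embed_2d(profile, 200, np.random.default_rng(5), n_neighbors=3)
        p2 = embed_2d(profile, 200, np.random.default_rng(5), n_neighbors=3)
        assert p1 == p2

    def test_too_few_elements_rejected(self):
        profile = _planted_profile(1, 3)
        with pytest.raises(ValueError):
            embed_2d(profile, 100, np.random.default_rng(0))


class TestOptimalK:
    def _blobs(self, k, per, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        pts = {}
        for g in range(k):
            centre = np.array([np.cos(2 * np.pi * g / k), np.sin(2 * np.pi * g / k)]) * 10
            for i in range(per):
                xy = centre + rng.normal(0, spread, 2)
                pts[f"g{g}e{i}"] = (float(xy[0]), float(xy[1]))
        return pts

    def test_two_blobs(self):
        pts = self._blobs(2, 8)
        k, sil, mem = optimal_k(pts, rng=np.random.default_rng(1))
        assert k == 2
        assert sil > 0.95

    def test_twelve_blobs(self):
        pts = self._blobs(12, 5)
        k, sil, mem = optimal_k(pts, rng=np.random.default_rng(2))
        assert k == 12
        assert sil > 0.9

    def test_identical_points_degenerate(self):
        pts = {f"e{i}": (1.0, 1.0) for i in range(6)}
        k, sil, mem = optimal_k(pts, rng=np.random.default_rng(3))
        assert k == 1
        assert np.isnan(sil)

    def test_silhouette_matches_independent_recomputation(self):
        from sklearn.metrics import silhouette_score

        pts = self._blobs(3, 6, spread=0.5)
        k, sil, mem = optimal_k(pts, rng=np.random.default_rng(4))
        elements = sorted(pts)
        X = np.array([pts[e] for e in elements])
        labels = [mem[e] for e in elements]
        assert sil == pytest.approx(float(silhouette_score(X, labels)), abs=1e-9)


class TestDendrogram:
    def test_two_distant_pairs_merge_first(self):
        pts = {"a1": (0.0, 0.0), "a2": (0.1, 0.0), "b1": (10.0, 0.0), "b2": (10.1, 0.0)}
        sol = hierarchical_dendrogram(pts, k=2)
        assert sol.memberships["a1"] == sol.memberships["a2"]
        assert sol.memberships["b1"] == sol.memberships["b2"]
        assert sol.memberships["a1"] != sol.memberships["b1"]
        # merge heights non-decreasing
        heights = sol.dendrogram[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("k,expected_groups", [(1, 1), (4, 4)])
    def test_extreme_cuts(self, k, expected_groups):
        pts = {"a": (0, 0), "b": (1, 0), "c": (5, 0), "d": (6, 0)}
        sol = hierarchical_dendrogram(pts, k=k)
        assert len(set(sol.memberships.values())) == expected_groups

    def test_newick_export_contains_all_leaves(self):
        pts = {"a": (0, 0), "b": (1, 0), "c": (5, 0), "d": (6, 0)}
        sol = hierarchical_dendrogram(pts, k=2)
        nwk = dendrogram_to_newick(sol.dendrogram, sorted(pts))
        assert nwk.endswith(";")
        for leaf in pts:
            assert leaf in nwk


class TestConsensus:
    def test_recovers_planted_groups_and_reports_modal_k(self):
        from sklearn.metrics import adjusted_rand_score

        profile = _planted_profile(4, 5, noise=0.01, seed=7)
        cfg = PipelineConfig(n_embedding_runs=4, mean_epochs=300, lump_min_count=1)
        sol, stability = consensus_clusters(profile, cfg, np.random.default_rng(8))
        truth = [i // 5 for i in range(20)]
        labels = [sol.memberships[e] for e in profile.elements]
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert sol.acceptable
        # identical-row elements co-cluster in every run
        assert stability[("e00", "e01")] == pytest.approx(1.0)

    def test_final_k_is_the_mode(self):
        profile = _planted_profile(3, 5, noise=0.01, seed=9)
        cfg = PipelineConfig(n_embedding_runs=3, mean_epochs=200, lump_min_count=1)
        sol, _ = consensus_clusters(profile, cfg, np.random.default_rng(10))
        assert sol.k == 3
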