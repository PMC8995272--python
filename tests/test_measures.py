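import numpy as np
import pytest

from mrfviz import (
    Embedding,
    SimilarityMatrix,
    dimensionality_sweep,
    encoding_epsilon,
    measure_table,
    similarity_matrix,
    stability_experiment,
    svd_embed,
    tissue_slice,
)
from mrfviz.registration import SimilarityTransform


class TestSimilarityMatrix:
    def test_identical_rows_all_ones(self):
        S = similarity_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert np.array_equal(S.values, np.ones((2, 2)))

    def test_orthonormal_rows_zero_off_diagonal(self):
        S = similarity_matrix(np.eye(2))
        assert np.allclose(S.values, np.eye(2))

    def test_unit_diagonal_symmetry_and_range(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        S = similarity_matrix(X)
        assert np.allclose(np.diag(S.values), 1.0)
        assert np.allclose(S.values, S.values.T)
        assert S.values.min() >= 0.0 and S.values.max() <= 1.0

    def test_zero_norm_row_rejected_when_normalizing(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            similarity_matrix(X, normalize_rows=True)


class TestTissueSlice:
    def test_wm_gm_slice_sizes(self, full_scale_grid):
        coords = np.random.default_rng(0).normal(size=(full_scale_grid.n_entries, 2))
        S = similarity_matrix(coords)
        assert tissue_slice(S, full_scale_grid, "T2", 80.0).size == 64
        assert tissue_slice(S, full_scale_grid, "T2", 110.0).size == 63

    def test_slice_preserves_global_rescale(self, small_grid):
        coords = np.random.default_rng(1).normal(size=(small_grid.n_entries, 2))
        S = similarity_matrix(coords)
        sub = tissue_slice(S, small_grid, "T2", 60.0)
        idx = small_grid.slice_indices("T2", 60.0)
        assert np.array_equal(sub.values, S.values[np.ix_(idx, idx)])

    def test_off_grid_value_rejected(self, small_grid):
        coords = np.random.default_rng(1).normal(size=(small_grid.n_entries, 2))
        S = similarity_matrix(coords)
        with pytest.raises(ValueError):
            tissue_slice(S, small_grid, "T2", 5.0)


class TestEncodingEpsilon:
    @pytest.mark.parametrize("variant", ["induced_l1", "entrywise_mean"])
    def test_identity_gives_zero(self, variant):
        for m in (2, 5, 10):
            S = SimilarityMatrix(values=np.eye(m), entry_index=np.arange(m))
            assert encoding_epsilon(S, variant=variant).epsilon == 0.0

    @pytest.mark.parametrize("variant", ["induced_l1", "entrywise_mean"])
    def test_hand_computed_values(self, variant):
        all_ones = SimilarityMatrix(values=np.ones((3, 3)), entry_index=np.arange(3))
        assert encoding_epsilon(all_ones, variant=variant).epsilon == pytest.approx(
            2 / 3
        )
        half = SimilarityMatrix(
            values=np.array([[1.0, 0.5], [0.5, 1.0]]), entry_index=np.arange(2)
        )
        assert encoding_epsilon(half, variant=variant).epsilon == pytest.approx(0.25)

    def test_positive_unless_identity(self):
        S = SimilarityMatrix(
            values=np.array([[1.0, 0.01], [0.01, 1.0]]), entry_index=np.arange(2)
        )
        assert encoding_epsilon(S).epsilon > 0

    def test_unknown_variant_rejected(self):
        S = SimilarityMatrix(values=np.eye(2), entry_index=np.arange(2))
        with pytest.raises(ValueError):
            encoding_epsilon(S, variant="spectral")

    def test_invariant_under_similarity_transform(self, small_grid):
        """epsilon computed from embedding coordinates is unchanged by any
        rotation/reflection, isotropic scaling and translation."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(small_grid.n_entries, 2))
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        t = SimilarityTransform(scale=4.2, orthogonal=q, translation=rng.normal(size=2))
        eps = []
        for c in (coords, t.apply(coords)):
            S = similarity_matrix(c)
            eps.append(
                encoding_epsilon(tissue_slice(S, small_grid, "T2", 60.0)).epsilon
            )
        assert eps[0] == pytest.approx(eps[1], abs=1e-12)


class TestMeasureTable:
    def test_cardinality(self, small_dict):
        embs = dimensionality_sweep(small_dict, [2, 3], method="svd")
        table = measure_table(
            small_dict,
            embs,
            tissues=[("T2", 60.0, "WM-like"), ("T2", 100.0, "GM-like")],
        )
        assert len(table) == 6
        assert set(table.source) == {"full", "svd-2d", "svd-3d"}

    def test_full_rank_svd_matches_full_source(self, small_dict):
        full_rank = min(small_dict.signals.shape)
        emb = svd_embed(small_dict, n_dim=full_rank)
        table = measure_table(
            small_dict, [emb], tissues=[("T2", 60.0, "WM-like")]
        )
        eps = table.set_index("source").epsilon
        assert eps["full"] == pytest.approx(eps[f"svd-{full_rank}d"], abs=1e-6)


class TestStabilityExperiment:
    def test_identical_seeds_zero_distances(self, small_dict):
        rep = stability_experiment(
            small_dict, seeds=[0, 0], perplexity=10, n_iter=300
        )
        assert np.allclose(rep.distances[0], 0.0, atol=1e-9)

    def test_report_shape(self, small_dict):
        rep = stability_experiment(
            small_dict, seeds=[0, 1, 2], perplexity=10, n_iter=300
        )
        assert len(rep.distances) == 2
        assert rep.e1_nn_distances.shape == (small_dict.grid.n_entries,)
        assert len(rep.percentiles) == 3  # two runs + the E1-nn reference row

    def test_too_few_runs_rejected(self, small_dict):
        with pytest.raises(ValueError):
            stability_experiment(small_dict, seeds=[0])
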