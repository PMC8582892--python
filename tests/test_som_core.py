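"""Unit tests for map geometry, competitive training and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somexposure.exceptions import (
    DegenerateLabelsError,
    InvalidConfigError,
    NoYLayerError,
    SomexposureError,
)
from somexposure.grid import SOMGrid
from somexposure.som import (
    KohonenSOM,
    SupervisedKohonenSOM,
    SOMResults,
    TrainingConfig,
    find_bmu,
    initialize_codebooks,
    learning_rate,
    neighborhood_value,
    quantization_error,
    topographic_error,
    update_codebooks,
)


class TestGrid:
    def test_reading_order_bottom_left_first(self):
        g = SOMGrid(4, 4)
        assert g.linear_index(0, 0) == 0          # node 1: bottom-left
        assert g.linear_index(0, 3) == 3          # end of bottom row
        assert g.linear_index(3, 3) == 15         # node 16: top-right
        assert g.node_position(5) == (1, 1)

    def test_linear_indexing_bijective(self):
        g = SOMGrid(3, 5)
        seen = {g.linear_index(k, j) for k in range(3) for j in range(5)}
        assert seen == set(range(15))

    def test_rectangular_corner_has_two_neighbours(self):
        g = SOMGrid(4, 4)
        assert len(g.neighbours(0)) == 2
        assert len(g.neighbours(5)) == 4  # interior node

    def test_hexagonal_interior_has_six_neighbours(self):
        g = SOMGrid(5, 5, topology="hexagonal")
        centre = g.linear_index(2, 2)
        assert len(g.neighbours(centre)) == 6

    @pytest.mark.parametrize("rows,cols", [(0, 4), (4, 0), (-1, 1)])
    def test_degenerate_dimensions_rejected(self, rows, cols):
        with pytest.raises(InvalidConfigError):
            SOMGrid(rows, cols)

    def test_linear_topology_rejected_explicitly(self):
        with pytest.raises(InvalidConfigError, match="linear"):
            SOMGrid(1, 8, topology="linear")


class TestInitialization:
    @pytest.mark.parametrize("rows,cols,expected", [(4, 4, 16), (8, 8, 64)])
    def test_codebook_count_matches_grid(self, rng, rows, cols, expected):
        grid = SOMGrid(rows, cols)
        W = initialize_codebooks(grid, np.zeros(3), np.ones(3), rng)
        assert W.shape == (expected, 3)

    def test_codebooks_within_feature_ranges(self, rng):
        lo, hi = np.array([-2.0, 5.0]), np.array([1.0, 9.0])
        W = initialize_codebooks(SOMGrid(6, 6), lo, hi, rng)
        assert (W >= lo).all() and (W <= hi).all()

    def test_degenerate_range_collapses_to_value(self, rng):
        W = initialize_codebooks(SOMGrid(3, 3), np.array([0.0]), np.array([0.0]), rng)
        assert (W == 0.0).all()

    def test_zero_dimension_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            initialize_codebooks(SOMGrid(2, 2), np.array([]), np.array([]), rng)


class TestBMU:
    def test_nearest_codebook_wins(self):
        W = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert find_bmu(W, np.array([0.1, 0.0])) == 0

    def test_exact_match_wins_with_zero_distance(self):
        W = np.array([[0.3, -1.2], [2.0, 2.0]])
        assert find_bmu(W, W[1]) == 1

    def test_tie_breaks_to_lowest_linear_index(self):
        W = np.array([[1.0], [-1.0], [1.0]])
        assert find_bmu(W, np.array([0.0])) == 0

    def test_matches_exhaustive_scan(self, rng):
        W = rng.normal(size=(25, 6))
        for z in rng.normal(size=(100, 6)):
            expected = min(range(25), key=lambda i: np.sum((z - W[i]) ** 2))
            assert find_bmu(W, z) == expected


class TestSchedules:
    def test_learning_rate_at_zero_is_eta0(self):
        assert learning_rate(0, 0.1, 50.0) == pytest.approx(0.1)

    def test_learning_rate_one_decay_constant(self):
        assert learning_rate(100.0, 0.1, 100.0) == pytest.approx(0.1 * np.exp(-1))

    def test_exponential_identity(self):
        eta0, tau2 = 0.2, 37.0
        assert learning_rate(2 * tau2, eta0, tau2) == pytest.approx(
            learning_rate(tau2, eta0, tau2) ** 2 / eta0
        )

    def test_strictly_decreasing(self):
        vals = [learning_rate(t, 0.5, 20.0) for t in range(0, 100, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestNeighborhood:
    def test_bmu_gets_full_learning_rate(self):
        g = SOMGrid(3, 3)
        h = neighborhood_value(g, 4, 4, t=7, sigma0=1.5, tau1=100, eta0=0.3, tau2=50)
        assert h == pytest.approx(learning_rate(7, 0.3, 50))

    def test_gaussian_kernel_value_at_unit_distance(self):
        # d=1, sigma=1, eta=1 -> exp(-1/2)
        g = SOMGrid(1, 2)
        h = neighborhood_value(g, 0, 1, t=0, sigma0=1.0, tau1=1e12, eta0=1.0, tau2=1e12)
        assert h == pytest.approx(np.exp(-0.5))

    def test_collapsed_radius_updates_bmu_only(self):
        g = SOMGrid(2, 2)
        assert neighborhood_value(g, 0, 1, t=0, sigma0=0.0, tau1=10, eta0=0.5, tau2=10) == 0.0
        assert neighborhood_value(g, 0, 0, t=0, sigma0=0.0, tau1=10, eta0=0.5, tau2=10) == 0.5


class TestUpdate:
    @pytest.mark.parametrize(
        "w,z,h,expected",
        [
            ([[0.0]], [1.0], [1.0], [[1.0]]),           # full step lands on z
            ([[0.7]], [1.0], [0.0], [[0.7]]),           # h = 0 leaves unchanged
            ([[0.0, 0.0]], [2.0, 4.0], [0.5], [[1.0, 2.0]]),  # half step
        ],
    )
    def test_update_moves_by_fraction_h(self, w, z, h, expected):
        W = np.array(w, dtype=float)
        update_codebooks(W, np.array(z), np.array(h))
        assert W == pytest.approx(np.array(expected))

    @settings(derandomize=True, max_examples=50)
    @given(
        w=st.floats(-10, 10),
        z=st.floats(-10, 10),
        h=st.floats(0, 1),
    )
    def test_update_is_convex(self, w, z, h):
        """Each component stays between its old value and the pattern."""
        W = np.array([[w]])
        update_codebooks(W, np.array([z]), np.array([h]))
        lo, hi = min(w, z), max(w, z)
        assert lo - 1e-12 <= W[0, 0] <= hi + 1e-12


class TestQuantizationError:
    def test_zero_when_patterns_sit_on_codebooks(self):
        W = np.array([[0.0, 0.0], [1.0, 1.0]])
        qe = quantization_error(W, W.copy())
        assert qe.mean == 0.0 and qe.total == 0.0

    def test_hand_computed_mean_squared_distance(self):
        qe = quantization_error(np.array([[1.0]]), np.array([[0.0], [2.0]]))
        assert qe.mean == pytest.approx(1.0)
        assert qe.total == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        W = rng.normal(size=(9, 4))
        X = rng.normal(size=(50, 4))
        brute = np.mean([
            min(np.sum((z - w) ** 2) for w in W) for z in X
        ])
        assert quantization_error(W, X).mean == pytest.approx(brute, abs=1e-12)

    def test_empty_pattern_set_rejected(self):
        with pytest.raises(SomexposureError):
            quantization_error(np.ones((2, 1)), np.empty((0, 1)))


class TestTopographicError:
    def test_adjacent_runner_up_scores_zero(self):
        g = SOMGrid(1, 3)
        W = np.array([[0.0], [0.1], [5.0]])
        assert topographic_error(g, W, np.array([[0.0]])) == 0.0

    def test_opposite_corners_score_one(self):
        g = SOMGrid(3, 3)
        W = np.full((9, 1), 100.0)
        W[0], W[8] = 0.0, 0.2  # two nearest at opposite corners
        assert topographic_error(g, W, np.array([[0.0]])) == 1.0

    def test_range_contract_on_random_data(self, rng):
        g = SOMGrid(4, 4)
        W = rng.normal(size=(16, 3))
        te = topographic_error(g, W, rng.normal(size=(40, 3)))
        assert 0.0 <= te <= 1.0

    def test_single_node_map_undefined(self):
        with pytest.raises(SomexposureError):
            topographic_error(SOMGrid(1, 1), np.ones((1, 1)), np.ones((3, 1)))


class TestTrainingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eta0": 0.0}, {"eta0": 1.5}, {"tau2": -1.0}, {"sigma0": -0.1},
            {"n_epochs": 0}, {"x_weight": 0.0}, {"x_weight": 1.2},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            TrainingConfig(**kwargs)


class TestUnsupervisedTraining:
    def test_single_node_converges_to_data_mean(self, rng):
        """Closed-form limit: a single unit under a decaying learning rate is
        a weighted running average of the patterns, hence -> data mean."""
        X = rng.normal(3.0, 0.05, size=(100, 2))
        res = KohonenSOM(X, grid=(1, 1)).fit(
            seed=0, n_epochs=1000, tau2=20000.0, stop_tol=0.0
        )
        assert np.allclose(res.codebooks[0], X.mean(axis=0), atol=1e-3)

    def test_same_seed_gives_identical_codebooks(self, rng):
        X = rng.normal(size=(80, 3))
        a = KohonenSOM(X, grid=(3, 3)).fit(seed=9, n_epochs=10)
        b = KohonenSOM(X, grid=(3, 3)).fit(seed=9, n_epochs=10)
        assert np.array_equal(a.codebooks, b.codebooks)

    def test_different_seeds_differ(self, rng):
        X = rng.normal(size=(80, 3))
        a = KohonenSOM(X, grid=(3, 3)).fit(seed=1, n_epochs=5)
        b = KohonenSOM(X, grid=(3, 3)).fit(seed=2, n_epochs=5)
        assert not np.array_equal(a.codebooks, b.codebooks)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_final_qe_not_worse_than_first_epoch(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 4))
        res = KohonenSOM(X, grid=(4, 4)).fit(seed=seed, n_epochs=30)
        assert res.qe_history[-1] <= res.qe_history[0]

    def test_history_length_equals_completed_epochs(self, trained_unsupervised):
        assert trained_unsupervised.n_epochs_run == len(trained_unsupervised.qe_history)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            KohonenSOM(np.array([[np.nan, 1.0]]))


class TestSupervisedTraining:
    def test_node_classes_match_cluster_sides(self, blob_data, trained_supervised):
        """On two well-separated clusters, each node's Y argmax agrees with
        the X-side cluster its codebook sits in."""
        res = trained_supervised
        node_class = np.argmax(res.y_codebooks, axis=1)
        # cluster side by X codebook position (clusters at 0 and 8)
        side = (res.codebooks.mean(axis=1) > 4.0).astype(int)
        assert (node_class == side).all()

    def test_y_codebook_rows_stay_on_simplex(self, trained_supervised):
        sums = trained_supervised.y_codebooks.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_x_weight_one_reduces_to_unsupervised(self, blob_data):
        X, y = blob_data
        a = KohonenSOM(X, grid=(4, 4)).fit(seed=5, n_epochs=8)
        b = SupervisedKohonenSOM(X, y, grid=(4, 4)).fit(seed=5, n_epochs=8, x_weight=1.0)
        assert np.array_equal(a.codebooks, b.codebooks)

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(DegenerateLabelsError):
            SupervisedKohonenSOM(X, np.zeros(30, dtype=int))


class TestPrediction:
    def test_training_patterns_get_their_labels_back(self, blob_data, trained_supervised):
        X, y = blob_data
        assert (trained_supervised.predict(X) == y).mean() > 0.99

    def test_tied_y_codebook_predicts_class_zero(self, trained_supervised):
        res = trained_supervised
        tied = SOMResults(
            model=res.model, grid=res.grid, codebooks=res.codebooks,
            y_codebooks=np.full_like(res.y_codebooks, 0.5), config=res.config,
        )
        assert (tied.predict() == 0).all()

    def test_feature_permutation_invariance(self, blob_data, trained_supervised):
        """Permuting features consistently in the codebooks and the input
        leaves the BMU search, and hence predictions, unchanged."""
        X, _ = blob_data
        res = trained_supervised
        perm = [2, 0, 3, 1]
        permuted = SOMResults(
            model=res.model, grid=res.grid, codebooks=res.codebooks[:, perm],
            y_codebooks=res.y_codebooks, config=res.config,
        )
        assert np.array_equal(res.predict(X), permuted.predict(X[:, perm]))

    def test_unsupervised_model_cannot_predict(self, trained_unsupervised):
        with pytest.raises(NoYLayerError):
            trained_unsupervised.predict()


class TestResultsSurface:
    def test_summary_mentions_map_and_errors(self, trained_supervised):
        text = trained_supervised.summary()
        assert "5 x 5" in text
        assert "Quantization error" in text
        assert "supervised" in text

    def test_json_round_trip(self, tmp_path, trained_supervised):
        path = tmp_path / "model.json"
        trained_supervised.save(path)
        loaded = SOMResults.load(path)
        assert np.array_equal(loaded.codebooks, trained_supervised.codebooks)
        assert np.array_equal(loaded.y_codebooks, trained_supervised.y_codebooks)
        assert loaded.grid.n_rows == 5 and loaded.grid.topology == "rectangular"
        assert loaded.qe_history == trained_supervised.qe_history
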