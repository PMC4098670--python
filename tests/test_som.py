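"""SOM grid geometry, distances, training loop, restarts and projection."""

import math

import numpy as np
import pandas as pd
import pytest

from airsom import (
    PollutantMatrix,
    SOMGrid,
    TrainingSchedule,
    assign,
    build_grid,
    dissimilarity,
    quantization_error,
    standardize,
    train,
    train_with_restarts,
)
from airsom.data import IntegrityError, SchemaError, StandardizationParams
from airsom.som import (
    UNLABELED,
    find_bmu,
    initialize_codebooks,
    load_model,
    modal_qe_choice,
    save_model,
    update_step,
)


class TestGrid:
    def test_4x4_rectangular_geometry(self):
        grid = build_grid(4, 4, "rectangular")
        assert grid.k == 16
        d = grid.distances()
        assert d.max() == pytest.approx(math.sqrt(18))  # (1,1) to (4,4)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d[~np.eye(16, dtype=bool)] > 0)

    def test_single_node(self):
        grid = build_grid(1, 1)
        assert grid.k == 1 and grid.distances()[0, 0] == 0

    def test_hexagonal_2x1(self):
        grid = build_grid(2, 1, "hexagonal")
        assert grid.distances()[0, 1] == pytest.approx(1.0)

    def test_hexagonal_row_offset_and_spacing(self):
        grid = build_grid(2, 2, "hexagonal")
        coords = grid.coords
        # second (even) row offset by +0.5, rows sqrt(3)/2 apart
        assert coords[2, 0] - coords[0, 0] == pytest.approx(0.5)
        assert coords[2, 1] - coords[0, 1] == pytest.approx(math.sqrt(3) / 2)
        # all nearest neighbors at unit distance
        d = grid.distances()
        assert d[0, 2] == pytest.approx(1.0)

    def test_row_major_labels_from_bottom_left(self):
        grid = build_grid(3, 2)
        assert grid.labels[0] == (1, 1)
        assert grid.labels[2] == (3, 1)
        assert grid.labels[3] == (1, 2)

    def test_bad_dimensions(self):
        with pytest.raises(ValueError):
            build_grid(0, 3)
        with pytest.raises(ValueError):
            build_grid(2, 2, "toroidal")


class TestDissimilarity:
    def test_euclidean_345(self):
        assert dissimilarity([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_identity_is_zero(self):
        assert dissimilarity([1.5, -2], [1.5, -2]) == 0.0

    def test_masked_rescaling(self):
        # one of two dims observed: |1-0| * sqrt(2/1)
        d = dissimilarity([1.0, np.nan], [0.0, 9.0], observed_mask=[True, False])
        assert d == pytest.approx(math.sqrt(2))

    def test_no_observed_dimensions_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            dissimilarity([1.0], [2.0], observed_mask=[False])


class TestInitializeCodebooks:
    def test_n_equals_k_is_permutation(self):
        Z = np.arange(8, dtype=float).reshape(4, 2)
        cb = initialize_codebooks(Z, build_grid(2, 2), seed=3)
        assert sorted(map(tuple, cb)) == sorted(map(tuple, Z))

    def test_determinism(self):
        Z = np.random.default_rng(0).standard_normal((50, 3))
        a = initialize_codebooks(Z, build_grid(2, 2), seed=9)
        b = initialize_codebooks(Z, build_grid(2, 2), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_always_distinct_rows_of_z(self):
        Z = np.random.default_rng(1).standard_normal((100, 2))
        rows = {tuple(r) for r in Z}
        for seed in range(100):
            cb = initialize_codebooks(Z, build_grid(2, 2), seed=seed)
            picked = {tuple(r) for r in cb}
            assert len(picked) == 4 and picked <= rows

    def test_more_nodes_than_days(self):
        with pytest.raises(IntegrityError, match="more nodes"):
            initialize_codebooks(np.zeros((3, 2)), build_grid(2, 2), seed=0)


class TestFindBmu:
    def test_nearest_and_tie_rule(self):
        cb = np.array([[0.0, 0.0], [10.0, 10.0]])
        assert find_bmu([1, 1], cb) == 0
        tie = np.array([[0.0], [2.0]])
        assert find_bmu([1.0], tie) == 0  # equidistant -> lowest id

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        cb = rng.standard_normal((50, 4))
        for z in rng.standard_normal((200, 4)):
            expected = min(
                range(50), key=lambda m: float(np.sum((cb[m] - z) ** 2))
            )
            assert find_bmu(z, cb) == expected


class TestUpdateStep:
    def test_bmu_only_update(self):
        grid = build_grid(2, 1)
        cb = np.zeros((2, 2))
        out = update_step(cb, [1.0, 1.0], bmu=0, alpha=0.05, radius=0.5, grid=grid)
        np.testing.assert_allclose(out[0], [0.05, 0.05])
        np.testing.assert_allclose(out[1], [0.0, 0.0])

    def test_tiny_alpha_limit(self):
        grid = build_grid(2, 2)
        cb = np.random.default_rng(0).standard_normal((4, 3))
        out = update_step(cb, np.ones(3), bmu=1, alpha=1e-12, radius=10, grid=grid)
        np.testing.assert_allclose(out, cb, atol=1e-10)

    def test_radius_beyond_diameter_moves_all_nodes(self):
        grid = build_grid(3, 3)
        rng = np.random.default_rng(2)
        cb = rng.standard_normal((9, 2))
        z = rng.standard_normal(2)
        out = update_step(cb, z, bmu=4, alpha=0.1, radius=100.0, grid=grid)
        # loop oracle: every node moves toward z by factor alpha
        for m in range(9):
            np.testing.assert_allclose(out[m], cb[m] + 0.1 * (z - cb[m]))


class TestSchedule:
    def test_defaults_for_4x4(self):
        sched = TrainingSchedule(seed=0).resolve(build_grid(4, 4))
        assert sched.t_total == 8000
        assert sched.alpha(4000) == pytest.approx(0.03)  # midpoint of 0.05 -> 0.01
        assert sched.alpha(0) == 0.05

    def test_radius_piecewise_linear(self):
        sched = TrainingSchedule(
            t_total=900, radius_start=4.0, radius_end=1.0, radius_fraction=1 / 3
        )
        assert sched.radius(0) == 4.0
        assert sched.radius(150) == pytest.approx(2.5)
        assert sched.radius(300) == 1.0
        assert sched.radius(899) == 1.0

    def test_radius_start_covers_two_thirds_of_distances(self):
        grid = build_grid(4, 4)
        sched = TrainingSchedule().resolve(grid)
        d = grid.distances()
        uniq = np.unique(d[d > 0])
        covered = (uniq <= sched.radius_start).mean()
        assert covered >= 2 / 3
        assert sched.radius_start in uniq

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainingSchedule(alpha_start=0.01, alpha_end=0.05)
        with pytest.raises(ValueError):
            TrainingSchedule(radius_fraction=0.0)
        with pytest.raises(ValueError):
            TrainingSchedule(radius_start=0.5, radius_end=1.0)


class TestTrain:
    def test_same_seed_bit_identical(self, clustered_data):
        Z, _ = clustered_data
        grid = build_grid(2, 2)
        sched = TrainingSchedule(seed=3, t_total=1000)
        a = train(Z, grid, sched)
        b = train(Z, grid, sched)
        np.testing.assert_array_equal(a.codebooks, b.codebooks)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.qe == b.qe

    def test_replay_oracle_reproduces_codebooks(self):
        """The fast training loop matches a step-by-step replay via update_step."""
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((30, 3))
        grid = build_grid(2, 2)
        sched = TrainingSchedule(seed=17, t_total=200).resolve(grid)
        model = train(Z, grid, sched)

        replay_rng = np.random.default_rng(sched.seed)
        cb = initialize_codebooks(Z, grid, seed=int(replay_rng.integers(2**31)))
        order = replay_rng.integers(0, 30, size=sched.t_total)
        for t in range(sched.t_total):
            z = Z[order[t]]
            cb = update_step(
                cb, z, find_bmu(z, cb), sched.alpha(t), sched.radius(t), grid
            )
        np.testing.assert_allclose(model.codebooks, cb, atol=1e-12)

    def test_converges_on_duplicate_blocks(self):
        """With n identical days per node and BMU-only fine tuning, QE -> 0."""
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0], [8.0, 8.0]])
        Z = np.repeat(centers, 50, axis=0)
        sched = TrainingSchedule(
            seed=1, t_total=20000, radius_start=0.5, radius_end=0.5
        )
        model = train(Z, build_grid(2, 2), sched)
        assert model.qe < 1e-3
        matched = sorted(tuple(np.round(c, 3)) for c in model.codebooks)
        assert matched == sorted(map(tuple, centers))

    def test_incomplete_input_rejected(self):
        Z = np.ones((10, 2))
        Z[0, 0] = np.nan
        with pytest.raises(IntegrityError):
            train(Z, build_grid(2, 1), TrainingSchedule(seed=0, t_total=10))

    def test_assignments_are_bmus_and_qe_recomputable(self, tiny_model, clustered_data):
        Z, _ = clustered_data
        for i in range(Z.shape[0]):
            assert tiny_model.assignments[i] == find_bmu(Z[i], tiny_model.codebooks)
        assert quantization_error(Z, tiny_model) == pytest.approx(
            tiny_model.qe, abs=1e-12
        )


class TestQuantizationError:
    def test_hand_example(self):
        model_like = type("M", (), {})()
        model_like.codebooks = np.array([[1.0, 0.0]])
        model_like.assignments = np.array([0, 0])
        Z = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert quantization_error(Z, model_like) == pytest.approx(1.0)

    def test_zero_when_days_equal_codebooks(self):
        model_like = type("M", (), {})()
        model_like.codebooks = np.array([[1.0], [2.0]])
        model_like.assignments = np.array([0, 1])
        assert quantization_error(np.array([[1.0], [2.0]]), model_like) == 0.0

    def test_matches_loop_oracle(self, tiny_model, clustered_data):
        Z, _ = clustered_data
        expected = np.mean(
            [
                dissimilarity(Z[i], tiny_model.codebooks[tiny_model.assignments[i]])
                for i in range(Z.shape[0])
            ]
        )
        assert quantization_error(Z, tiny_model) == pytest.approx(expected, abs=1e-12)


class TestRestarts:
    def test_modal_rule_prefers_most_frequent_bin(self):
        # two restarts rounding to 0.900, one better at 0.85: the 0.900 bin wins
        assert modal_qe_choice([0.9001, 0.8999, 0.85]) == 1  # lowest unrounded in bin

    def test_all_distinct_degenerates_to_minimum(self):
        assert modal_qe_choice([0.91, 0.87, 0.93]) == 1

    def test_single_restart_returned(self, clustered_data):
        Z, _ = clustered_data
        sched = TrainingSchedule(seed=2, t_total=500)
        model = train_with_restarts(Z, build_grid(2, 2), sched, n_restarts=1)
        assert len(model.restart_qes) == 1
        assert model.qe == model.restart_qes[0]

    def test_returned_qe_bounded_and_logged(self, clustered_data):
        Z, _ = clustered_data
        sched = TrainingSchedule(seed=2, t_total=500)
        model = train_with_restarts(Z, build_grid(2, 2), sched, n_restarts=5)
        assert len(model.restart_qes) == 5
        assert model.qe <= max(model.restart_qes)
        assert model.qe in model.restart_qes


class TestAssign:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(size=(60, 2))
        pm = PollutantMatrix(
            dates=pd.date_range("2000-01-01", periods=60),
            values=values,
            columns=["a", "b"],
        )
        Zs, params = standardize(pm)
        model = train(
            Zs.values,
            build_grid(2, 1),
            TrainingSchedule(seed=4, t_total=500),
            standardization=params,
            columns=pm.columns,
        )
        return pm, model

    def test_training_rows_reproject_to_training_assignment(self, fitted):
        pm, model = fitted
        np.testing.assert_array_equal(assign(pm, model), model.assignments)

    def test_masked_projection(self):
        params = StandardizationParams(means=[0.0, 0.0], sds=[1.0, 1.0], columns=["a", "b"])
        model_like = train(
            np.array([[0.0, 0.0], [10.0, 0.0], [0.1, 0.1], [9.9, 0.2]]),
            build_grid(2, 1),
            TrainingSchedule(seed=0, t_total=50),
            standardization=params,
            columns=["a", "b"],
        )
        model_like.codebooks = np.array([[0.0, 0.0], [10.0, 0.0]])
        pm = PollutantMatrix(
            dates=pd.date_range("2000-01-01", periods=2),
            values=[[1.0, np.nan], [np.nan, np.nan]],
            columns=["a", "b"],
        )
        labels = assign(pm, model_like)
        assert labels[0] == 0  # masked distance 1*sqrt(2) vs 9*sqrt(2)
        assert labels[1] == UNLABELED

    def test_schema_mismatch(self, fitted):
        pm, model = fitted
        wrong = PollutantMatrix(
            dates=pm.dates, values=pm.values, columns=["x", "y"]
        )
        with pytest.raises(SchemaError):
            assign(wrong, model)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, clustered_data):
        Z, _ = clustered_data
        params = StandardizationParams(
            means=np.zeros(2), sds=np.ones(2), columns=["a", "b"]
        )
        model = train(
            Z,
            build_grid(2, 2),
            TrainingSchedule(seed=6, t_total=800),
            standardization=params,
            columns=["a", "b"],
        )
        path = tmp_path / "model.som"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.codebooks, model.codebooks)
        np.testing.assert_array_equal(back.assignments, model.assignments)
        assert back.qe == model.qe
        assert back.schedule == model.schedule
        assert back.grid == model.grid
        np.testing.assert_array_equal(
            back.standardization.means, model.standardization.means
        )
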