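"""Correlation filter, ordered split, OLS and GA subset search."""

import itertools

import numpy as np
import pytest

from ponqsar.descriptors import DescriptorMatrix
from ponqsar.modeling import (
    GAConfig,
    MLRModel,
    ModelingError,
    drop_correlated,
    fit_mlr,
    ga_select,
    load_fixture_model,
    ordered_split,
    predict,
)
from ponqsar.synthetic import SyntheticSpec, generate
from ponqsar.validation import q2_loo


def _matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"X{j}" for j in range(values.shape[1])]
    return DescriptorMatrix(
        [f"c{i}" for i in range(values.shape[0])], names, values
    )


class TestDropCorrelated:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        m = _matrix(np.column_stack([x, rng.standard_normal(20), x]))
        out = drop_correlated(m, 0.95)
        assert out.descriptor_names == ["X0", "X1"]

    def test_orthogonal_columns_kept(self):
        m = _matrix(np.array([[1, 0], [-1, 0], [0, 1], [0, -1.0]]))
        out = drop_correlated(m, 0.95)
        assert out.descriptor_names == ["X0", "X1"]

    def test_constant_column_removed_first(self):
        rng = np.random.default_rng(1)
        m = _matrix(
            np.column_stack([np.full(15, 3.0), rng.standard_normal(15)])
        )
        assert drop_correlated(m, 0.95).descriptor_names == ["X1"]

    def test_noisy_block_leaves_first_survivor(self):
        """One survivor from a near-duplicate block, cross-checked by an
        exhaustive pairwise-correlation scan."""
        rng = np.random.default_rng(7)
        base = rng.standard_normal(200)
        block = np.column_stack(
            [base + 0.05 * rng.standard_normal(200) for _ in range(4)]
        )
        rest = rng.standard_normal((200, 6))
        m = _matrix(np.column_stack([block, rest]))
        out = drop_correlated(m, 0.95)
        survivors = out.descriptor_names
        assert [s for s in survivors if s in ("X0", "X1", "X2", "X3")] == ["X0"]
        # oracle: no remaining pair correlated above threshold
        vals = out.values
        for i, j in itertools.combinations(range(vals.shape[1]), 2):
            r = np.corrcoef(vals[:, i], vals[:, j])[0, 1]
            assert abs(r) <= 0.95


class TestOrderedSplit:
    def test_30_compounds_80_20(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(30)
        train, test = ordered_split(y, 5)
        assert len(train) == 24 and len(test) == 6
        assert sorted(np.concatenate([train, test])) == list(range(30))

    def test_every_fifth_by_descending_response(self):
        y = np.arange(30, 0, -1)  # already descending
        train, test = ordered_split(y, 5)
        np.testing.assert_array_equal(test, [4, 9, 14, 19, 24, 29])

    def test_five_distinct_takes_smallest(self):
        y = [3.0, 1.0, 5.0, 2.0, 4.0]
        _, test = ordered_split(y, 5)
        np.testing.assert_array_equal(test, [1])

    def test_ties_broken_by_row_order(self):
        y = np.zeros(10)
        _, test = ordered_split(y, 5)
        np.testing.assert_array_equal(test, [4, 9])

    def test_too_few_rows_warns_empty_test(self):
        with pytest.warns(UserWarning):
            train, test = ordered_split([1.0, 2.0, 3.0], 5)
        assert len(train) == 3 and len(test) == 0

    @pytest.mark.parametrize("n", [5, 10, 20, 25, 30])
    def test_partition_sizes_for_multiples_of_five(self, n):
        y = np.random.default_rng(n).standard_normal(n)
        train, test = ordered_split(y, 5)
        assert len(test) == n // 5
        assert len(train) == n - n // 5


class TestFitPredict:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = 0.3 + X @ beta
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(0.3, abs=1e-10)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-10)

    def test_zero_variance_column_rank_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ModelingError, match="x0"):
            fit_mlr(X, np.arange(10.0))

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        model = fit_mlr(X, y)
        d = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(d.T @ d, d.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        model = fit_mlr(X, y)
        resid = y - predict(model, X)
        assert abs(resid.sum()) < 1e-9
        np.testing.assert_allclose(X.T @ resid, 0, atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        model = fit_mlr(
            np.random.default_rng(0).standard_normal((10, 2)),
            np.arange(10.0),
            names=["A", "B"],
        )
        p = tmp_path / "m.json"
        model.to_json(p)
        again = MLRModel.from_json(p)
        assert again == model


class TestFixtureModels:
    def test_q_model_terms(self):
        model = load_fixture_model("Q")
        assert model.n_descriptors == 4
        assert model.descriptor_names == ["Mor10m", "Mor17m", "E1v", "H8m"]
        assert model.intercept == pytest.approx(-0.487)

    def test_r_model_terms(self):
        model = load_fixture_model("R")
        assert model.n_descriptors == 4
        assert model.descriptor_names == ["SIC0", "Mor17m", "Mor22m", "Mor25m"]
        assert model.intercept == pytest.approx(4.879)

    def test_zero_row_evaluates_to_intercept(self):
        zero = np.zeros((1, 4))
        assert predict(load_fixture_model("Q"), zero)[0] == pytest.approx(
            -0.487
        )
        assert predict(load_fixture_model("R"), zero)[0] == pytest.approx(
            4.879
        )

    def test_single_term_hand_evaluation(self):
        # Mor17m = 1, all other descriptors 0
        model = load_fixture_model("Q")
        x = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert predict(model, x)[0] == pytest.approx(-0.487 + 3.970)

    def test_missing_column_named_in_error(self):
        m = DescriptorMatrix(
            ["a", "b", "c"],
            ["Mor10m", "E1v", "H8m"],
            np.zeros((3, 3)),
        )
        with pytest.raises(ModelingError, match="Mor17m"):
            predict(load_fixture_model("Q"), m)


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_compounds=30,
        n_descriptors=50,
        informative=[(3, 2.0), (11, 4.0), (27, 3.3), (40, -2.8)],
        noise_sd=0.5,
        seed=17,
    )
    return generate(spec)


class TestGASelect:
    def test_recovers_planted_set_low_noise(self, planted):
        m, y, truth = planted
        ranked = ga_select(m, y, GAConfig(seed=4))
        assert set(ranked[0].descriptor_names) == set(
            truth["informative_names"]
        )

    def test_deterministic_given_seed(self, planted):
        m, y, _ = planted
        cfg = GAConfig(seed=12, generations=30)
        a = ga_select(m, y, cfg)
        b = ga_select(m, y, GAConfig(seed=12, generations=30))
        assert [r.descriptor_names for r in a] == [
            r.descriptor_names for r in b
        ]
        assert [r.fitness for r in a] == [r.fitness for r in b]

    def test_matches_exhaustive_optimum_small_pool(self):
        """GA's winner equals the global best 4-subset of 15 columns."""
        spec = SyntheticSpec(
            n_compounds=30,
            n_descriptors=15,
            informative=[(1, 2.0), (4, 4.0), (9, 3.3), (13, -2.8)],
            noise_sd=2.2,
            seed=3,
        )
        m, y, _ = generate(spec)
        best_f, best_cols = -np.inf, None
        for cols in itertools.combinations(range(15), 4):
            f = q2_loo(m.values[:, cols], y)[0]
            if f > best_f:
                best_f, best_cols = f, cols
        ranked = ga_select(m, y, GAConfig(seed=21))
        assert ranked[0].descriptor_names == tuple(
            m.descriptor_names[j] for j in best_cols
        )
        assert ranked[0].fitness == pytest.approx(best_f, abs=1e-12)

    def test_beats_random_subsets(self, planted):
        m, y, _ = planted
        ranked = ga_select(m, y, GAConfig(seed=4, generations=50))
        rng = np.random.default_rng(99)
        random_best = max(
            q2_loo(
                m.values[:, rng.choice(50, size=4, replace=False)], y
            )[0]
            for _ in range(100)
        )
        assert ranked[0].fitness >= random_best

    def test_model_size_too_large_rejected(self, planted):
        m, y, _ = planted
        with pytest.raises(ModelingError):
            ga_select(m, y, GAConfig(model_size=50, seed=1))

    def test_fitness_recomputable_from_descriptor_set(self, planted):
        m, y, _ = planted
        ranked = ga_select(m, y, GAConfig(seed=4, generations=30))
        top = ranked[0]
        sub = m.subset(list(top.descriptor_names))
        assert q2_loo(sub.values, y)[0] == pytest.approx(
            top.fitness, abs=1e-12
        )
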