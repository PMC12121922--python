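"""Wrapper feature selection: fitness, non-dominated sorting, the four metaheuristics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from thermocad.phantoms import planted_feature_table
from thermocad.selection import (
    Objectives,
    SubsetEvaluator,
    das_dennis_reference_points,
    de_select,
    evaluate_subset,
    fast_non_dominated_sort,
    ga_select,
    nsga3_select,
    objective_vs_k_curve,
    pso_select,
)


def brute_force_fronts(F):
    """Oracle: repeated O(n^2) pairwise-domination scan."""
    F = np.asarray(F, dtype=float)
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                np.all(F[j] <= F[i]) and np.any(F[j] < F[i]) for j in remaining if j != i
            )
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def separable_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 4))
    X[:, 0] += 10.0 * y  # one perfectly separating feature
    return pd.DataFrame(X, columns=list("abcd")), y


class TestEvaluateSubset:
    def test_separable_data_zero_error(self):
        table, y = separable_table()
        obj = evaluate_subset(np.ones(4, bool), table, y, seed=0)
        assert obj.error == 0.0
        assert obj.nf_frac == 1.0

    def test_nf_frac_arithmetic(self):
        bits = np.zeros(25, bool)
        bits[:8] = True
        table = pd.DataFrame(np.random.default_rng(0).standard_normal((40, 25)))
        y = np.repeat([0, 1], 20)
        assert evaluate_subset(bits, table, y).nf_frac == pytest.approx(0.32)

    def test_pure_noise_features_chance_level(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(rng.standard_normal((200, 5)))
            y = np.repeat([0, 1], 100)
            errs.append(evaluate_subset(np.ones(5, bool), table, y, seed=seed).error)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.1)

    def test_empty_subset_repaired_with_warning(self):
        table, y = separable_table()
        ev = SubsetEvaluator(table, y, seed=0)
        with pytest.warns(RuntimeWarning, match="repaired"):
            obj = ev(np.zeros(4, bool))
        assert obj.nf_frac == pytest.approx(0.25)
        assert obj.error == 0.0  # the best univariate feature is the separating one

    def test_deterministic_for_fixed_seed(self):
        table, y = separable_table(seed=3)
        a = evaluate_subset(np.array([1, 0, 1, 0], bool), table, y, seed=5)
        b = evaluate_subset(np.array([1, 0, 1, 0], bool), table, y, seed=5)
        assert a == b


class TestNonDominatedSorting:
    def test_known_six_point_configuration(self):
        F = np.array([[1, 5], [2, 4], [3, 3], [2, 6], [4, 4], [1.5, 4.5]])
        fronts = fast_non_dominated_sort(F)
        assert sorted(fronts[0].tolist()) == [0, 1, 2, 5]
        assert sorted(fronts[1].tolist()) == [3, 4]

    def test_matches_brute_force_on_random_populations(self, rng):
        for _ in range(20):
            F = rng.random((rng.integers(5, 40), 2))
            got = [sorted(f.tolist()) for f in fast_non_dominated_sort(F)]
            assert got == brute_force_fronts(F)

    def test_reference_points_cover_simplex(self):
        refs = das_dennis_reference_points(2, 30)
        assert refs.shape == (30, 2)
        np.testing.assert_allclose(refs.sum(1), 1.0)


class TestMetaheuristics:
    def test_nsga3_pareto_mutually_nondominated(self):
        table, y, _ = planted_feature_table(80, 2, 6, seed=0)
        res = nsga3_select(table, y, seed=0, n_gen=5)
        F = np.array([[o.error, o.nf_frac] for _, o in res.pareto])
        assert len(brute_force_fronts(F)) == 1

    def test_nsga3_bit_reproducible(self):
        table, y, _ = planted_feature_table(80, 2, 6, seed=1)
        a = nsga3_select(table, y, seed=3, n_gen=4)
        b = nsga3_select(table, y, seed=3, n_gen=4)
        assert np.array_equal(a.chosen_bits, b.chosen_bits)
        assert a.history == b.history

    def test_nsga3_no_variation_keeps_population(self):
        table, y, _ = planted_feature_table(60, 2, 4, seed=2)
        ev = SubsetEvaluator(table, y, seed=0)
        res = nsga3_select(table, y, seed=0, n_gen=1, p_crossover=0.0, p_mutation=0.0,
                           evaluator=ev)
        # with no offspring, environmental selection can only return initial members
        rng = np.random.default_rng(0)
        init = {ev.repair(rng.random(6) < 0.5).tobytes() for _ in range(30)}
        assert all(bits.tobytes() in init for bits, _ in res.pareto)

    def test_nsga3_population_floor(self):
        table, y, _ = planted_feature_table(60, 2, 4, seed=0)
        with pytest.raises(ValueError, match="at least 4"):
            nsga3_select(table, y, n_pop=2)

    def test_ga_history_nonincreasing_elitist(self):
        table, y, _ = planted_feature_table(80, 2, 8, seed=0)
        res = ga_select(table, y, seed=0, n_gen=10)
        assert all(b <= a + 1e-12 for a, b in zip(res.history, res.history[1:]))

    def test_pso_history_nonincreasing(self):
        table, y, _ = planted_feature_table(80, 2, 8, seed=0)
        res = pso_select(table, y, seed=0, n_gen=8)
        assert all(b <= a + 1e-12 for a, b in zip(res.history, res.history[1:]))

    def test_de_beats_all_features_genome(self):
        table, y, _ = planted_feature_table(100, 2, 10, seed=4)
        ev = SubsetEvaluator(table, y, seed=4)
        res = de_select(table, y, seed=4, evaluator=ev)
        j_all = ev(np.ones(12, bool)).scalar()
        assert res.best_scalar <= j_all + 1e-12

    @pytest.mark.parametrize("select", [ga_select, pso_select, de_select])
    def test_single_objective_methods_reproducible(self, select):
        table, y, _ = planted_feature_table(60, 2, 4, seed=5)
        a = select(table, y, seed=1, n_gen=3)
        b = select(table, y, seed=1, n_gen=3)
        assert np.array_equal(a.chosen_bits, b.chosen_bits)
        assert a.best_scalar == b.best_scalar


class TestObjectiveCurve:
    def test_elbow_well_defined_on_monotone_curve(self):
        pareto = [
            (np.array([True] + [False] * 4), Objectives(0.30, 0.2)),
            (np.array([True, True] + [False] * 3), Objectives(0.10, 0.4)),
            (np.array([True] * 3 + [False] * 2), Objectives(0.096, 0.6)),
            (np.array([True] * 4 + [False]), Objectives(0.09, 0.8)),
        ]
        from thermocad.selection import SelectionResult

        res = SelectionResult(pareto=pareto, best_scalar=0.09, chosen_bits=pareto[2][0],
                              chosen_subset=[], history=[], runtime=0.0, method="x")
        curve = objective_vs_k_curve(res, epsilon=0.01)
        assert curve.loc[curve.is_elbow, "k"].tolist() == [2]

    def test_single_point_pareto(self):
        from thermocad.selection import SelectionResult

        pareto = [(np.array([True, False]), Objectives(0.2, 0.5))]
        res = SelectionResult(pareto=pareto, best_scalar=0.2, chosen_bits=pareto[0][0],
                              chosen_subset=["a"], history=[], runtime=0.0, method="x")
        curve = objective_vs_k_curve(res)
        assert len(curve) == 1 and bool(curve.is_elbow.iloc[0])

    def test_planted_recovery_small(self):
        """3 informative features recovered on a small planted problem."""
        table, y, info = planted_feature_table(120, 3, 5, effect_size=2.0, seed=6)
        res = nsga3_select(table, y, seed=6, n_gen=10)
        assert all(n in res.chosen_subset for n in info)
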