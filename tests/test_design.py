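"""Factor space, model-matrix coding and D-optimal exchange construction."""

import itertools

import numpy as np
import pytest

from dllmeopt.design import (
    Condition,
    FactorSpace,
    ModelSpec,
    REDUCED_ETHYL_OCTANOATE_TERMS,
    d_criterion,
    d_optimal_design,
    enumerate_grid,
    model_matrix,
)


def line_spec():
    return ModelSpec(("intercept", "main(X2)"))


class TestFactorSpace:
    def test_default_levels(self, space):
        assert len(space.extraction_solvent_levels) == 5
        assert len(space.extraction_volume_levels) == 5
        assert len(space.disperser_solvent_levels) == 3
        assert len(space.disperser_volume_levels) == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"extraction_solvent_levels": ()},
            {"extraction_volume_levels": (500, 500, 1000, 1500, 2000)},
            {"extraction_volume_levels": (2000, 1500, 1000, 750, 500)},
            {"reference_extraction_solvent": "ether"},
            {"reference_disperser_solvent": "water"},
        ],
    )
    def test_invalid_spaces_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FactorSpace(**kwargs)


class TestEnumerateGrid:
    def test_full_grid_has_225_conditions(self, space, grid):
        assert len(grid) == 225
        assert len(set(grid)) == 225

    def test_grid_length_is_product_of_level_counts(self, toy_line_space):
        assert len(enumerate_grid(toy_line_space)) == 4
        two_by_two = FactorSpace(
            extraction_solvent_levels=("a", "b"),
            extraction_volume_levels=(1, 2),
            disperser_solvent_levels=("x",),
            disperser_volume_levels=(1,),
            reference_extraction_solvent="a",
            reference_disperser_solvent="x",
        )
        assert len(enumerate_grid(two_by_two)) == 4
        one = FactorSpace(
            extraction_solvent_levels=("a",),
            extraction_volume_levels=(1,),
            disperser_solvent_levels=("x",),
            disperser_volume_levels=(1,),
            reference_extraction_solvent="a",
            reference_disperser_solvent="x",
        )
        assert len(enumerate_grid(one)) == 1

    def test_enumeration_order_is_nested_field_order(self, space, grid):
        # first block holds the reference solvent at the smallest volumes
        assert grid[0] == Condition("chloroform", 500, "acetone", 500)
        assert grid[1] == Condition("chloroform", 500, "acetone", 1000)
        assert grid[-1] == Condition("CH:P (2:1)", 2000, "methanol", 1500)


class TestModelMatrix:
    def test_reference_level_row(self, space):
        X, labels = model_matrix(
            [Condition("chloroform", 500, "acetone", 500)], ModelSpec(), space
        )
        row = dict(zip(labels, X[0]))
        assert row["intercept"] == 1
        assert row["X2"] == 500 and row["X2^2"] == 250_000
        assert row["X4"] == 500 and row["X4^2"] == 250_000
        dummy_cols = [lab for lab in labels if "[" in lab]
        assert all(row[lab] == 0 for lab in dummy_cols)

    def test_full_spec_has_25_columns(self, space, grid):
        X, labels = model_matrix(grid, ModelSpec(), space)
        # 1 + 4 + 1 + 1 + 2 + 1 + 1 + 4 + 2 + 8
        assert len(labels) == 25
        assert X.shape == (225, 25)
        assert np.linalg.matrix_rank(X) == 25

    def test_pentane_row_under_reduced_spec(self, space, reduced_spec):
        X, labels = model_matrix(
            [Condition("pentane", 500, "acetone", 1500)], reduced_spec, space
        )
        row = dict(zip(labels, X[0]))
        assert row["X1[pentane]"] == 1
        assert row["X2"] == 500
        assert row["X1[pentane]:X2"] == 500
        assert row["X3[acetonitrile]"] == 0 and row["X3[methanol]"] == 0

    def test_condition_outside_space_names_offender(self, space):
        with pytest.raises(ValueError, match="ether"):
            model_matrix([Condition("ether", 500, "acetone", 500)], ModelSpec(), space)


class TestDCriterion:
    def test_hand_computed_two_run_determinants(self, toy_line_space):
        grid = enumerate_grid(toy_line_space)
        # det [[1,1],[v1,v2]]ᵀ[[..]] = (v2 − v1)²
        d14 = d_criterion([grid[0], grid[3]], line_spec(), toy_line_space)
        d23 = d_criterion([grid[1], grid[2]], line_spec(), toy_line_space)
        assert d14 == pytest.approx(9.0)
        assert d23 == pytest.approx(1.0)

    def test_duplicated_point_is_singular(self, toy_line_space):
        grid = enumerate_grid(toy_line_space)
        assert d_criterion([grid[1], grid[1]], line_spec(), toy_line_space) == 0.0

    def test_permutation_invariance(self, space, grid):
        runs = [grid[i] for i in range(0, 225, 15)] * 2
        spec = ModelSpec(REDUCED_ETHYL_OCTANOATE_TERMS)
        a = d_criterion(runs, spec, space)
        b = d_criterion(list(reversed(runs)), spec, space)
        assert a == pytest.approx(b, rel=1e-9)
        assert a > 0


class TestDOptimalDesign:
    def test_toy_two_run_optimum_is_extreme_pair(self, toy_line_space):
        # exhaustive search over all unordered pairs shows the end points win
        grid = enumerate_grid(toy_line_space)
        brute = max(
            itertools.combinations_with_replacement(range(4), 2),
            key=lambda pair: d_criterion(
                [grid[i] for i in pair], line_spec(), toy_line_space
            ),
        )
        des = d_optimal_design(toy_line_space, line_spec(), n_runs=2, seed=0, n_starts=5)
        assert sorted(c.x2 for c in des.runs) == sorted(grid[i].x2 for i in brute)
        assert {c.x2 for c in des.runs} == {1.0, 4.0}

    def test_matches_exhaustive_optimum_on_small_candidate_sets(self):
        # 10 candidates (5 volumes × 2 disperser volumes), 3 runs, 3 parameters
        sp = FactorSpace(
            extraction_solvent_levels=("a",),
            extraction_volume_levels=(1, 2, 3, 4, 5),
            disperser_solvent_levels=("x",),
            disperser_volume_levels=(1, 2),
            reference_extraction_solvent="a",
            reference_disperser_solvent="x",
        )
        spec = ModelSpec(("intercept", "main(X2)", "main(X4)"))
        grid = enumerate_grid(sp)
        brute_best = max(
            d_criterion([grid[i] for i in combo], spec, sp)
            for combo in itertools.combinations_with_replacement(range(len(grid)), 3)
        )
        des = d_optimal_design(sp, spec, n_runs=3, seed=3, n_starts=20)
        assert d_criterion(list(des.runs), spec, sp) == pytest.approx(brute_best, rel=1e-9)

    def test_sixty_run_design_is_estimable_and_beats_random(self, space, grid):
        spec = ModelSpec()
        des = d_optimal_design(space, spec, n_runs=60, seed=11, n_starts=10)
        assert des.n_runs == 60
        X, labels = model_matrix(list(des.runs), spec, space)
        assert np.linalg.matrix_rank(X) == len(labels)
        crit = d_criterion(list(des.runs), spec, space)
        rng = np.random.default_rng(11)
        for _ in range(100):
            rand = [grid[i] for i in rng.integers(0, len(grid), 60)]
            assert crit >= d_criterion(rand, spec, space)

    def test_fewer_runs_than_parameters_errors(self, space):
        with pytest.raises(ValueError, match="inestimable"):
            d_optimal_design(space, ModelSpec(), n_runs=10, seed=0)

    def test_deterministic_given_seed(self, space):
        spec = ModelSpec(REDUCED_ETHYL_OCTANOATE_TERMS)
        a = d_optimal_design(space, spec, n_runs=15, seed=7, n_starts=5)
        b = d_optimal_design(space, spec, n_runs=15, seed=7, n_starts=5)
        assert a.runs == b.runs
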