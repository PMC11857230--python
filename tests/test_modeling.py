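"""OLS fitting, partial-F term tests and backward elimination."""

import numpy as np
import pytest

from dllmeopt.design import (
    Design,
    FactorSpace,
    ModelSpec,
    REDUCED_ETHYL_OCTANOATE_TERMS,
    enumerate_grid,
)
from dllmeopt.modeling import _fit, backward_eliminate, fit_model
from dllmeopt.synthetic import (
    ETHYL_OCTANOATE_TRUTH,
    GroundTruthModel,
    SyntheticStudyConfig,
    generate_design_responses,
)


class TestFitModel:
    def test_noiseless_fit_recovers_printed_coefficients(
        self, space, grid, eo_noiseless, reduced_spec
    ):
        m = _fit(grid, eo_noiseless, reduced_spec, "ethyl octanoate", space)
        assert m.coefficients["intercept"] == pytest.approx(58_296, rel=1e-8)
        assert m.coefficients["X1[pentane]"] == pytest.approx(173_542, rel=1e-8)
        assert m.coefficients["X3[acetonitrile]"] == pytest.approx(-29_513, rel=1e-8)
        assert m.coefficients["X2"] == pytest.approx(36, rel=1e-8)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-6)
        assert m.r_squared == pytest.approx(1.0)

    def test_exact_line_on_toy_space(self, toy_line_space):
        grid = enumerate_grid(toy_line_space)
        y = 2.0 + 3.0 * np.array([c.x2 for c in grid])
        m = _fit(grid, y, ModelSpec(("intercept", "main(X2)")), "toy", toy_line_space)
        assert m.coefficients["intercept"] == pytest.approx(2.0)
        assert m.coefficients["X2"] == pytest.approx(3.0)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_underdetermined_fit_errors(self, space, grid):
        with pytest.raises(ValueError, match="underdetermined"):
            _fit(grid[:10], np.arange(10.0), ModelSpec(), "x", space)

    def test_all_non_detect_analyte_errors(self, space, grid):
        truth = GroundTruthModel(
            "gone", {"intercept": 1.0},
            failing_solvents=frozenset(space.extraction_solvent_levels),
        )
        design = Design(runs=tuple(grid))
        tab = generate_design_responses(
            design, [truth], SyntheticStudyConfig(seed=0, n_replicates=1), space
        )
        with pytest.raises(ValueError, match="unmodellable"):
            fit_model(tab, design, ModelSpec(), analyte="gone", space=space)

    def test_non_detect_rows_are_excluded_not_imputed(self, space, grid):
        truth = GroundTruthModel(
            "eo", dict(ETHYL_OCTANOATE_TRUTH.coefficients),
            noise_cv=0.0, failing_solvents=frozenset({"pentane"}),
        )
        design = Design(runs=tuple(grid))
        tab = generate_design_responses(
            design, [truth], SyntheticStudyConfig(seed=0, n_replicates=1), space
        )
        # fit on the 4 surviving solvents: restrict the space so the pentane
        # dummy (all-zero after exclusion) is not in the matrix
        sub = FactorSpace(
            extraction_solvent_levels=("chloroform", "DCM", "hexane", "CH:P (2:1)"),
            reference_extraction_solvent="chloroform",
        )
        m = fit_model(tab, design, ModelSpec(REDUCED_ETHYL_OCTANOATE_TERMS),
                      analyte="eo", space=sub)
        assert m.n_obs == 180  # 225 − 45 pentane runs
        assert m.coefficients["intercept"] == pytest.approx(58_296, rel=1e-8)

    def test_rank_deficiency_names_collinear_columns(self, space):
        # a single condition repeated cannot separate intercept from X2
        grid = [enumerate_grid(space)[0]] * 30
        y = np.ones(30)
        with pytest.raises(ValueError, match="collinear|rank"):
            _fit(grid, y, ModelSpec(("intercept", "main(X2)")), "x", space)

    def test_partial_f_equals_squared_t_for_single_column_term(self, space, grid):
        rng = np.random.default_rng(2)
        y = ETHYL_OCTANOATE_TRUTH.linear_predictor(grid, space) * (
            1 + rng.normal(0, 0.05, len(grid))
        )
        m = _fit(grid, y, ModelSpec(REDUCED_ETHYL_OCTANOATE_TERMS), "eo", space)
        from scipy import stats

        t = m.coefficients["X2"] / m.std_errors["X2"]
        p_t = 2 * stats.t.sf(abs(t), m.n_obs - len(m.coefficients))
        assert m.term_pvalues["main(X2)"] == pytest.approx(p_t, rel=1e-6)

    def test_agrees_with_statsmodels_ols(self, space, grid, reduced_spec):
        import statsmodels.api as sm

        from dllmeopt.design import model_matrix

        rng = np.random.default_rng(3)
        y = ETHYL_OCTANOATE_TRUTH.linear_predictor(grid, space) * (
            1 + rng.normal(0, 0.05, len(grid))
        )
        m = _fit(grid, y, reduced_spec, "eo", space)
        X, labels = model_matrix(grid, reduced_spec, space)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(
            [m.coefficients[lab] for lab in labels], ref.params, rtol=1e-8
        )
        assert np.allclose(
            [m.std_errors[lab] for lab in labels], ref.bse, rtol=1e-6
        )
        assert m.r_squared == pytest.approx(ref.rsquared, rel=1e-8)


class TestBackwardElimination:
    def test_low_noise_data_retains_the_four_true_terms(self, space, grid):
        rng = np.random.default_rng(0)
        y = ETHYL_OCTANOATE_TRUTH.linear_predictor(grid, space) * (
            1 + rng.normal(0, 0.02, len(grid))
        )
        full = _fit(grid, y, ModelSpec(), "eo", space)
        red = backward_eliminate(full, alpha=0.05)
        assert set(red.spec.terms) == {
            "intercept", "main(X1)", "main(X2)", "main(X3)", "inter(X1,X2)",
        }

    def test_elimination_is_monotone_and_idempotent(self, space, grid):
        rng = np.random.default_rng(1)
        y = ETHYL_OCTANOATE_TRUTH.linear_predictor(grid, space) * (
            1 + rng.normal(0, 0.1, len(grid))
        )
        full = _fit(grid, y, ModelSpec(), "eo", space)
        red = backward_eliminate(full, alpha=0.05)
        assert set(red.spec.terms) <= set(full.spec.terms)
        refit = _fit(grid, y, red.spec, "eo", space)
        for lab, val in red.coefficients.items():
            assert refit.coefficients[lab] == pytest.approx(val, rel=1e-10)
        again = backward_eliminate(red, alpha=0.05)
        assert again.spec.terms == red.spec.terms

    def test_all_significant_model_is_a_fixed_point(self, space, grid, reduced_spec):
        y = ETHYL_OCTANOATE_TRUTH.linear_predictor(grid, space) * (
            1 + np.random.default_rng(4).normal(0, 0.02, len(grid))
        )
        m = _fit(grid, y, reduced_spec, "eo", space)
        assert all(p < 0.05 for p in m.term_pvalues.values())
        assert backward_eliminate(m).spec.terms == m.spec.terms

    def test_heredity_protects_mains_of_retained_interactions(self, space, grid):
        # truth has a strong X1:X2 interaction but a weak X2 main effect;
        # with heredity on, main(X2) must survive while inter(X1,X2) does
        coef = dict(ETHYL_OCTANOATE_TRUTH.coefficients)
        coef["X2"] = 0.01
        truth = GroundTruthModel("h", coef, noise_cv=0.0)
        rng = np.random.default_rng(5)
        y = truth.linear_predictor(grid, space) * (1 + rng.normal(0, 0.05, len(grid)))
        full = _fit(grid, y, ModelSpec(), "h", space)
        red = backward_eliminate(full, alpha=0.05, heredity=True)
        if "inter(X1,X2)" in red.spec.terms:
            assert "main(X1)" in red.spec.terms
            assert "main(X2)" in red.spec.terms

    def test_intercept_only_truth_eliminates_everything_at_typical_seeds(
        self, toy_line_space
    ):
        grid = enumerate_grid(toy_line_space) * 10
        eliminated = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 100.0 * (1 + rng.normal(0, 0.05, len(grid)))
            m = _fit(grid, y, ModelSpec(("intercept", "main(X2)", "quad(X2)")),
                     "flat", toy_line_space)
            red = backward_eliminate(m, alpha=0.05)
            eliminated += red.spec.terms == ("intercept",)
        assert eliminated >= 17  # ≈ (1 − α)² of seeds keep nothing
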