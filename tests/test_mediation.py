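import numpy as np
import pandas as pd
import pytest

from waveconn import (
    PathModelSpec,
    fit_path_model,
    indirect_effect,
    residualize,
    trim_model,
)


def simulate_mediation(rng, n, a=-0.5, b=0.4, c=-0.3):
    x = rng.normal(size=n)
    m = a * x + rng.normal(size=n)
    y = b * m + c * x + rng.normal(size=n)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


MEDIATOR_SPEC = PathModelSpec(("X", "M", "Y"), (("X", "M"), ("M", "Y"), ("X", "Y")))


class TestResidualize:
    def test_orthogonal_covariate_returns_centered_target(self, rng):
        n = 200
        cov = np.cos(2 * np.pi * np.arange(n) / n)
        y = rng.normal(size=n)
        y -= np.dot(y, cov) / np.dot(cov, cov) * cov
        df = pd.DataFrame({"y": y, "c": cov})
        out = residualize(df, ["y"], ["c"])
        assert np.allclose(out["y"], y - y.mean(), atol=1e-10)
        assert "c" not in out.columns

    def test_collinear_target_vanishes(self, rng):
        c = rng.normal(size=100)
        df = pd.DataFrame({"y": 2 * c, "c": c})
        assert np.abs(residualize(df, ["y"], ["c"])["y"]).max() < 1e-10

    def test_matches_pseudoinverse_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(120, 4)), columns=["y1", "y2", "c1", "c2"])
        design = np.column_stack((np.ones(120), df[["c1", "c2"]]))
        expected = df[["y1", "y2"]].to_numpy() - design @ (
            np.linalg.pinv(design) @ df[["y1", "y2"]].to_numpy()
        )
        out = residualize(df, ["y1", "y2"], ["c1", "c2"])
        assert np.allclose(out[["y1", "y2"]], expected, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        c = rng.normal(size=50)
        df = pd.DataFrame({"y": rng.normal(size=50), "c1": c, "c2": c})
        with pytest.raises(ValueError, match="rank"):
            residualize(df, ["y"], ["c1", "c2"])


class TestPathModelSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec(("A", "B"), (("A", "B"), ("B", "A")))

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PathModelSpec(("A", "B"), (("A", "B"), ("A", "B")))

    def test_exogenous_partition(self):
        assert MEDIATOR_SPEC.exogenous == ("X",)
        assert MEDIATOR_SPEC.endogenous == ("M", "Y")

    def test_text_roundtrip(self):
        text = "X -> M\nM -> Y\nX -> Y\n"
        spec = PathModelSpec.from_text(text)
        assert spec.edges == MEDIATOR_SPEC.edges
        assert spec.to_text() == text

    def test_df_counting(self):
        # p=3 -> 6 moments; saturated mediator model: 3 edges + 2 psi + 1 phi
        assert MEDIATOR_SPEC.degrees_of_freedom() == 0
        assert MEDIATOR_SPEC.without_edge(("X", "Y")).degrees_of_freedom() == 1


class TestFitPathModel:
    def test_saturated_model_fits_exactly(self, rng):
        fit = fit_path_model(MEDIATOR_SPEC, simulate_mediation(rng, 300))
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0 and fit.rmsea == 0.0 and fit.cfi == 1.0

    def test_estimates_equal_equationwise_ols(self, rng):
        """ML for recursive models = per-equation OLS (statsmodels oracle)."""
        import statsmodels.api as sm

        df = simulate_mediation(rng, 400)
        fit = fit_path_model(MEDIATOR_SPEC, df)
        ols_m = sm.OLS(df["M"], sm.add_constant(df["X"])).fit()
        ols_y = sm.OLS(df["Y"], sm.add_constant(df[["M", "X"]])).fit()
        assert fit.estimate("X", "M").unstandardized == pytest.approx(ols_m.params["X"], abs=1e-6)
        assert fit.estimate("M", "Y").unstandardized == pytest.approx(ols_y.params["M"], abs=1e-6)
        assert fit.estimate("X", "Y").unstandardized == pytest.approx(ols_y.params["X"], abs=1e-6)
        assert fit.estimate("X", "M").p == pytest.approx(ols_m.pvalues["X"], abs=1e-8)
        assert fit.estimate("M", "Y").se == pytest.approx(ols_y.bse["M"], abs=1e-8)

    def test_parameter_recovery_large_n(self, rng):
        df = simulate_mediation(rng, 2000)
        fit = fit_path_model(MEDIATOR_SPEC, df)
        assert fit.estimate("X", "M").unstandardized == pytest.approx(-0.5, abs=0.05)
        assert fit.estimate("M", "Y").unstandardized == pytest.approx(0.4, abs=0.05)
        assert fit.estimate("X", "Y").unstandardized == pytest.approx(-0.3, abs=0.05)

    def test_ml_equals_ols_on_random_recursive_models(self, rng):
        """Property: for random 4-variable recursive models, every coefficient
        equals the corresponding OLS regression coefficient."""
        import statsmodels.api as sm

        names = ("A", "B", "C", "D")
        for _ in range(5):
            data = pd.DataFrame(rng.normal(size=(150, 4)), columns=names)
            edges = tuple(
                (names[i], names[j])
                for i in range(4)
                for j in range(i + 1, 4)
                if rng.random() < 0.6
            )
            if not edges:
                continue
            spec = PathModelSpec(names, edges)
            fit = fit_path_model(spec, data)
            for target in spec.endogenous:
                parents = list(spec.parents(target))
                ols = sm.OLS(data[target], sm.add_constant(data[parents])).fit()
                for src in parents:
                    assert fit.estimate(src, target).unstandardized == pytest.approx(
                        ols.params[src], abs=1e-8
                    )

    def test_chi_square_scale_invariance(self, rng):
        df = simulate_mediation(rng, 500)
        spec = MEDIATOR_SPEC.without_edge(("X", "Y"))
        fit = fit_path_model(spec, df)
        scaled = df * np.array([10.0, 0.2, 7.0])
        fit_scaled = fit_path_model(spec, scaled)
        assert fit_scaled.chi_square == pytest.approx(fit.chi_square, rel=1e-8)
        assert fit_scaled.estimate("X", "M").standardized == pytest.approx(
            fit.estimate("X", "M").standardized, abs=1e-10
        )

    def test_fit_indices_in_range(self, rng):
        df = simulate_mediation(rng, 200, b=0.0)
        spec = MEDIATOR_SPEC.without_edge(("M", "Y"))
        fit = fit_path_model(spec, df)
        assert 0.0 <= fit.cfi <= 1.0
        assert fit.rmsea >= 0.0
        assert fit.df == 1
        assert 0.0 <= fit.p_fit <= 1.0

    def test_overparameterized_rejected(self):
        # 2 variables: 3 moments; 2 edges impossible (cyclic) so use 3 vars
        # with every edge plus an extra exogenous covariance -> df stays >= 0;
        # instead check n <= p rejection.
        data = pd.DataFrame(np.eye(3), columns=["X", "M", "Y"])
        with pytest.raises(ValueError, match="n >"):
            fit_path_model(MEDIATOR_SPEC, data)

    def test_r_squared_reported(self, rng):
        fit = fit_path_model(MEDIATOR_SPEC, simulate_mediation(rng, 1000))
        assert set(fit.r_squared) == {"M", "Y"}
        assert all(0 <= v < 1 for v in fit.r_squared.values())


class TestIndirectEffect:
    def test_planted_product_recovered(self, rng):
        df = simulate_mediation(rng, 500)
        eff = indirect_effect(MEDIATOR_SPEC, df, ("X", "M", "Y"), n_boot=1000, seed=7)
        assert eff.point_estimate == pytest.approx(-0.2, abs=0.06)
        assert eff.ci_high < 0  # CI excludes zero

    def test_bootstrap_reproducible_under_seed(self, rng):
        df = simulate_mediation(rng, 150)
        a = indirect_effect(MEDIATOR_SPEC, df, ("X", "M", "Y"), n_boot=200, seed=11)
        b = indirect_effect(MEDIATOR_SPEC, df, ("X", "M", "Y"), n_boot=200, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_single_replicate_degenerate_ci(self, rng):
        df = simulate_mediation(rng, 100)
        eff = indirect_effect(MEDIATOR_SPEC, df, ("X", "M", "Y"), n_boot=1, seed=5)
        assert eff.ci_low == eff.ci_high

    def test_missing_edge_rejected(self, rng):
        df = simulate_mediation(rng, 100)
        with pytest.raises(ValueError, match="not in model"):
            indirect_effect(MEDIATOR_SPEC, df, ("M", "X"), n_boot=10, seed=0)


class TestTrimModel:
    def test_strong_paths_survive(self, rng):
        df = simulate_mediation(rng, 800)
        spec, fit = trim_model(MEDIATOR_SPEC, df)
        assert spec.edges == MEDIATOR_SPEC.edges
        assert all(e.p <= 0.05 for e in fit.estimates.values())

    def test_null_direct_path_removed(self, rng):
        removed = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            df = simulate_mediation(local, 500, c=0.0)
            spec, _ = trim_model(MEDIATOR_SPEC, df)
            if ("X", "Y") not in spec.edges and {("X", "M"), ("M", "Y")} <= set(spec.edges):
                removed += 1
        assert removed >= 9

    def test_df_increases_with_removal(self, rng):
        """Dropping a path while the endogenous set is unchanged frees one
        moment: df rises by exactly one per removed edge."""
        df = simulate_mediation(rng, 800, c=0.0)
        spec, fit = trim_model(MEDIATOR_SPEC, df)
        assert spec.edges == (("X", "M"), ("M", "Y"))
        assert fit.df == MEDIATOR_SPEC.degrees_of_freedom() + 1

    def test_df_never_decreases_even_when_variables_orphaned(self, rng):
        """Removing every path into a variable re-classifies it as exogenous
        (its covariances become free), but df still never decreases."""
        df = simulate_mediation(rng, 300, b=0.0, c=0.0)
        spec, fit = trim_model(MEDIATOR_SPEC, df)
        assert fit.df >= MEDIATOR_SPEC.degrees_of_freedom()

    def test_deterministic(self, rng):
        df = simulate_mediation(rng, 200, c=0.0)
        a, _ = trim_model(MEDIATOR_SPEC, df)
        b, _ = trim_model(MEDIATOR_SPEC, df)
        assert a.edges == b.edges
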