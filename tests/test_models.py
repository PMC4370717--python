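"""Spline basis, model fitting, stepwise selection, LOO-CV and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from agribirds.models import (
    ModelSpec,
    backward_stepwise,
    build_design,
    fit_interaction_model,
    fit_model,
    loo_cv_error,
    residual_diagnostics,
    spline_basis,
)
from agribirds.spatial import build_contiguity, lattice_edges
from agribirds.synthetic_data import generate_interaction_response


def linear_data(rng, n=120, slope=2.0, noise=0.1):
    x = rng.uniform(0, 10, n)
    return pd.DataFrame({"y": 3.0 + slope * x + rng.normal(0, noise, n), "x": x})


class TestSplineBasis:
    @pytest.mark.parametrize("df", [1, 2, 3, 5])
    def test_column_count_equals_df(self, rng, df):
        assert spline_basis(rng.uniform(0, 1, 100), df).shape == (100, df)

    def test_df1_fit_equals_straight_line_fit(self, rng):
        d = linear_data(rng)
        smooth = fit_model(ModelSpec(response="y", smooth_terms=(("x", 1),)), d)
        linear = fit_model(ModelSpec(response="y", linear_terms=("x",)), d)
        assert np.allclose(smooth.fittedvalues, linear.fittedvalues, atol=1e-8)

    @pytest.mark.parametrize("a,b", [(1.0, 5.0), (3.5, -100.0), (0.01, 0.0)])
    def test_affine_transform_leaves_fitted_values(self, rng, a, b):
        d = linear_data(rng)
        d["y"] += np.sin(d["x"])
        spec = ModelSpec(response="y", smooth_terms=(("x", 2),))
        f1 = fit_model(spec, d)
        f2 = fit_model(spec, d.assign(x=a * d["x"] + b))
        assert np.allclose(f1.fittedvalues, f2.fittedvalues, atol=1e-7)

    def test_insufficient_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 1.0, 2.0, 2.0]), 3)

    def test_columns_are_centred(self, rng):
        B = spline_basis(rng.uniform(0, 800, 200), 3)
        assert np.allclose(B.mean(axis=0), 0.0, atol=1e-10)


class TestFitModel:
    def test_slope_recovery_in_low_noise(self, rng):
        d = linear_data(rng, noise=0.01)
        fit = fit_model(ModelSpec(response="y", linear_terms=("x",)), d)
        se = fit.bse["x"]
        assert abs(fit.params["x"] - 2.0) < 3 * se

    def test_fitted_plus_residuals_is_observed(self, rng):
        d = linear_data(rng)
        fit = fit_model(ModelSpec(response="y", smooth_terms=(("x", 2),)), d)
        assert np.allclose(fit.fittedvalues + fit.resid, d["y"], atol=1e-10)

    def test_smooth_f_test_nominal_level_under_null(self):
        # y independent of x: the basis-block F-test rejects ~5% of the time
        rng = np.random.default_rng(314)
        rejections = 0
        n_rep = 400
        spec = ModelSpec(response="y", smooth_terms=(("x", 2),))
        for _ in range(n_rep):
            d = pd.DataFrame({"x": rng.uniform(0, 1, 80), "y": 3.0 + rng.normal(0, 1, 80)})
            fit = fit_model(spec, d)
            rejections += fit.term_tests.loc[0, "p"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.075

    def test_rank_deficiency_names_columns(self, rng):
        d = linear_data(rng)
        d["x2"] = 2 * d["x"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_model(ModelSpec(response="y", linear_terms=("x", "x2")), d)

    def test_row_order_invariance(self, rng):
        d = linear_data(rng)
        spec = ModelSpec(response="y", smooth_terms=(("x", 2),))
        f1 = fit_model(spec, d)
        shuffled = d.sample(frac=1, random_state=0)
        f2 = fit_model(spec, shuffled)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)
        assert np.allclose(np.sort(f1.fittedvalues), np.sort(f2.fittedvalues), atol=1e-8)


def exhaustive_best_aic(spec, data):
    """Block-respecting best-subset search: minimal AIC over all droppable subsets."""
    from agribirds.models import _droppable, _fit

    all_terms = spec.term_names()
    droppable = _droppable(all_terms, spec)
    fixed = [t for t in all_terms if t not in droppable]
    best = np.inf
    for r in range(len(droppable) + 1):
        for keep in itertools.combinations(droppable, r):
            terms = [t for t in all_terms if t in fixed or t in keep]
            best = min(best, _fit(spec, data, terms).aic)
    return best


class TestStepwise:
    def test_attains_exhaustive_best_subset_aic(self, rng):
        for _ in range(8):
            n = 80
            X = rng.normal(size=(n, 5))
            y = 1.0 + 1.5 * X[:, 0] + rng.normal(0, 1, n)
            d = pd.DataFrame(X, columns=[f"v{i}" for i in range(5)])
            d["y"] = y
            spec = ModelSpec(response="y", linear_terms=tuple(f"v{i}" for i in range(5)))
            fit = backward_stepwise(spec, d)
            assert fit.aic == pytest.approx(exhaustive_best_aic(spec, d), abs=1e-8)

    def test_true_effect_always_retained_noise_rarely(self):
        rng = np.random.default_rng(2718)
        n_rep, n = 60, 400
        noise_retained = 0
        for _ in range(n_rep):
            X = rng.normal(size=(n, 4))
            y = 2.0 + 1.0 * X[:, 0] + rng.normal(0, 1, n)
            d = pd.DataFrame(X, columns=["true", "n1", "n2", "n3"])
            d["y"] = y
            fit = backward_stepwise(ModelSpec(response="y",
                                              linear_terms=("true", "n1", "n2", "n3")), d)
            assert "true" in fit.terms
            noise_retained += sum(t in fit.terms for t in ("n1", "n2", "n3"))
        # each noise term survives AIC drop-one with prob ~ P(chi2_1 > 2) ~ 0.157
        rate = noise_retained / (3 * n_rep)
        assert 0.05 <= rate <= 0.30

    def test_fixed_point_when_every_term_helps(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = 1.0 + X @ np.array([2.0, -1.5, 1.0]) + rng.normal(0, 0.3, n)
        d = pd.DataFrame(X, columns=["a", "b", "c"])
        d["y"] = y
        spec = ModelSpec(response="y", linear_terms=("a", "b", "c"))
        fit = backward_stepwise(spec, d)
        assert set(fit.terms) == {"a", "b", "c"}

    def test_selected_aic_never_exceeds_maximal(self, rng):
        n = 100
        X = rng.normal(size=(n, 5))
        d = pd.DataFrame(X, columns=[f"v{i}" for i in range(5)])
        d["y"] = rng.normal(size=n)
        spec = ModelSpec(response="y", linear_terms=tuple(f"v{i}" for i in range(5)))
        assert backward_stepwise(spec, d).aic <= fit_model(spec, d).aic + 1e-12

    def test_always_keep_and_hierarchy_respected(self, rng):
        n = 150
        d = pd.DataFrame({
            "x": rng.uniform(0, 1, n),
            "f": rng.integers(0, 2, n).astype(float),
            "junk": rng.normal(size=n),
        })
        d["y"] = rng.normal(size=n)  # nothing matters
        spec = ModelSpec(response="y", linear_terms=("junk",),
                         interaction_terms=(("x", "f"),),
                         always_keep=frozenset({"x:f"}))
        fit = backward_stepwise(spec, d)
        # the interaction is protected, so its main effects must survive too
        assert {"x", "f", "x:f"} <= set(fit.terms)


class TestLooCV:
    def test_perfect_linear_data_zero_error(self, rng):
        x = rng.uniform(1, 10, 50)
        d = pd.DataFrame({"y": 3.0 + 2.0 * x, "x": x})
        assert loo_cv_error(ModelSpec(response="y", linear_terms=("x",)), d) == \
            pytest.approx(0.0, abs=1e-8)

    def test_matches_hat_matrix_identity(self, rng):
        d = linear_data(rng, n=60)
        spec = ModelSpec(response="y", linear_terms=("x",))
        X, _ = build_design(spec, d)
        Xv = X.to_numpy()
        y = d["y"].to_numpy()
        H = Xv @ np.linalg.solve(Xv.T @ Xv, Xv.T)
        e = y - H @ y
        loo_resid = e / (1 - np.diag(H))
        expected = np.mean(np.abs(loo_resid)) / np.mean(y) * 100
        assert loo_cv_error(spec, d) == pytest.approx(expected, abs=1e-10)

    def test_row_shuffle_invariance(self, rng):
        d = linear_data(rng, n=40)
        spec = ModelSpec(response="y", smooth_terms=(("x", 2),))
        a = loo_cv_error(spec, d)
        b = loo_cv_error(spec, d.sample(frac=1, random_state=1))
        assert a == pytest.approx(b, abs=1e-9)

    def test_per_observation_variant(self, rng):
        d = linear_data(rng, n=40)
        spec = ModelSpec(response="y", linear_terms=("x",))
        assert loo_cv_error(spec, d, method="per_obs") > 0


class TestInteractionModel:
    def interaction_data(self, rng, n=332, b3=7.602e-4):
        x = rng.uniform(100, 800, n)
        a = (rng.random(n) < 0.5).astype(float)
        y = 1.779 - 1.165e-3 * x - 0.297 * a + b3 * x * a + rng.normal(0, 0.25, n)
        return pd.DataFrame({"csig": y, "ic_per_ha": x, "aggregated": a})

    def test_recovers_planted_coefficients_within_3se(self, rng):
        d = self.interaction_data(rng)
        spec = ModelSpec(response="csig", interaction_terms=(("ic_per_ha", "aggregated"),))
        fit = fit_interaction_model(spec, d)
        for col, truth in [("ic_per_ha", -1.165e-3), ("aggregated", -0.297),
                           ("ic_per_ha:aggregated", 7.602e-4)]:
            assert abs(fit.params[col] - truth) < 3 * fit.bse[col]

    def test_zero_interaction_t_test_nominal_level(self):
        rng = np.random.default_rng(1618)
        spec = ModelSpec(response="csig", interaction_terms=(("ic_per_ha", "aggregated"),))
        n_rep, rejections = 300, 0
        for _ in range(n_rep):
            d = self.interaction_data(rng, n=150, b3=0.0)
            fit = fit_interaction_model(spec, d)
            p = fit.term_tests.set_index("term").loc["ic_per_ha:aggregated", "p"]
            rejections += p < 0.05
        assert 0.025 <= rejections / n_rep <= 0.08

    def test_group_coding_swap_leaves_fitted_values(self, rng):
        d = self.interaction_data(rng, n=200)
        spec = ModelSpec(response="csig", interaction_terms=(("ic_per_ha", "aggregated"),))
        f1 = fit_interaction_model(spec, d)
        f2 = fit_interaction_model(spec, d.assign(aggregated=1.0 - d["aggregated"]))
        assert np.allclose(f1.fittedvalues, f2.fittedvalues, atol=1e-8)
        # reparameterisation: baseline slope + difference swaps roles
        assert f1.params["ic_per_ha"] + f1.params["ic_per_ha:aggregated"] == \
            pytest.approx(f2.params["ic_per_ha"], abs=1e-10)

    def test_single_level_factor_rejected(self, rng):
        d = self.interaction_data(rng, n=50)
        d["aggregated"] = 1.0
        spec = ModelSpec(response="csig", interaction_terms=(("ic_per_ha", "aggregated"),))
        with pytest.raises(ValueError, match="both values"):
            fit_interaction_model(spec, d)


class TestResidualDiagnostics:
    def diag_setup(self, rng):
        n_sar, sites_per = 25, 4
        sar_ids = [f"R{i}" for i in range(n_sar)]
        w = build_contiguity([(f"R{a}", f"R{b}") for a, b in lattice_edges(5, 5)], sar_ids)
        site_ids = [f"s{i}" for i in range(n_sar * sites_per)]
        site_sar = pd.Series(np.repeat(sar_ids, sites_per), index=site_ids)
        x = rng.uniform(0, 1, len(site_ids))
        y = 1.0 + 0.5 * x + rng.normal(0, 0.1, len(site_ids))
        d = pd.DataFrame({"y": y, "x": x}, index=site_ids)
        return d, site_sar, w, sar_ids

    def test_iid_residuals_pass_all_checks(self, rng):
        d, site_sar, w, sar_ids = self.diag_setup(rng)
        fit = fit_model(ModelSpec(response="y", linear_terms=("x",)), d)
        rep = residual_diagnostics(fit, site_sar, w, sar_ids, n_perm=199, seed=1)
        assert rep.n_sar == 25
        assert not rep.flags["spatially_autocorrelated"]

    def test_planted_smooth_sar_field_detected(self, rng):
        n_sar, sites_per = 25, 4
        sar_ids = [f"R{i}" for i in range(n_sar)]
        w = build_contiguity([(f"R{a}", f"R{b}") for a, b in lattice_edges(5, 5)], sar_ids)
        site_ids = [f"s{i}" for i in range(n_sar * sites_per)]
        site_sar = pd.Series(np.repeat(sar_ids, sites_per), index=site_ids)
        # residual field = smooth gradient over the SAR lattice
        gradient = dict(zip(sar_ids, np.repeat(np.arange(5), 5) + np.tile(np.arange(5), 5)))
        x = rng.uniform(0, 1, len(site_ids))
        y = x * 0.0 + np.array([gradient[s] for s in site_sar]) + rng.normal(0, 0.1, 100)
        d = pd.DataFrame({"y": y, "x": x}, index=site_ids)
        fit = fit_model(ModelSpec(response="y", linear_terms=("x",)), d)
        rep = residual_diagnostics(fit, site_sar, w, sar_ids, n_perm=999, seed=2)
        assert rep.moran_p <= 0.01

    def test_deterministic_given_seed(self, rng):
        d, site_sar, w, sar_ids = self.diag_setup(rng)
        fit = fit_model(ModelSpec(response="y", linear_terms=("x",)), d)
        r1 = residual_diagnostics(fit, site_sar, w, sar_ids, n_perm=199, seed=9)
        r2 = residual_diagnostics(fit, site_sar, w, sar_ids, n_perm=199, seed=9)
        assert (r1.moran_i, r1.moran_p) == (r2.moran_i, r2.moran_p)


class TestInteractionResponseGenerator:
    def test_truth_recorded_and_recoverable(self, small_landscape):
        d = generate_interaction_response(small_landscape, seed=4)
        truth = d.attrs["truth"]
        spec = ModelSpec(response="csig", interaction_terms=(("ic_per_ha", "aggregated"),))
        fit = fit_interaction_model(spec, d)
        assert abs(fit.params["ic_per_ha"] - truth["slope"]) < 4 * fit.bse["ic_per_ha"]
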