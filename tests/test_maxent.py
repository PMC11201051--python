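"""Feature expansion, Gibbs-model fitting (closed-form and oracle checks),
prediction transforms, importance measures, and response curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import nichemax as nm
from nichemax.grid_io import EnvGrid, align_stack
from nichemax.maxent import (DegenerateModelError, FeatureDef, FeatureSpace,
                             MaxentModel, ResponseCurve, TrainConfig,
                             build_feature_space, compute_betas, fit,
                             fit_maxent, optimal_range, permutation_importance,
                             jackknife_gains, response_curve)


def linear_space(var="x", lo=0.0, hi=1.0):
    return FeatureSpace([var], {var: (lo, hi)},
                        [FeatureDef("linear", (var,))])


def toy_fit(beta_mult=0.0):
    """4 background cells with binary feature (1,1,0,0), presence mean 0.75."""
    space = linear_space()
    F_bg = np.array([[1.0], [1.0], [0.0], [0.0]])
    F_pres = np.array([[1.0], [1.0], [1.0], [0.0]])
    cfg = TrainConfig(reg_multiplier=beta_mult, tolerance=1e-12)
    return fit_maxent(F_pres, F_bg, space, cfg), F_bg, F_pres, cfg


def oracle_optimum(F_pres, F_bg, betas):
    """Independent L1 optimum via L-BFGS-B on the split formulation."""
    J = F_bg.shape[1]
    fbar = F_pres.mean(axis=0)
    logN = np.log(F_bg.shape[0])

    def neg(x):
        lam = x[:J] - x[J:]
        return -(fbar @ lam - logsumexp(F_bg @ lam) + logN
                 - betas @ (x[:J] + x[J:]))

    res = minimize(neg, np.zeros(2 * J), method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * J),
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
    return res.x[:J] - res.x[J:], -res.fun


class TestFeatures:
    def test_linear_only_matrix_is_scaled_values(self):
        bg = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        space = build_feature_space(bg, ["x"], TrainConfig(
            feature_classes=frozenset({"linear"})))
        F = space.evaluate(bg)
        assert np.allclose(F.ravel(), [0.0, 0.5, 1.0])

    def test_product_is_elementwise_product_of_scaled(self):
        bg = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 2.0, 4.0]})
        space = build_feature_space(bg, ["x", "y"], TrainConfig(
            feature_classes=frozenset({"linear", "product"})))
        F = space.evaluate(bg)
        prod_col = [i for i, f in enumerate(space.features)
                    if f.kind == "product"][0]
        assert np.allclose(F[:, prod_col], F[:, 0] * F[:, 1])

    def test_hinge_knots_at_background_deciles(self):
        rng = np.random.default_rng(20)
        bg = pd.DataFrame({"x": rng.uniform(0, 10, 500)})
        space = build_feature_space(bg, ["x"], TrainConfig(
            hinge_knots=10,
            feature_classes=frozenset({"linear", "forward_hinge"})))
        knots = sorted(f.knot for f in space.features
                       if f.kind == "forward_hinge")
        z = (bg["x"] - bg["x"].min()) / (bg["x"].max() - bg["x"].min())
        expected = sorted(np.round(np.quantile(z, np.arange(0, 10) / 10), 12))
        assert np.allclose(knots, expected)

    def test_constant_variable_keeps_only_linear(self):
        bg = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        space = build_feature_space(bg, ["x"], TrainConfig())
        assert [f.kind for f in space.features] == ["linear"]


class TestFit:
    def test_uniform_environment_gives_null_model(self):
        bg = pd.DataFrame({"x": [5.0] * 6})
        space = build_feature_space(bg, ["x"], TrainConfig())
        F_bg = space.evaluate(bg)
        F_pres = space.evaluate(pd.DataFrame({"x": [5.0] * 4}))
        model = fit_maxent(F_pres, F_bg, space, TrainConfig())
        assert np.all(model.lambdas == 0.0)
        assert model.gain == 0.0
        assert np.allclose(model.predict_raw(F_bg), 1 / 6)
        assert np.allclose(model.predict_logistic(F_bg), 0.5)

    def test_binary_toy_closed_form(self):
        model, F_bg, _, _ = toy_fit(0.0)
        assert model.lambdas[0] == pytest.approx(np.log(3), abs=1e-6)
        assert np.allclose(model.predict_raw(F_bg),
                           [0.375, 0.375, 0.125, 0.125], atol=1e-9)

    def test_binary_toy_with_penalty_hits_kkt_boundary(self):
        # beta = 0.05 exactly: reg_multiplier chosen so
        # beta = mult * 0.05 * sd(f) / sqrt(m) = 0.05
        space = linear_space()
        F_bg = np.array([[1.0], [1.0], [0.0], [0.0]])
        F_pres = np.array([[1.0], [1.0], [1.0], [0.0]])
        sd = F_bg.std()
        mult = 0.05 / (0.05 * sd / np.sqrt(4))
        cfg = TrainConfig(reg_multiplier=mult, tolerance=1e-12)
        model = fit_maxent(F_pres, F_bg, space, cfg)
        assert model.betas[0] == pytest.approx(0.05)
        q = model.predict_raw(F_bg)
        assert abs(q @ F_bg[:, 0] - 0.75) == pytest.approx(0.05, abs=1e-8)
        # independent convex-optimiser oracle agrees
        lam_o, _ = oracle_optimum(F_pres, F_bg, model.betas)
        assert model.lambdas[0] == pytest.approx(lam_o[0], abs=1e-4)

    def test_raw_distribution_normalised_and_gain_monotone(self, small_fit):
        model, data, _ = small_fit
        assert model.predict_raw(data.F_bg).sum() == pytest.approx(1.0,
                                                                   abs=1e-9)
        gains = [g for _, g in model.gain_trace]
        assert all(b >= a - 1e-9 for a, b in zip(gains, gains[1:]))
        assert 0 <= model.entropy_H <= np.log(model.n_background) + 1e-9

    def test_kkt_against_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n_bg, m, J = 25, 8, 3
            F_bg = rng.uniform(0, 1, (n_bg, J))
            F_pres = rng.uniform(0, 1, (m, J))
            space = FeatureSpace(
                [f"v{j}" for j in range(J)],
                {f"v{j}": (0.0, 1.0) for j in range(J)},
                [FeatureDef("linear", (f"v{j}",)) for j in range(J)])
            cfg = TrainConfig(reg_multiplier=rng.uniform(0.2, 2.0),
                              tolerance=1e-10, max_iterations=2000)
            model = fit_maxent(F_pres, F_bg, space, cfg)
            fbar = F_pres.mean(axis=0)
            q = model.predict_raw(F_bg)
            gap = np.abs(fbar - q @ F_bg) - model.betas
            assert np.all(gap <= 1e-6)  # KKT box condition
            # equality (tight) for active coordinates
            active = np.abs(model.lambdas) > 1e-8
            assert np.all(np.abs(gap[active]) <= 1e-6)
            _, obj_o = oracle_optimum(F_pres, F_bg, model.betas)
            assert model.gain == pytest.approx(obj_o, abs=1e-6)

    def test_too_few_presences_rejected(self):
        space = linear_space()
        with pytest.raises(ValueError):
            fit_maxent(np.array([[1.0]]), np.array([[1.0], [0.0]]), space,
                       TrainConfig())


class TestPredictions:
    def test_logistic_formula_on_toy(self):
        model, F_bg, _, _ = toy_fit(0.0)
        q = np.array([0.375, 0.375, 0.125, 0.125])
        H = -np.sum(q * np.log(q))
        assert model.entropy_H == pytest.approx(H, abs=1e-9)
        expected = np.exp(H) * q / (1 + np.exp(H) * q)
        assert np.allclose(model.predict_logistic(F_bg), expected, atol=1e-9)

    def test_logistic_monotone_in_raw(self, small_fit):
        model, data, _ = small_fit
        q = model.predict_raw(data.F_bg)
        p = model.predict_logistic(data.F_bg)
        order = np.argsort(q)
        assert np.all(np.diff(p[order]) >= -1e-15)
        assert np.all((p > 0) & (p < 1))

    def test_projection_onto_training_stack_is_identity(self, small_fit,
                                                        small_niche_setup):
        model, data, _ = small_fit
        stack, _, _ = small_niche_setup
        grid = model.project(stack)
        table = stack.to_table()
        direct = model.score_table(table)
        assert np.allclose(
            grid.values[table["row"], table["col"]], direct, atol=1e-12)

    def test_projection_clamps_to_training_range(self, small_fit,
                                                 small_niche_setup):
        model, data, _ = small_fit
        stack, _, _ = small_niche_setup
        hot = align_stack([g.with_values(g.values + 100.0)
                           for g in stack.layers.values()])
        clamped = model.project(hot)
        at_max = model.score_table(pd.DataFrame(
            {v: [model.space.scaling[v][1]] for v in model.variables}))
        vals = clamped.values[~np.isnan(clamped.values)]
        assert np.allclose(vals, at_max[0], atol=1e-12)

    def test_missing_variable_is_schema_error(self, small_fit, header3):
        model, _, _ = small_fit
        partial = align_stack([EnvGrid(header3, "env01", np.ones((3, 3)))])
        with pytest.raises(KeyError):
            model.project(partial)


class TestImportance:
    def test_single_variable_model_gets_full_credit(self, small_niche_setup):
        stack, _, occ = small_niche_setup
        cfg = TrainConfig(seed=30, background_size=800)
        model, data = fit(stack, occ, cfg, variables=["env01"])
        assert model.percent_contribution()["env01"] == pytest.approx(100.0)
        perm = permutation_importance(model, data, seed=31)
        assert perm["env01"] == pytest.approx(100.0)

    def test_duplicated_variables_share_to_100(self, small_niche_setup):
        stack, _, occ = small_niche_setup
        dup = align_stack([stack.layers["env01"],
                           stack.layers["env01"].with_values(
                               stack.layers["env01"].values.copy(),
                               name="copy")])
        cfg = TrainConfig(seed=32, background_size=800, max_iterations=60)
        model, _ = fit(dup, occ, cfg)
        contrib = model.percent_contribution()
        assert contrib.sum() == pytest.approx(100.0, abs=0.2)

    def test_informative_variable_outranks_noise(self, small_fit):
        model, data, _ = small_fit
        contrib = model.percent_contribution()
        perm = permutation_importance(model, data, seed=33)
        niche_vars = {"env01", "env02"}
        noise_vars = {"env05", "env06"}
        assert contrib.sum() == pytest.approx(100.0, abs=0.2)
        assert perm.sum() == pytest.approx(100.0, abs=0.2)
        assert max(contrib[v] for v in niche_vars) > max(
            contrib[v] for v in noise_vars)
        assert max(perm[v] for v in niche_vars) > max(
            perm[v] for v in noise_vars)


class TestJackknife:
    def test_nested_gains_and_dominant_variable(self, small_niche_setup):
        stack, _, occ = small_niche_setup
        sub = stack.subset(["env01", "env02", "env05"])
        cfg = TrainConfig(seed=34, background_size=800, max_iterations=80)
        jk = jackknife_gains(sub, occ, cfg)
        assert jk.gain_full >= 0
        for v in sub.names:
            assert jk.with_only[v] >= 0
            assert jk.gain_full >= jk.without[v] - 1e-6
        # a niche variable in isolation carries more gain than pure noise
        assert max(jk.with_only["env01"], jk.with_only["env02"]) \
            > jk.with_only["env05"]


class TestResponseCurves:
    def test_curve_bounded_and_dense(self, small_niche_setup):
        stack, _, occ = small_niche_setup
        cfg = TrainConfig(seed=35, background_size=800)
        curve = response_curve("env01", stack, occ, cfg)
        assert len(curve.values) >= 100
        assert np.all((curve.probability >= 0) & (curve.probability <= 1))

    def test_single_linear_feature_curve_is_monotone(self, small_niche_setup):
        stack, _, occ = small_niche_setup
        cfg = TrainConfig(seed=36, background_size=800,
                          feature_classes=frozenset({"linear"}))
        curve = response_curve("env03", stack, occ, cfg)
        diffs = np.diff(curve.probability)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)

    def test_optimal_range_of_identity_curve(self):
        x = np.linspace(0, 1, 101)
        ranges = optimal_range(ResponseCurve("x", x, x.copy()), 0.5)
        assert len(ranges) == 1
        lo, hi = ranges[0]
        assert lo == pytest.approx(0.5, abs=1e-12)
        assert hi == pytest.approx(1.0)

    def test_flat_curve_below_threshold_empty(self):
        x = np.linspace(0, 1, 101)
        assert optimal_range(ResponseCurve("x", x, np.full(101, 0.4))) == []

    def test_interval_matches_dense_scan_oracle(self):
        # unimodal curve with known crossing at |x-3| = sqrt(ln 2)
        x = np.linspace(0, 6, 121)
        p = np.exp(-(x - 3.0) ** 2)
        (lo, hi), = optimal_range(ResponseCurve("x", x, p), 0.5)
        dense = np.linspace(0, 6, 600001)
        above = dense[np.exp(-(dense - 3.0) ** 2) > 0.5]
        step = x[1] - x[0]
        assert abs(lo - above[0]) < step
        assert abs(hi - above[-1]) < step
        half_width = np.sqrt(np.log(2))
        assert lo == pytest.approx(3 - half_width, abs=step)
        assert hi == pytest.approx(3 + half_width, abs=step)
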