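import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from nichediverge import envsel, maxent, synthgen
from nichediverge.maxent import (
    FeatureSpec,
    aicc,
    auc_score,
    build_features,
    evaluate_replicates,
    fit_maxent,
    fit_model,
    permutation_importance,
    project_raster,
    select_model,
)


def env_df(X, names):
    return pd.DataFrame(np.asarray(X, dtype=float), columns=names)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class TestBuildFeatures:
    def test_linear_arity(self, rng):
        df = env_df(rng.random((30, 2)), ["a", "b"])
        F, builder = build_features(df, FeatureSpec("L"))
        assert F.shape == (30, 2)
        assert builder.feature_classes == ["L", "L"]

    def test_lqp_combinatorics(self, rng):
        df = env_df(rng.random((30, 3)), ["a", "b", "c"])
        F, _ = build_features(df, FeatureSpec("LQP"))
        assert F.shape[1] == 3 + 3 + 3

    def test_hinge_count_and_range(self, rng):
        df = env_df(rng.random((50, 1)), ["a"])
        F, builder = build_features(df, FeatureSpec("H", hinge_knots=5))
        assert F.shape[1] == 2 * 5
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_threshold_features_binary(self, rng):
        df = env_df(rng.random((50, 1)), ["a"])
        F, _ = build_features(df, FeatureSpec("T", threshold_knots=4))
        assert set(np.unique(F)) <= {0.0, 1.0}

    def test_constant_variable_hinges_dropped(self, rng):
        df = env_df(np.column_stack([rng.random(40), np.ones(40)]), ["a", "b"])
        F, builder = build_features(df, FeatureSpec("LH", hinge_knots=3))
        assert all("b" not in n for n in builder.feature_names)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown feature classes"):
            FeatureSpec("LX")

    def test_scaling_on_background_unit_interval(self, rng):
        df = env_df(rng.normal(50, 10, (100, 2)), ["a", "b"])
        F, _ = build_features(df, FeatureSpec("LQ"))
        assert F.min() == pytest.approx(0.0)
        assert F.max() == pytest.approx(1.0)


def oracle_objective(Fp, Fb, lam, b):
    """Penalized objective evaluated independently (per-presence scale)."""
    u = Fb @ lam
    lse = np.log(np.exp(u - u.max()).sum()) + u.max()
    return lse - Fp.mean(0) @ lam + b @ np.abs(lam)


class TestFitMaxent:
    def test_empty_spec_uniform(self, rng):
        Fp = np.empty((5, 0))
        Fb = np.empty((20, 0))
        res = fit_maxent(Fp, Fb, rm=1.0, feature_classes=[])
        assert res.log_partition == pytest.approx(np.log(20))

    def test_moment_matching_at_zero_rm(self, rng):
        Fb = rng.random((60, 3))
        Fp = rng.random((12, 3)) * 0.5 + 0.3
        res = fit_maxent(Fp, Fb, rm=0.0, feature_classes=["L"] * 3,
                         max_iter=20000, tol=1e-13)
        q = np.exp(Fb @ res.lambdas - res.log_partition)
        np.testing.assert_allclose(Fb.T @ q, Fp.mean(0), atol=1e-6)

    def test_matches_generic_solver(self, rng):
        Fb = rng.random((80, 4))
        Fp = rng.random((10, 4)) * 0.6 + 0.2
        classes = ["L"] * 4
        res = fit_maxent(Fp, Fb, rm=0.5, feature_classes=classes,
                         max_iter=20000, tol=1e-13)
        # independent oracle: BFGS on the objective with smoothed |.|
        n_p = len(Fp)
        sd = Fp.std(0)
        beta = 0.5 * 1.0 * sd / np.sqrt(n_p)  # base penalty 1.0 at n=10
        b = beta / n_p
        eps = 1e-10

        def obj(l):
            u = Fb @ l
            lse = np.log(np.exp(u - u.max()).sum()) + u.max()
            return lse - Fp.mean(0) @ l + b @ np.sqrt(l ** 2 + eps)

        oracle = minimize(obj, np.zeros(4), method="BFGS",
                          options={"gtol": 1e-10, "maxiter": 5000})
        ours = oracle_objective(Fp, Fb, res.lambdas, b)
        assert ours <= oracle.fun + 1e-6

    def test_large_rm_shrinks_to_zero(self, rng):
        Fb = rng.random((50, 3))
        Fp = rng.random((10, 3))
        res = fit_maxent(Fp, Fb, rm=1e6, feature_classes=["L"] * 3)
        assert np.abs(res.lambdas).max() == pytest.approx(0.0, abs=1e-12)

    def test_raw_sums_to_one_over_background(self, rng):
        df = env_df(rng.random((100, 2)), ["a", "b"])
        pres = df.iloc[:20]
        model = fit_model(pres, df, FeatureSpec("LQ"), rm=1.0)
        raw = model.predict(df, output="raw", clamp=False)
        assert raw.sum() == pytest.approx(1.0, rel=1e-8)

    def test_presence_smaller_than_two_rejected(self, rng):
        with pytest.raises(ValueError, match="presence"):
            fit_maxent(rng.random((1, 2)), rng.random((10, 2)))


class TestPredict:
    def test_clamp_inactive_inside_bounds(self, rng):
        df = env_df(rng.random((50, 2)), ["a", "b"])
        model = fit_model(df.iloc[:10], df, FeatureSpec("LQ"), rm=1.0)
        on = model.predict(df, clamp=True)
        off = model.predict(df, clamp=False)
        np.testing.assert_allclose(on, off)

    def test_clamp_truncates_to_training_max(self, rng):
        df = env_df(rng.random((50, 2)), ["a", "b"])
        model = fit_model(df.iloc[:10], df, FeatureSpec("LQ"), rm=1.0)
        hi = pd.DataFrame({"a": [10.0], "b": [0.5]})
        at_max = pd.DataFrame({"a": [df["a"].max()], "b": [0.5]})
        np.testing.assert_allclose(model.predict(hi, clamp=True),
                                   model.predict(at_max, clamp=True))

    def test_logistic_in_unit_interval(self, rng):
        df = env_df(rng.random((80, 2)), ["a", "b"])
        model = fit_model(df.iloc[:15], df, FeatureSpec("LQ"), rm=0.5)
        out = model.predict(df, output="logistic")
        assert ((out > 0) & (out < 1)).all()

    def test_missing_variable_rejected(self, rng):
        df = env_df(rng.random((30, 2)), ["a", "b"])
        model = fit_model(df.iloc[:5], df, FeatureSpec("L"), rm=1.0)
        with pytest.raises(ValueError, match="missing"):
            model.predict(pd.DataFrame({"a": [0.5]}))


class TestAicc:
    def test_zero_case(self):
        assert aicc(0.0, 0, 10) == 0.0

    def test_hand_arithmetic(self):
        assert aicc(-100.0, 2, 20) == pytest.approx(204.0 + 12.0 / 17.0)

    def test_degenerate_denominator(self):
        assert aicc(-5.0, 9, 10) == np.inf

    def test_affine_rescaled_variables_same_loglik(self, rng):
        # linear and hinge features are affine-equivariant, and the [0,1]
        # background rescaling plus sd-scaled penalties absorb the transform,
        # so the fit (and hence the AICc ranking) is unchanged
        df = env_df(rng.random((100, 2)), ["a", "b"])
        pres = df.iloc[:20]
        m1 = fit_model(pres, df, FeatureSpec("LH"), rm=1.0,
                       max_iter=20000, tol=1e-12)
        df2 = df * 3.0 + 7.0
        m2 = fit_model(df2.iloc[:20], df2, FeatureSpec("LH"), rm=1.0,
                       max_iter=20000, tol=1e-12)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-5)
        assert aicc(m1.loglik, m1.k_nonzero, 20) == pytest.approx(
            aicc(m2.loglik, m2.k_nonzero, 20), abs=1e-4)


class TestSelectModel:
    def test_single_candidate_wins(self, rng):
        df = env_df(rng.random((80, 2)), ["a", "b"])
        sel = select_model(df.iloc[:15], df, [FeatureSpec("L")], [1.0])
        assert sel.best_index == 0

    def test_informative_rm_beats_crushing_rm(self, small_stack, virtual_species):
        occ = synthgen.sample_occurrences(virtual_species, 60, seed=21)
        pres = envsel.extract_env(occ, small_stack)
        bg = small_stack.valid_cell_table()
        sel = select_model(pres, bg, [FeatureSpec("L")], [1.0, 1000.0],
                           variables=["BIO10", "BIO12"])
        assert sel.table.loc[sel.best_index, "rm"] == 1.0

    def test_duplicate_candidates_deterministic_tie_break(self, rng):
        df = env_df(rng.random((60, 2)), ["a", "b"])
        sel = select_model(df.iloc[:12], df, [FeatureSpec("L"), FeatureSpec("L")],
                           [1.0])
        assert sel.table["aicc"].iloc[0] == pytest.approx(sel.table["aicc"].iloc[1])
        assert sel.best_index == 0

    def test_delta_nonnegative(self, rng):
        df = env_df(rng.random((60, 2)), ["a", "b"])
        sel = select_model(df.iloc[:12], df, [FeatureSpec("L"), FeatureSpec("LQ")],
                           [0.5, 2.0])
        assert (sel.table["delta_aicc"] >= 0).all()


class TestEvaluateReplicates:
    def test_separable_scores_auc_one(self):
        assert auc_score([3.0, 4.0], [1.0, 2.0]) == 1.0

    def test_null_scores_auc_half(self, rng):
        pos = rng.random(1000)
        neg = rng.random(1000)
        assert auc_score(pos, neg) == pytest.approx(0.5, abs=0.05)

    def test_replicate_count_and_range(self, small_stack, virtual_species):
        occ = synthgen.sample_occurrences(virtual_species, 40, seed=22)
        pres = envsel.extract_env(occ, small_stack)
        bg = small_stack.valid_cell_table()
        ev = evaluate_replicates(pres, bg, FeatureSpec("L"), 1.0, n_reps=30,
                                 train_frac=0.75, seed=1,
                                 variables=["BIO10", "BIO12"],
                                 max_iter=300, tol=1e-5)
        assert len(ev.aucs) == 30
        assert ((ev.aucs >= 0) & (ev.aucs <= 1)).all()
        assert ev.aucs.mean() > 0.5  # informative species

    def test_bad_train_frac_rejected(self, rng):
        df = env_df(rng.random((30, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="train_frac"):
            evaluate_replicates(df.iloc[:10], df, FeatureSpec("L"), 1.0,
                                train_frac=1.5)


class TestPermutationImportance:
    def _single_var_model(self, stack, coef_name):
        vs = synthgen.make_virtual_species(stack, {coef_name: 3.0})
        occ = synthgen.sample_occurrences(vs, 60, seed=23)
        pres = envsel.extract_env(occ, stack)
        bg = stack.valid_cell_table()
        return fit_model(pres, bg, FeatureSpec("L"), rm=1.0,
                         variables=["BIO10", "BIO12"]), pres, bg

    def test_dominant_variable_near_total(self, small_stack):
        model, pres, bg = self._single_var_model(small_stack, "BIO10")
        imp = permutation_importance(model, pres, bg, n_perm=5, seed=1)
        assert imp["BIO10"] > 80

    def test_sums_to_hundred(self, small_stack):
        model, pres, bg = self._single_var_model(small_stack, "BIO10")
        imp = permutation_importance(model, pres, bg, n_perm=3, seed=2)
        assert imp.sum() == pytest.approx(100.0)

    def test_symmetric_variables_split_evenly(self):
        # two layers that are transposes of each other plus a deterministic,
        # transpose-closed presence set make the variables exactly
        # exchangeable; only permutation noise remains
        from nichediverge.raster import ClimateStack, GridTransform

        rng = np.random.default_rng(31)
        n = 50
        a = rng.standard_normal((n, n))
        grid = np.stack([a, a.T], axis=2)
        stack = ClimateStack(["BIO10", "BIO12"],
                             grid, GridTransform(-1.0, 1.0, 2.0 / n, 2.0 / n))
        vs = synthgen.make_virtual_species(stack, {"BIO10": 2.0, "BIO12": 2.0})
        bg = stack.valid_cell_table()
        suit = vs.true_suitability[bg["row"].to_numpy(), bg["col"].to_numpy()]
        pres = bg.iloc[np.argsort(suit)[-100:]]
        model = fit_model(pres, bg, FeatureSpec("L"), rm=1.0,
                          variables=["BIO10", "BIO12"])
        imp = permutation_importance(model, pres, bg, n_perm=10, seed=3)
        assert imp["BIO10"] == pytest.approx(50.0, abs=10.0)


class TestProjectRaster:
    def test_training_stack_consistency(self, small_stack, virtual_species):
        occ = synthgen.sample_occurrences(virtual_species, 30, seed=24)
        pres = envsel.extract_env(occ, small_stack)
        bg = small_stack.valid_cell_table()
        model = fit_model(pres, bg, FeatureSpec("LQ"), rm=1.0,
                          variables=["BIO10", "BIO12"])
        smap = project_raster(model, small_stack)
        direct = model.predict(bg, output="logistic")
        np.testing.assert_allclose(
            smap.grid[bg["row"].to_numpy(), bg["col"].to_numpy()], direct)

    def test_missing_layer_rejected(self, small_stack, virtual_species):
        occ = synthgen.sample_occurrences(virtual_species, 30, seed=25)
        pres = envsel.extract_env(occ, small_stack)
        bg = small_stack.valid_cell_table()
        model = fit_model(pres, bg, FeatureSpec("L"), rm=1.0,
                          variables=["BIO10", "BIO12"])
        clipped = synthgen.make_climate_stack(20, 20, layer_names=["BIO10"], seed=1)
        with pytest.raises(ValueError, match="lacks model variables"):
            project_raster(model, clipped)

    def test_constant_model_constant_map(self, small_stack, rng):
        bg = small_stack.valid_cell_table()
        pres = bg.iloc[:10]
        model = fit_model(pres, bg, FeatureSpec("L"), rm=1e9,
                          variables=["BIO10", "BIO12"])
        smap = project_raster(model, small_stack)
        vals = smap.grid[small_stack.valid_mask]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)


class TestParameterRecovery:
    def test_virtual_species_rank_recovery(self):
        stack = synthgen.make_climate_stack(100, 100, seed=41)
        vs = synthgen.make_virtual_species(stack, {"BIO10": 2.0, "BIO12": 1.0})
        occ = synthgen.sample_occurrences(vs, 200, seed=42)
        pres = envsel.extract_env(occ, stack)
        cells = stack.valid_cell_table()
        rng = np.random.default_rng(43)
        bg = cells.iloc[rng.integers(0, len(cells), 5000)].reset_index(drop=True)
        model = fit_model(pres, bg, FeatureSpec("LQ"), rm=1.0,
                          variables=stack.layer_names)
        smap = project_raster(model, stack)
        rho = spearmanr(vs.true_suitability[stack.valid_mask],
                        smap.grid[stack.valid_mask]).statistic
        assert rho >= 0.9
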