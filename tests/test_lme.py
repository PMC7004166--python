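"""Mixed-effects model: oracles, recovery, selection, effect ratios."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from musthtrack.lme import (LmeDesign, _profile, build_design, effect_ratio,
                            fit_lme, lrt, select_model)


def simulate_daily(n_groups=10, n_days=40, G=((0.04, 0.0), (0.0, 0.01)),
                   phi=0.4, delta=1.5, sigma=0.25,
                   beta=None, seed=1, gap_days=0, bout_days=10):
    """Daily table drawn from the marginal LME model itself."""
    beta = beta or {"intercept": -1.0, "musth": 0.4, "ndvi": 0.1,
                    "musth:age": 0.02}
    rng = np.random.default_rng(seed)
    G = np.asarray(G, float)
    recs = []
    for g in range(n_groups):
        age = int(rng.integers(22, 50))
        ndvi = rng.normal(0, 1, n_days)
        musth = np.zeros(n_days)
        blen = min(bout_days, max(1, n_days // 3))
        s = int(rng.integers(0, max(n_days - blen, 1)))
        musth[s:s + blen] = 1
        b = rng.multivariate_normal([0, 0], G)
        e = np.empty(n_days)
        e[0] = rng.normal()
        for t in range(1, n_days):
            e[t] = phi * e[t - 1] + rng.normal() * np.sqrt(1 - phi ** 2)
        w = np.where(musth > 0, delta, 1.0)
        eta = (beta["intercept"] + beta.get("musth", 0) * musth
               + beta.get("ndvi", 0) * ndvi
               + beta.get("musth:age", 0) * musth * (age - 35))
        y = eta + b[0] + b[1] * ndvi + sigma * w * e
        day = 0
        for t in range(n_days):
            recs.append({"individual_id": f"g{g:02d}",
                         "date": dt.date(2012, 1, 1) + dt.timedelta(days=day),
                         "mean_speed_kmh": float(np.exp(y[t])),
                         "musth": float(musth[t]), "age": float(age - 35),
                         "ndvi": float(ndvi[t]), "slope": float(rng.normal()),
                         "vrm": float(rng.normal()),
                         "dist_water": float(rng.normal()),
                         "protected": float(rng.integers(0, 2))})
            day += 1 + (gap_days if (t % 7 == 6) else 0)
    return pd.DataFrame(recs)


class TestBuildDesign:
    def test_group_index_sorted_blocks(self):
        df = simulate_daily(n_groups=2, n_days=3)
        d = build_design(df)
        assert d.groups.tolist() == [0, 0, 0, 1, 1, 1]

    def test_full_design_has_24_fixed_columns(self):
        d = build_design(simulate_daily(n_groups=3, n_days=10))
        assert d.X.shape[1] == 24
        assert d.colnames[:2] == ["intercept", "musth"]
        assert sum(c.startswith("musth:") for c in d.colnames) == 11

    def test_musth_all_zero_kills_interactions(self):
        df = simulate_daily(n_groups=3, n_days=10)
        df["musth"] = 0.0
        d = build_design(df)
        inter = [i for i, c in enumerate(d.colnames) if c.startswith("musth")]
        assert np.all(d.X[:, inter] == 0)


class TestFit:
    def test_degenerate_case_equals_ols_loglik(self):
        """With G = 0, phi = 0, delta = 1 the profiled marginal likelihood
        collapses to the closed-form OLS Gaussian log-likelihood."""
        d = build_design(simulate_daily(n_groups=6, n_days=20, seed=3))
        bh, s2, ll, _ = _profile(d, np.zeros((2, 2)), 0.0, 1.0, False)
        bo, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        r = d.y - d.X @ bo
        s2_ols = r @ r / len(d.y)
        ll_ols = -0.5 * len(d.y) * (np.log(2 * np.pi * s2_ols) + 1)
        assert ll == pytest.approx(ll_ols, abs=1e-8)
        np.testing.assert_allclose(bh, bo, atol=1e-8)

    def test_loglik_invariant_to_column_reordering(self):
        d = build_design(simulate_daily(n_groups=5, n_days=15, seed=4))
        cols = list(d.colnames)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(cols))
        f1 = fit_lme(d, "ML")
        f2 = fit_lme(d.subset_columns(perm), "ML", theta0=f1.theta)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)

    def test_duplicating_individuals_keeps_beta_shrinks_se(self):
        d = build_design(simulate_daily(n_groups=6, n_days=20, seed=5))
        f1 = fit_lme(d, "ML")
        d2 = d.subset_groups(list(range(d.n_groups)) * 2)
        f2 = fit_lme(d2, "ML", theta0=f1.theta)
        np.testing.assert_allclose(f2.beta.to_numpy(), f1.beta.to_numpy(),
                                   atol=2e-3)
        ratio = (f2.se / f1.se).to_numpy()
        np.testing.assert_allclose(ratio, 1 / np.sqrt(2), atol=0.02)

    def test_parameter_recovery_within_3se(self):
        truth = {"intercept": -1.0, "musth": 0.4, "ndvi": 0.1, "musth:age": 0.02}
        df = simulate_daily(n_groups=14, n_days=60, phi=0.4, delta=1.5,
                            sigma=0.25, beta=truth, seed=6)
        fit = fit_lme(build_design(df), "ML")
        for term, val in truth.items():
            assert abs(fit.beta[term] - val) < 3 * fit.se[term], term
        assert abs(fit.phi - 0.4) < 0.15
        assert abs(fit.delta - 1.5) < 0.35
        assert abs(fit.sigma - 0.25) < 0.05

    def test_gls_normal_equations_at_optimum(self):
        d = build_design(simulate_daily(n_groups=5, n_days=15, seed=7))
        fit = fit_lme(d, "ML")
        A = fit.G / fit.sigma ** 2
        from scipy import linalg
        grad = np.zeros(d.X.shape[1])
        for g in range(d.n_groups):
            sel = d.groups == g
            Xg, yg, Zg = d.X[sel], d.y[sel], d.Z[sel]
            dd = np.abs(np.subtract.outer(d.day[sel], d.day[sel])).astype(int)
            w = np.where(d.musth[sel] > 0, fit.delta, 1.0)
            V = Zg @ A @ Zg.T + np.outer(w, w) * np.power(fit.phi, dd)
            r = yg - Xg @ fit.beta.to_numpy()
            grad += Xg.T @ linalg.solve(V, r)
        np.testing.assert_allclose(grad, 0.0, atol=1e-6)

    def test_matches_independent_random_slope_implementation(self):
        """With phi = 0 and delta = 1 fixed, the fit agrees with
        statsmodels MixedLM (random intercept + NDVI slope)."""
        import statsmodels.regression.mixed_linear_model as mlm
        df = simulate_daily(n_groups=8, n_days=30, phi=0.0, delta=1.0, seed=8)
        d = build_design(df)
        keep = ["intercept", "musth", "ndvi", "age"]
        fit = fit_lme(d.subset_columns(keep), "REML", ar1=False, het=False)
        exog = pd.DataFrame(d.subset_columns(keep).X, columns=keep)
        m = mlm.MixedLM(d.y, exog, groups=d.groups,
                        exog_re=pd.DataFrame(d.Z, columns=["icpt", "ndvi_re"]))
        sm = m.fit(reml=True)
        np.testing.assert_allclose(fit.beta.to_numpy(), sm.fe_params,
                                   rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose(fit.sigma ** 2, sm.scale, rtol=1e-3)
        np.testing.assert_allclose(fit.G, sm.cov_re.to_numpy() * 1.0,
                                   rtol=2e-2, atol=1e-4)


class TestSelection:
    def _small_design(self, seed, beta=None):
        df = simulate_daily(n_groups=6, n_days=25, seed=seed, beta=beta)
        d = build_design(df)
        keep = ["intercept", "musth", "age", "age2", "ndvi", "musth:age"]
        return d.subset_columns(keep)

    def test_marginality_linear_not_droppable_under_quadratic(self):
        from musthtrack.lme import _droppable
        cols = ["intercept", "musth", "age", "age2", "ndvi", "musth:age"]
        drop = _droppable(cols)
        assert "age" not in drop          # age2 and musth:age need it
        assert "musth" not in drop        # musth:age needs it
        assert {"age2", "ndvi", "musth:age"} <= set(drop)

    def test_lrt_single_term_df_one(self):
        d = self._small_design(9)
        full = fit_lme(d, "ML")
        red = fit_lme(d.subset_columns([c for c in d.colnames if c != "ndvi"]),
                      "ML", theta0=full.theta)
        chi2, df_, p = lrt(full, red)
        assert df_ == 1
        assert chi2 >= 0

    def test_null_terms_usually_dropped(self):
        """A term with true coefficient 0 is deleted by backward selection
        in most replicates (type-I behaviour of the alpha = 0.05 LRT)."""
        dropped = 0
        n_rep = 20
        for rep in range(n_rep):
            d = self._small_design(100 + rep,
                                   beta={"intercept": -1.0, "musth": 0.5,
                                         "ndvi": 0.3, "musth:age": 0.0})
            sel = select_model(d)
            dropped += "musth:age" not in sel.fit.beta.index
        assert dropped >= int(0.8 * n_rep)

    def test_final_fit_is_reml(self):
        d = self._small_design(10)
        sel = select_model(d)
        assert sel.fit.method == "REML"
        assert sel.ml_fit.method == "ML"
        assert not sel.table.empty


class TestEffectRatio:
    def _fit_with_beta(self, coef):
        d = build_design(simulate_daily(n_groups=4, n_days=15, seed=11))
        fit = fit_lme(d, "ML")
        fit.beta[:] = 0.0
        for k, v in coef.items():
            fit.beta[k] = v
        return fit

    def test_pure_musth_effect_at_centring_age(self):
        fit = self._fit_with_beta({"musth": np.log(1.49)})
        assert effect_ratio(fit, 35, n_boot=0).ratio == pytest.approx(1.49)

    def test_zero_musth_terms_give_unit_ratio(self):
        fit = self._fit_with_beta({"ndvi": 0.7, "age": -0.01})
        for age in (20, 35, 50):
            assert effect_ratio(fit, age, n_boot=0).ratio == 1.0

    def test_age_interaction_hand_formula(self):
        fit = self._fit_with_beta({"musth": 0.3, "musth:age": 0.02})
        want = np.exp(0.3 + 15 * 0.02)
        assert effect_ratio(fit, 50, n_boot=0).ratio == pytest.approx(want)

    def test_bootstrap_ci_brackets_point(self):
        d = build_design(simulate_daily(n_groups=8, n_days=30, seed=12))
        fit = fit_lme(d, "ML")
        er = effect_ratio(fit, 35, n_boot=200, seed=1)
        assert er.lo <= er.ratio <= er.hi
        er2 = effect_ratio(fit, 35, n_boot=200, seed=1)
        assert (er.lo, er.hi) == (er2.lo, er2.hi)  # seeded determinism
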