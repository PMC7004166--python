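"""Ordered three-state HMM: oracles, sampler contracts, decoding, PPC."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from musthtrack.musth_hmm import (SCALED_CONFIG, HmmConfig, HmmParams,
                                  HmmPriors, HmmWindow, WindowSelectionError,
                                  decode_states, hmm_loglik,
                                  posterior_predictive_check, sample_posterior,
                                  select_window)
from musthtrack.synthetic import simulate_hmm_window


def enumeration_loglik(params, window):
    """Brute-force oracle: sum over all monotone state paths.

    A path is determined by (n1, n2, n3), the day counts in each state,
    with n1 >= 1 and state 3 reachable only through state 2.
    """
    T = len(window.y)
    b, s = params.beta, params.sigma
    terms = []
    for n1 in range(1, T + 1):
        for n2 in range(0, T - n1 + 1):
            n3 = T - n1 - n2
            if n2 == 0 and n3 > 0:
                continue
            lp = (n1 - 1) * np.log(1 - params.q1)
            if n2 > 0:
                lp += np.log(params.q1) + (n2 - 1) * np.log(1 - params.q2)
            if n3 > 0:
                lp += np.log(params.q2)
            states = [0] * n1 + [1] * n2 + [2] * n3
            for t in range(T):
                if window.observed[t]:
                    lp += norm.logpdf(window.y[t], b[states[t]], s[states[t]])
            terms.append(lp)
    m = max(terms)
    return m + np.log(np.sum(np.exp(np.array(terms) - m)))


def random_params(rng):
    return HmmParams(beta=rng.normal(0, 1, 3),
                     sigma=rng.uniform(0.1, 1.0, 3),
                     q1=float(rng.uniform(0.01, 0.5)),
                     q2=float(rng.uniform(0.01, 0.5)))


class TestLikelihood:
    def test_single_day_is_state1_density(self):
        w = HmmWindow("b", [0.3], [True], [dt.date(2012, 1, 1)])
        p = HmmParams(beta=np.array([0.1, 1.0, -0.5]),
                      sigma=np.array([0.2, 0.3, 0.4]), q1=0.05, q2=0.05)
        assert hmm_loglik(p, w) == pytest.approx(
            norm.logpdf(0.3, 0.1, 0.2), abs=1e-12)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            T = int(rng.integers(2, 9))
            w, _ = simulate_hmm_window(T=T, bout=(1, max(1, T // 2)),
                                       missing=0.2, seed=trial)
            p = random_params(rng)
            assert hmm_loglik(p, w) == pytest.approx(
                enumeration_loglik(p, w), abs=1e-10)

    def test_identical_states_collapse_to_iid_normal(self):
        w, _ = simulate_hmm_window(T=50, seed=3)
        for q1, q2 in [(0.02, 0.1), (0.4, 0.4)]:
            p = HmmParams(beta=np.full(3, -1.0), sigma=np.full(3, 0.3),
                          q1=q1, q2=q2)
            iid = norm.logpdf(w.y[w.observed], -1.0, 0.3).sum()
            assert hmm_loglik(p, w) == pytest.approx(iid, abs=1e-10)

    def test_reversed_window_changes_likelihood(self):
        """Ordering matters: a bout at the end is not a bout at the start."""
        w, _ = simulate_hmm_window(T=60, bout=(40, 55), seed=4)
        rev = HmmWindow("b", w.y[::-1].copy(), w.observed[::-1].copy(),
                        list(reversed(w.dates)))
        p = HmmParams(beta=np.array([-1.2, -0.4, -1.2]),
                      sigma=np.full(3, 0.2), q1=0.03, q2=0.03)
        assert abs(hmm_loglik(p, w) - hmm_loglik(p, rev)) > 1.0

    def test_matches_importance_sampling_over_paths(self):
        """The marginalized forward value equals the Monte-Carlo average
        of emission likelihoods over prior path draws."""
        rng = np.random.default_rng(5)
        w, _ = simulate_hmm_window(T=6, bout=(2, 4), seed=6)
        p = HmmParams(beta=np.array([-1.0, -0.3, -1.1]),
                      sigma=np.array([0.3, 0.3, 0.3]), q1=0.3, q2=0.3)
        n = 200_000
        states = np.zeros((n, 6), int)
        for t in range(1, 6):
            u = rng.random(n)
            s = states[:, t - 1]
            adv = np.where(s == 0, u < p.q1, np.where(s == 1, u < p.q2, False))
            states[:, t] = np.minimum(s + adv, 2)
        like = np.ones(n)
        for t in range(6):
            like *= norm.pdf(w.y[t], p.beta[states[:, t]], p.sigma[states[:, t]])
        est = like.mean()
        mc_se = like.std() / np.sqrt(n)
        assert abs(np.exp(hmm_loglik(p, w)) - est) < 3 * mc_se


class TestWindowSelection:
    def _daily(self, n=240, start=dt.date(2012, 1, 1), missing_every=0):
        rows = []
        for i in range(n):
            if missing_every and i % missing_every == 0:
                continue
            rows.append({"individual_id": "b", "date": start + dt.timedelta(days=i),
                         "mean_speed_kmh": 0.3, "mcp95_km2": 3.0})
        return pd.DataFrame(rows)

    def _obs(self, musth_days, nonmusth_days, start=dt.date(2012, 1, 1)):
        rows = [{"individual_id": "b", "date": start + dt.timedelta(days=d),
                 "label": "musth"} for d in musth_days]
        rows += [{"individual_id": "b", "date": start + dt.timedelta(days=d),
                  "label": "non_musth"} for d in nonmusth_days]
        return pd.DataFrame(rows)

    def test_five_observations_rejected(self):
        with pytest.raises(WindowSelectionError, match="observations"):
            select_window(self._daily(), self._obs([100], [50, 60, 70, 80]), "b")

    def test_excess_missing_rejected(self):
        daily = self._daily(missing_every=8)  # 12.5% of days missing
        obs = self._obs([100, 140], [50, 60, 70, 80])
        with pytest.raises(WindowSelectionError, match="missing"):
            select_window(daily, obs, "b")

    def test_window_centred_on_musth_midpoint(self):
        daily = self._daily(n=400)
        obs = self._obs([100, 140], [50, 60, 70, 80])
        w = select_window(daily, obs, "b")
        mid = dt.date(2012, 1, 1) + dt.timedelta(days=120)
        assert w.dates[0] == mid - dt.timedelta(days=120)
        assert w.dates[-1] == mid + dt.timedelta(days=120)
        assert w.span_days == 241

    def test_no_musth_observation_rejected(self):
        with pytest.raises(WindowSelectionError, match="musth"):
            select_window(self._daily(),
                          self._obs([], [10, 20, 30, 40, 50, 60]), "b")


class TestSampler:
    def test_default_config_retains_40000_samples(self):
        assert HmmConfig().n_retained == 40_000
        assert HmmConfig().chains == 8

    def test_scaled_run_sample_count_and_convergence(self):
        w, _ = simulate_hmm_window(T=240, bout=(100, 160), seed=0)
        post = sample_posterior(w, config=dataclasses.replace(SCALED_CONFIG, seed=0))
        assert post.n_retained == SCALED_CONFIG.n_retained == 4000
        assert post.converged
        assert max(post.rhat.values()) <= 1.1

    def test_same_seed_identical_samples(self):
        w, _ = simulate_hmm_window(T=120, bout=(40, 80), seed=1)
        cfg = HmmConfig(chains=2, warmup=300, iters=300, seed=7)
        a = sample_posterior(w, config=cfg)
        b = sample_posterior(w, config=cfg)
        for k in a.samples:
            np.testing.assert_array_equal(a.samples[k], b.samples[k])

    def test_posterior_means_near_truth_when_separated(self):
        beta = (-1.2, -0.4, -1.2)
        w, _ = simulate_hmm_window(T=240, bout=(100, 160), beta=beta,
                                   sigma=(0.2, 0.2, 0.2), seed=2)
        post = sample_posterior(w, config=dataclasses.replace(SCALED_CONFIG, seed=2))
        for k, truth in zip(("beta1", "beta2", "beta3"), beta):
            draws = post.flat(k)
            lo, hi = np.quantile(draws, [0.025, 0.975])
            assert lo - 0.05 <= truth <= hi + 0.05, k

    def test_ordering_constraint_beta2_largest(self):
        w, _ = simulate_hmm_window(T=120, bout=(40, 80), seed=3)
        post = sample_posterior(w, config=dataclasses.replace(SCALED_CONFIG, seed=3))
        assert np.all(post.flat("beta2") >= post.flat("beta1"))
        assert np.all(post.flat("beta2") >= post.flat("beta3"))


class TestDecode:
    def test_well_separated_bout_recovered(self):
        w, _ = simulate_hmm_window(T=240, bout=(100, 160), seed=4)
        post = sample_posterior(w, config=dataclasses.replace(SCALED_CONFIG, seed=4))
        dec = decode_states(post, w, seed=0)
        idx = np.flatnonzero(dec.assigned)
        assert abs(idx[0] - 100) <= 2 and abs(idx[-1] - 160) <= 2
        assert dec.duration_sd < 5.0
        assert np.all((dec.p_state2 >= 0) & (dec.p_state2 <= 1))

    def test_monotone_path_constraint_in_draws(self):
        from musthtrack._hmm_core import ffbs_path
        w, _ = simulate_hmm_window(T=100, bout=(30, 60), seed=5)
        rng = np.random.default_rng(0)
        p = HmmParams(beta=np.array([-1.2, -0.4, -1.2]), sigma=np.full(3, 0.2),
                      q1=0.03, q2=0.03)
        for _ in range(50):
            path = ffbs_path(w.y, w.observed, p.beta, p.sigma, p.q1, p.q2,
                             rng.random(100))
            assert np.all(np.diff(path) >= 0)

    def test_no_bout_window_rarely_assigned(self):
        hits = 0
        n_days = 0
        for seed in range(10):
            w, _ = simulate_hmm_window(T=120, bout=None, seed=seed)
            post = sample_posterior(
                w, config=dataclasses.replace(SCALED_CONFIG, seed=seed))
            dec = decode_states(post, w, seed=seed)
            hits += int(dec.assigned.sum())
            n_days += len(dec.assigned)
        assert hits / n_days < 0.05


class TestPpc:
    def test_model_drawn_data_not_flagged(self):
        """When the data really come from the model, PPC quantiles stay
        away from the extremes (they are conservative for fitted
        statistics, so a well-specified model is essentially never
        flagged)."""
        cfg = HmmConfig(chains=2, warmup=500, iters=500, thin=2)
        qs = {"q_mean": [], "q_max": [], "q_lag1": []}
        for seed in range(30):
            w, _ = simulate_hmm_window(T=120, bout=(40, 80), seed=200 + seed)
            post = sample_posterior(w, config=dataclasses.replace(cfg, seed=seed))
            ppc = posterior_predictive_check(post, w, n_draws=200, seed=seed)
            for k in qs:
                qs[k].append(getattr(ppc, k))
        for k, v in qs.items():
            extreme = sum(q < 0.01 or q > 0.99 for q in v)
            assert extreme <= 2, (k, sorted(v)[:5], sorted(v)[-5:])
            # quantiles spread across the unit interval, not stuck at 0/1
            assert 0.1 < np.median(v) < 0.9, k

    def test_constant_series_flagged_extreme(self):
        """A constant observed series scored against a posterior fitted to
        ordinary variable data sits in the far tail of the replicated
        mean/max distributions."""
        T = 120
        w_fit, _ = simulate_hmm_window(T=T, bout=(40, 80), seed=11)
        post = sample_posterior(w_fit,
                                config=dataclasses.replace(SCALED_CONFIG, seed=9))
        w_const = HmmWindow("b", np.full(T, -2.5), np.ones(T, bool),
                            [dt.date(2012, 1, 1) + dt.timedelta(days=i)
                             for i in range(T)])
        ppc = posterior_predictive_check(post, w_const, seed=0)
        assert ppc.q_mean < 0.01 or ppc.q_mean > 0.99
        assert ppc.q_max < 0.01 or ppc.q_max > 0.99

    def test_autocorrelated_residuals_flagged_by_lag1(self):
        """Strong residual autocorrelation shows up in the lag-1 PPC, the
        misfit the independent-error model is expected to display."""
        rng = np.random.default_rng(12)
        T = 160
        e = np.empty(T)
        e[0] = rng.normal()
        for t in range(1, T):
            e[t] = 0.85 * e[t - 1] + 0.53 * rng.normal()
        states = np.zeros(T, int)
        states[60:100] = 1
        states[100:] = 2
        beta = np.array([-1.2, -0.4, -1.2])
        y = beta[states] + 0.25 * e
        w = HmmWindow("b", y, np.ones(T, bool),
                      [dt.date(2012, 1, 1) + dt.timedelta(days=i)
                       for i in range(T)])
        post = sample_posterior(w, config=dataclasses.replace(SCALED_CONFIG, seed=13))
        ppc = posterior_predictive_check(post, w, seed=1)
        assert ppc.q_lag1 > 0.95


def test_compiled_posterior_density_matches_python_spec():
    """The numba log-posterior agrees with the pure-Python prior plus
    forward likelihood (including transform Jacobians)."""
    from musthtrack._hmm_core import _log_posterior
    from musthtrack.musth_hmm import (HmmPriors, _log_prior, _theta_to_params,
                                      hmm_loglik)
    w, _ = simulate_hmm_window(T=60, bout=(20, 40), seed=8)
    pri = HmmPriors.from_window(w)
    rng = np.random.default_rng(1)
    for _ in range(20):
        th = rng.normal(0, 1, 8) + np.array([pri.m0, pri.m0, -0.5,
                                             -1.5, -1.5, -1.5, -3.0, -3.0])
        want = hmm_loglik(_theta_to_params(th), w) + _log_prior(th, pri)
        got = _log_posterior(th, w.y, w.observed, pri.m0, pri.beta_sd,
                             pri.beta2_offset_mean, pri.sigma_scale,
                             pri.q_a, pri.q_b)
        assert got == pytest.approx(want, abs=1e-9)
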