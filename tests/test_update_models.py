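"""Discounted-PE empathy-update models: sums, prediction, fitting, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import empathlearn as el
from empathlearn.update_models import UpdateModelSpec, UpdateParams


def _sum_loop(pe, gamma, t, sign):
    """Brute-force loop oracle for the discounted sign-filtered sum."""
    total = 0.0
    for tau in range(1, t + 1):
        d = pe[tau - 1]
        if sign == "pos" and d <= 0:
            continue
        if sign == "neg" and d >= 0:
            continue
        total += gamma ** (t - tau) * d
    return total


class TestDiscountedSums:
    def test_gamma_zero_keeps_only_last_pe(self):
        pe = [3.0, -2.0, 7.0]
        assert el.discounted_pe_sums(pe, 0.0, 3, "all") == 7.0
        assert el.discounted_pe_sums(pe, 0.0, 2, "pos") == 0.0
        assert el.discounted_pe_sums(pe, 0.0, 2, "neg") == -2.0

    def test_gamma_one_is_plain_sum(self):
        pe = [3.0, -2.0, 7.0, 0.0]
        assert el.discounted_pe_sums(pe, 1.0, 4, "all") == 8.0
        assert el.discounted_pe_sums(pe, 1.0, 4, "pos") == 10.0
        assert el.discounted_pe_sums(pe, 1.0, 4, "neg") == -2.0

    def test_hand_example(self):
        """delta = [10, -5], gamma = 0.5 at t = 2: pos sum 5, neg sum -5."""
        assert el.discounted_pe_sums([10.0, -5.0], 0.5, 2, "pos") == 5.0
        assert el.discounted_pe_sums([10.0, -5.0], 0.5, 2, "neg") == -5.0

    def test_out_of_range_inputs(self):
        with pytest.raises(el.InputError):
            el.discounted_pe_sums([1.0], 0.5, 2)
        with pytest.raises(el.InputError):
            el.discounted_pe_sums([1.0], 1.5, 1)
        with pytest.raises(el.InputError):
            el.discounted_pe_sums([1.0], 0.5, 1, sign="bogus")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(gamma=st.floats(0.0, 1.0), seed=st.integers(0, 2**16),
       sign=st.sampled_from(["pos", "neg", "all"]))
def test_sums_match_brute_force_loop(gamma, seed, sign):
    """Filter implementation equals the loop oracle to 1e-12 everywhere."""
    rng = np.random.default_rng(seed)
    pe = rng.normal(0, 10, rng.integers(1, 40))
    series = el.discounted_pe_series(pe, gamma, sign)
    for t in range(1, pe.size + 1):
        assert abs(series[t - 1] - _sum_loop(pe, gamma, t, sign)) < 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(gamma=st.floats(0.0, 1.0), seed=st.integers(0, 2**16))
def test_sums_satisfy_recursion(gamma, seed):
    """S(t) = gamma * S(t-1) + delta_t(sign), exactly."""
    pe = np.random.default_rng(seed).normal(0, 10, 25)
    for sign in ("pos", "neg", "all"):
        S = el.discounted_pe_series(pe, gamma, sign)
        filt = np.where(pe > 0, pe, 0.0) if sign == "pos" else \
            np.where(pe < 0, pe, 0.0) if sign == "neg" else pe
        assert abs(S[0] - filt[0]) < 1e-12
        assert np.allclose(S[1:], gamma * S[:-1] + filt[1:], atol=1e-10)


class TestPredictEmpathy:
    def test_zero_weights_flat_at_baseline(self):
        spec = UpdateModelSpec("M3")
        params = UpdateParams(weights=dict.fromkeys(spec.weight_names, 0.0),
                              gamma=0.5, empathy_t0=48.0)
        traj = el.predict_empathy(spec, params, np.random.default_rng(0).normal(0, 10, 30))
        assert np.allclose(traj, 48.0)

    def test_hand_example_half_split(self):
        """delta = [+10, +10] in the first half, gamma 1, W1_pos 0.5, t0 50 -> 55, 60."""
        spec = UpdateModelSpec("M3")
        params = UpdateParams(
            weights={"w1_pos": 0.5, "w1_neg": 0.0, "w2_pos": 0.0, "w2_neg": 0.0},
            gamma=1.0, empathy_t0=50.0)
        traj = el.predict_empathy(spec, params, [10.0, 10.0],
                                  first_half=np.array([True, True]))
        assert np.allclose(traj, [55.0, 60.0])

    def test_m2_with_equal_weights_reproduces_m1(self, rng):
        pe = rng.normal(0, 8, 30)
        m1 = el.predict_empathy(UpdateModelSpec("M1"),
                                UpdateParams(weights={"w": 0.4}, gamma=0.6, empathy_t0=50.0), pe)
        m2 = el.predict_empathy(UpdateModelSpec("M2"),
                                UpdateParams(weights={"w_pos": 0.4, "w_neg": 0.4},
                                             gamma=0.6, empathy_t0=50.0), pe)
        assert np.allclose(m1, m2, atol=1e-12)

    def test_m3_with_equal_halves_reproduces_m2(self, rng):
        pe = rng.normal(0, 8, 30)
        m2 = el.predict_empathy(UpdateModelSpec("M2"),
                                UpdateParams(weights={"w_pos": 0.3, "w_neg": 0.7},
                                             gamma=0.8, empathy_t0=50.0), pe)
        m3 = el.predict_empathy(UpdateModelSpec("M3"),
                                UpdateParams(weights={"w1_pos": 0.3, "w1_neg": 0.7,
                                                      "w2_pos": 0.3, "w2_neg": 0.7},
                                             gamma=0.8, empathy_t0=50.0), pe)
        assert np.allclose(m2, m3, atol=1e-12)

    def test_weight_set_must_match_model(self):
        with pytest.raises(el.ConfigurationError):
            el.predict_empathy(UpdateModelSpec("M2"),
                               UpdateParams(weights={"w": 0.4}, gamma=0.5, empathy_t0=50.0),
                               [1.0, 2.0])


class TestFitUpdateModel:
    @staticmethod
    def _simulate(rng, weights, gamma=0.8, t0=50.0, noise=0.0, n=36):
        pe = rng.normal(3, 8, n)
        spec = UpdateModelSpec("M3")
        params = UpdateParams(weights=weights, gamma=gamma, empathy_t0=t0)
        traj = el.predict_empathy(spec, params, pe, first_half=np.arange(n) < n // 2)
        if noise:
            traj = traj + rng.normal(0, noise, n)
        return pe, traj

    def test_noiseless_recovery_within_tolerance(self):
        """Noise-free half-split data: all parameters recovered to ~1e-2."""
        rng = np.random.default_rng(1)
        truth = {"w1_pos": 0.6, "w1_neg": 0.2, "w2_pos": 0.3, "w2_neg": 0.5}
        pe, ratings = self._simulate(rng, truth, gamma=0.8)
        fit = el.fit_update_model(ratings, pe, UpdateModelSpec("M3"), empathy_t0=50.0,
                                  first_half=np.arange(36) < 18, seed=0)
        for name, value in truth.items():
            assert abs(fit.map_params.weights[name] - value) < 1e-2
        assert abs(fit.map_params.gamma - 0.8) < 1e-2
        assert fit.r2 > 1.0 - 1e-9

    def test_noisy_weight_recovery_mean(self):
        """Mean recovered w1_pos over replicates within 0.15 of the truth."""
        estimates = []
        for i in range(60):
            rng = np.random.default_rng(300 + i)
            truth = {"w1_pos": 0.6, "w1_neg": 0.0, "w2_pos": 0.6, "w2_neg": 0.0}
            pe, ratings = self._simulate(rng, truth, gamma=0.8, noise=5.0, n=48)
            fit = el.fit_update_model(ratings, pe, UpdateModelSpec("M3"), empathy_t0=50.0,
                                      first_half=np.arange(48) < 24, seed=i, n_restarts=5)
            estimates.append(fit.map_params.weights["w1_pos"])
        assert abs(np.mean(estimates) - 0.6) < 0.15

    def test_module_level_parameter_recovery_correlations(self):
        """Over 50 synthetic series at 5-point noise, corr(true, fitted) is
        >= 0.7 for the active weight and >= 0.5 for gamma."""
        rng = np.random.default_rng(9)
        tw, fw, tg, fg = [], [], [], []
        for i in range(50):
            w1 = rng.uniform(0.2, 1.0)
            w2 = rng.uniform(0.2, 1.0)
            gamma = rng.uniform(0.3, 0.95)
            truth = {"w1_pos": w1, "w1_neg": 0.0, "w2_pos": w2, "w2_neg": 0.0}
            pe, ratings = self._simulate(rng, truth, gamma=gamma, noise=5.0, n=36)
            fit = el.fit_update_model(ratings, pe, UpdateModelSpec("M3"), empathy_t0=50.0,
                                      first_half=np.arange(36) < 18, seed=i, n_restarts=6)
            tw.append(w1); fw.append(fit.map_params.weights["w1_pos"])
            tg.append(gamma); fg.append(fit.map_params.gamma)
        assert np.corrcoef(tw, fw)[0, 1] >= 0.7
        assert np.corrcoef(tg, fg)[0, 1] >= 0.5

    def test_log_likelihood_monotone_in_model_richness(self, rng):
        """On the same data, maximized log likelihood never decreases with
        model richness (M1 within M2 within M3).  Fitted with near-flat
        priors so the MAP approximates the maximum-likelihood fit; with
        informative priors, shrinkage can produce tiny reversals."""
        pe = rng.normal(2, 8, 36)
        ratings = 50.0 + 0.5 * el.discounted_pe_series(pe, 0.7, "pos") + rng.normal(0, 5, 36)
        # near-flat in the unconstrained space: Beta(a, b) with a, b -> 0 is
        # approximately uniform over logit(gamma)
        weak = el.UpdatePriors(weight_sd=100.0, gamma_a=0.01, gamma_b=0.01,
                               log_sigma_sd=10.0)
        lls, fits = [], []
        for mid in ("M1", "M2", "M3"):
            fit = el.fit_update_model(ratings, pe, UpdateModelSpec(mid), priors=weak,
                                      empathy_t0=50.0, first_half=np.arange(36) < 18,
                                      seed=4, n_restarts=10, warm_starts=fits)
            fits.append(fit)
            lls.append(fit.log_likelihood)
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-6

    def test_single_sign_pe_series_flagged(self, rng):
        pe = np.abs(rng.normal(5, 3, 36))  # strictly positive
        ratings = 50.0 + 0.4 * el.discounted_pe_series(pe, 0.6, "pos")
        fit = el.fit_update_model(ratings, pe, UpdateModelSpec("M2"), empathy_t0=50.0,
                                  seed=0, n_restarts=3)
        assert "w_neg-prior-dominated-no-negative-pes" in fit.warnings

    def test_requires_empathy_t0_and_alignment(self, rng):
        pe = rng.normal(0, 5, 36)
        with pytest.raises(el.InputError):
            el.fit_update_model(pe + 50.0, pe, UpdateModelSpec("M1"))
        with pytest.raises(el.InputError):
            el.fit_update_model(np.zeros(10), pe, UpdateModelSpec("M1"), empathy_t0=50.0)


class TestWeightChangeCorrelation:
    def test_generative_coupling_recovers_positive_correlation(self):
        """Heterogeneous true w1 with low noise: fitted-w1 vs change rho >= 0.5."""
        rng = np.random.default_rng(5)
        weights, changes = [], []
        for _ in range(26):
            w1 = rng.uniform(0.1, 1.0)
            weights.append(w1 + rng.normal(0, 0.05))       # near-perfect fits
            changes.append(10.0 * w1 + rng.normal(0, 1.0))  # change driven by w1
        res = el.weight_change_correlation(weights, changes)
        assert res.rho >= 0.5 and res.pvalue < 0.01

    def test_permuted_scores_give_null_correlation(self):
        rng = np.random.default_rng(8)
        weights = rng.uniform(0.1, 1.0, 26)
        changes = rng.permutation(10.0 * weights)
        res = el.weight_change_correlation(list(weights), list(changes))
        assert abs(res.rho) < 0.3

    def test_zero_variance_flagged(self):
        res = el.weight_change_correlation([0.5] * 6, [1.0, 2, 3, 4, 5, 6])
        assert np.isnan(res.rho) and "zero-variance" in res.warnings

    def test_minimum_n_enforced(self):
        with pytest.raises(el.InputError):
            el.weight_change_correlation([0.1, 0.2], [1.0, 2.0])
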