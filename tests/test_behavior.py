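"""Model-independent behavioral statistics."""

import numpy as np
import pandas as pd
import pytest

import empathlearn as el
from empathlearn.behavior import SpearmanResult
from empathlearn.io import cohort_participants_frame


def _toy_trials(slopes, n_trials=20, intercept=50.0):
    """Perfectly linear painful learning series, one participant per slope."""
    rows = []
    for pid, (group, slope) in enumerate(slopes):
        for t in range(1, n_trials + 1):
            rows.append({
                "participant_id": f"p{pid}", "group": group, "session": "learning",
                "block": 1, "trial_index": t, "pain": "painful", "recipient_id": "A",
                "demonstrator_rating": 50.0, "prediction": 50.0,
                "empathy_rating": intercept + slope * t,
            })
    return pd.DataFrame(rows)


class TestTrends:
    def test_exact_slope_on_linear_series(self):
        trials = _toy_trials([("high", 0.5), ("high", -0.25), ("low", 0.0), ("low", 0.125)])
        res = el.fit_trends(trials, series="empathy")
        got = res.slopes.set_index("participant_id")["slope"]
        assert got["p0"] == pytest.approx(0.5, abs=1e-10)
        assert got["p1"] == pytest.approx(-0.25, abs=1e-10)
        assert got["p2"] == pytest.approx(0.0, abs=1e-10)
        assert got["p3"] == pytest.approx(0.125, abs=1e-10)

    def test_high_group_trend_positive_under_strong_weights(self):
        """A strongly-weighted, low-noise high-empathy cohort shows a clearly
        positive empathy trend over the learning session."""
        priors = el.CohortPriors(w_active=(0.6, 1.0), gamma=(0.5, 0.8),
                                 empathy_t0=(40.0, 50.0), empathy_noise_sd=2.0)
        cohort = el.simulate_cohort(8, priors=priors, seed=17, groups=("high",))
        trials = pd.concat([p.trials for p in cohort], ignore_index=True)
        slopes = [
            np.polyfit(sub.query("session == 'learning' and pain == 'painful'")["trial_index"],
                       sub.query("session == 'learning' and pain == 'painful'")["empathy_rating"],
                       1)[0]
            for _, sub in trials.groupby("participant_id")
        ]
        assert np.mean(slopes) > 0

    def test_participant_order_invariance(self, small_cohort_trials):
        shuffled = small_cohort_trials.sample(frac=1.0, random_state=1)
        a = el.fit_trends(small_cohort_trials, series="empathy")
        b = el.fit_trends(shuffled, series="empathy")
        assert a.group_difference == pytest.approx(b.group_difference, abs=1e-9)
        for g in a.group_means:
            assert a.group_means[g] == pytest.approx(b.group_means[g], abs=1e-9)

    def test_absent_series_raises(self):
        trials = _toy_trials([("high", 0.1), ("low", 0.2)])
        trials["prediction"] = np.nan
        with pytest.raises(el.AbsentSeriesError):
            el.fit_trends(trials, series="prediction")

    def test_unknown_series_rejected(self, small_cohort_trials):
        with pytest.raises(el.InputError):
            el.fit_trends(small_cohort_trials, series="helping")


class TestPEChangeRegression:
    def test_positive_coupling_recovered(self, rng):
        """d_empathy generated as 0.5 * pe + noise: pooled slope near 0.5."""
        rows = []
        for pid in range(8):
            pe = rng.normal(0, 8, 30)
            d = 0.5 * pe + rng.normal(0, 3, 30)
            rows.extend({"participant_id": f"p{pid}", "pe": float(a), "d_empathy": float(b)}
                        for a, b in zip(pe, d))
        res = el.pe_change_regression(pd.DataFrame(rows))
        assert res.params["pe"] == pytest.approx(0.5, abs=0.1)
        assert res.pvalues["pe"] < 1e-6

    def test_null_coupling_within_two_se(self, rng):
        rows = []
        for pid in range(10):
            pe = rng.normal(0, 8, 30)
            d = rng.normal(0, 3, 30)
            rows.extend({"participant_id": f"p{pid}", "pe": float(a), "d_empathy": float(b)}
                        for a, b in zip(pe, d))
        res = el.pe_change_regression(pd.DataFrame(rows))
        assert abs(res.params["pe"]) < 2 * res.bse["pe"]

    def test_study_interaction_detects_halved_coupling(self, rng):
        rows = []
        for study, slope in (("human", 0.5), ("computer", 0.25)):
            for pid in range(8):
                pe = rng.normal(0, 8, 30)
                d = slope * pe + rng.normal(0, 3, 30)
                rows.extend({"participant_id": f"{study}{pid}", "study": study,
                             "pe": float(a), "d_empathy": float(b)} for a, b in zip(pe, d))
        res = el.pe_change_regression(pd.DataFrame(rows), study_col="study")
        assert res.params["pe:C(study)[T.human]"] > 0

    def test_requires_two_participants(self):
        df = pd.DataFrame({"participant_id": ["a"] * 5, "pe": range(5), "d_empathy": range(5)})
        with pytest.raises(el.InputError):
            el.pe_change_regression(df)


class TestChangeScores:
    def test_change_scores_from_simulated_cohort(self, small_cohort, small_cohort_trials):
        participants = cohort_participants_frame(small_cohort)
        scores = el.compute_change_scores(small_cohort_trials, participants)
        assert len(scores) == len(small_cohort)
        assert {"empathy_change", "helping_change", "pain_intensity_change"} <= set(scores.columns)
        # learned change has opposite sign in the two groups on average
        by_group = scores.groupby("group")["empathy_change"].mean()
        assert by_group["high"] > by_group["low"]

    def test_monotone_helping_gives_rho_one(self):
        scores = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(8)],
            "empathy_change": np.arange(8.0),
            "helping_change": np.arange(8.0) ** 3,  # monotone transform
        })
        res = el.change_vs_helping(scores)
        assert res["overall"].rho == pytest.approx(1.0)

    def test_independent_scores_center_on_zero(self, rng):
        rhos = []
        for _ in range(200):
            scores = pd.DataFrame({
                "participant_id": [f"p{i}" for i in range(52)],
                "empathy_change": rng.normal(0, 5, 52),
                "helping_change": rng.normal(0, 5, 52),
            })
            rhos.append(el.change_vs_helping(scores)["overall"].rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_coupled_scores_recover_target_rho_regime(self, rng):
        """helping = 0.5 * empathy + noise calibrated to population rho ~ 0.35:
        the sampling distribution at n = 52 concentrates in [0.1, 0.6]."""
        noise_sd = 0.5 * 7.0 * np.sqrt(1 / 0.35**2 - 1)
        rhos = []
        for _ in range(40):
            emp = rng.normal(0, 7.0, 52)
            scores = pd.DataFrame({
                "participant_id": [f"p{i}" for i in range(52)],
                "empathy_change": emp,
                "helping_change": 0.5 * emp + rng.normal(0, noise_sd, 52),
            })
            rhos.append(el.change_vs_helping(scores)["overall"].rho)
        assert 0.2 <= np.mean(rhos) <= 0.5
        assert np.mean([(0.1 <= r <= 0.6) for r in rhos]) >= 0.8

    def test_zero_variance_flagged(self):
        scores = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(6)],
            "empathy_change": np.ones(6),
            "helping_change": np.arange(6.0),
        })
        res = el.change_vs_helping(scores)["overall"]
        assert isinstance(res, SpearmanResult)
        assert np.isnan(res.rho) and "zero-variance" in res.warnings

    def test_minimum_n_enforced(self):
        scores = pd.DataFrame({
            "participant_id": ["a", "b"],
            "empathy_change": [1.0, 2.0],
            "helping_change": [1.0, 2.0],
        })
        with pytest.raises(el.InputError):
            el.change_vs_helping(scores)
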