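"""Poisson age-effect GLMs, the quasi-binomial alpha model, overdispersion,
AIC comparison, subgroup models, DFE tests."""

import numpy as np
import pandas as pd
import pytest

from strdenovo.agemodels import (compare_expansion_deletion, compare_models_aic,
                                 constraint_interaction_model, dfe_ks_test,
                                 fit_age_model, fit_alpha_model,
                                 fit_offset_interaction_model, fit_poisson_glm,
                                 overdispersion_test, subgroup_age_models)
from strdenovo.errors import FitError, StrDenovoError


def draw_ages(rng, n=1593, mean=33.0, sd=5.5, lo=18.0, hi=50.0):
    ages = rng.normal(mean, sd, n)
    bad = (ages < lo) | (ages > hi)
    while bad.any():
        ages[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (ages < lo) | (ages > hi)
    return ages


class TestFitAgeModel:
    def test_constant_counts_flat_fit(self, rng):
        ages = draw_ages(rng, 200)
        fit = fit_age_model(np.full(200, 4), ages)
        assert fit.coef("age").estimate == pytest.approx(0.0, abs=1e-6)
        assert fit.coef("intercept").estimate == pytest.approx(4.0, abs=1e-6)

    def test_identity_slope_recovery(self, rng):
        """Recovery oracle: mean fitted slope over 60 replicates within 2
        Monte-Carlo SEs of the generating slope."""
        b0, b1, reps = 1.18, 0.14, 60
        slopes = []
        for _ in range(reps):
            ages = draw_ages(rng)
            counts = rng.poisson(b0 + b1 * ages)
            slopes.append(fit_age_model(counts, ages).coef("age").estimate)
        slopes = np.asarray(slopes)
        mc_se = slopes.std(ddof=1) / np.sqrt(reps)
        assert abs(slopes.mean() - b1) < 2 * mc_se

    def test_log_link_wins_on_exponential_counts(self, rng):
        """Model-selection oracle: on exponential-in-age counts the log link
        has lower AIC in nearly every replicate."""
        wins = 0
        reps = 20
        for _ in range(reps):
            ages = draw_ages(rng, 800)
            counts = rng.poisson(np.exp(-2.0 + 0.12 * ages))
            ident = fit_age_model(counts, ages, link="identity")
            log = fit_age_model(counts, ages, link="log")
            wins += log.aic < ident.aic
        assert wins >= 0.9 * reps

    def test_identity_fit_means_positive(self, rng):
        ages = draw_ages(rng, 400)
        counts = rng.poisson(0.3 + 0.01 * ages)
        fit = fit_age_model(counts, ages)
        assert fit.result.mu.min() > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_age_model([1, 2, 3], [30.0, 30.0, 30.0])
        with pytest.raises(FitError):
            fit_age_model([1.5, 2.2], [30.0, 40.0])


class TestOffsetInteraction:
    def _simulate(self, rng, slope_at=0.02, slope_gc=0.02, n=800,
                  denom_at=1200, denom_gc=800, base=-8.0):
        ages = draw_ages(rng, n, mean=31.0, sd=4.5)
        mu_at = denom_at * np.exp(base + slope_at * ages)
        mu_gc = denom_gc * np.exp(base + slope_gc * ages)
        counts = np.concatenate([rng.poisson(mu_at), rng.poisson(mu_gc)])
        age2 = np.concatenate([ages, ages])
        flag = np.concatenate([np.zeros(n), np.ones(n)])
        den = np.concatenate([np.full(n, denom_at), np.full(n, denom_gc)])
        return counts, age2, flag, den

    def test_null_interaction_ci_covers_zero(self, rng):
        counts, ages, flag, den = self._simulate(rng)
        fit = fit_offset_interaction_model(counts, ages, flag, den)
        lo, hi = fit.coef("age:class").ci()
        assert lo < 0 < hi

    def test_differential_slope_detected(self, rng):
        """Recovery oracle mirroring the AT-only vs GC-containing design:
        a stronger class-0 slope yields a negative age x class interaction."""
        counts, ages, flag, den = self._simulate(rng, slope_at=0.06, slope_gc=0.0,
                                                 n=1500, base=-7.0)
        fit = fit_offset_interaction_model(counts, ages, flag, den)
        coef = fit.coef("age:class")
        assert coef.estimate < 0
        assert coef.p_value < 0.05
        expected = 0.0 - 0.06
        assert abs(coef.estimate - expected) < 3 * coef.se

    def test_offset_algebra(self, rng):
        counts, ages, flag, den = self._simulate(rng)
        f1 = fit_offset_interaction_model(counts, ages, flag, den)
        f2 = fit_offset_interaction_model(counts, ages, flag, 2 * den)
        assert f2.coef("intercept").estimate == pytest.approx(
            f1.coef("intercept").estimate - np.log(2), abs=1e-6)
        for term in ("age", "class", "age:class"):
            assert f2.coef(term).estimate == pytest.approx(
                f1.coef(term).estimate, abs=1e-7)

    def test_zero_denominator_dropped(self, rng):
        counts, ages, flag, den = self._simulate(rng, n=50)
        den[0] = 0
        with pytest.warns(UserWarning, match="dropped 1"):
            fit = fit_offset_interaction_model(counts, ages, flag, den)
        assert fit.n_obs == 99


class TestAlphaModel:
    def test_constant_alpha_flat_slope(self, rng):
        ages = draw_ages(rng, 800)
        n = rng.poisson(7, 800) + 1
        pat = rng.binomial(n, 0.72)
        fit = fit_alpha_model(pat, n - pat, ages)
        lo, hi = fit.coef("age").ci()
        assert lo < 0 < hi
        assert fit.aic is None  # quasi-likelihood: no AIC

    def test_slope_recovery(self, rng):
        """Per-year alpha increase recovered within 2 Monte-Carlo SEs."""
        slope, reps = 0.0023, 80
        ests = []
        for _ in range(reps):
            ages = draw_ages(rng, 1593, lo=20.0, hi=48.0)
            n = rng.poisson(7, ages.size) + 1
            p = 0.72 + slope * (ages - 33.0)
            pat = rng.binomial(n, p)
            ests.append(fit_alpha_model(pat, n - pat, ages).coef("age").estimate)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - slope) < 2 * mc_se

    def test_fitted_fractions_in_unit_interval(self, rng):
        ages = draw_ages(rng, 500)
        n = rng.poisson(5, 500) + 1
        pat = rng.binomial(n, 0.75)
        fit = fit_alpha_model(pat, n - pat, ages)
        assert fit.result.mu.min() >= 0 and fit.result.mu.max() <= 1

    def test_children_without_phased_dnms_excluded(self, rng):
        pat = np.array([3, 0, 2, 0])
        mat = np.array([1, 0, 1, 0])
        fit = fit_alpha_model(pat, mat, np.array([30.0, 31.0, 40.0, 41.0]))
        assert fit.n_obs == 2
        assert fit.n_dropped == 2


class TestOverdispersion:
    def test_poisson_null_calibrated(self, rng):
        """Dispersion near 1 and mostly nonsignificant on Poisson data."""
        rejections = 0
        disps = []
        reps = 40
        for _ in range(reps):
            ages = draw_ages(rng, 800)
            counts = rng.poisson(1.0 + 0.1 * ages)
            res = overdispersion_test(fit_age_model(counts, ages))
            disps.append(res.dispersion)
            rejections += res.p_value < 0.05
        assert abs(np.mean(disps) - 1.0) < 0.1
        assert rejections <= 0.2 * reps

    def test_negative_binomial_detected(self, rng):
        ages = draw_ages(rng, 800)
        mu = 1.0 + 0.1 * ages
        counts = rng.negative_binomial(1, 1 / (1 + mu))  # size=1: variance mu(1+mu)
        res = overdispersion_test(fit_age_model(counts, ages))
        assert res.dispersion > 1.2
        assert res.p_value < 0.01

    def test_too_few_observations(self, rng):
        fit = fit_age_model([1, 2, 3], [30.0, 35.0, 40.0])
        with pytest.raises(StrDenovoError):
            overdispersion_test(fit)


class TestAICComparison:
    def test_identical_models_delta_zero(self, rng):
        ages = draw_ages(rng, 300)
        counts = rng.poisson(2 + 0.1 * ages)
        f1 = fit_age_model(counts, ages)
        f2 = fit_age_model(counts, ages)
        out = compare_models_aic({"a": f1, "b": f2})
        assert (out["delta_aic"].abs() < 1e-9).all()

    def test_useless_parameter_costs_about_two(self, rng):
        """A nested model with one pure-noise covariate pays ~ +2 AIC."""
        deltas = []
        for _ in range(30):
            ages = draw_ages(rng, 500)
            counts = rng.poisson(2 + 0.1 * ages)
            noise = rng.normal(size=500)
            small = fit_poisson_glm(counts, {"age": ages}, link="identity")
            big = fit_poisson_glm(counts, {"age": ages, "noise": noise},
                                  link="identity")
            deltas.append(big.aic - small.aic)
        assert abs(np.mean(deltas) - 1.0) < 1.2  # E[delta] = 2 - E[chi2_1] = 1

    def test_quasi_fits_excluded_with_note(self, rng):
        ages = draw_ages(rng, 300)
        counts = rng.poisson(2 + 0.1 * ages)
        n = rng.poisson(6, 300) + 1
        pat = rng.binomial(n, 0.7)
        alpha_fit = fit_alpha_model(pat, n - pat, ages)
        out = compare_models_aic({"poisson": fit_age_model(counts, ages),
                                  "alpha": alpha_fit})
        note = out.loc[out["model"] == "alpha", "note"].item()
        assert "quasi" in note
        assert np.isnan(out.loc[out["model"] == "alpha", "aic"].item())


class TestSubgroupModels:
    def _dnms(self, rng, children, ages, groups_slopes):
        rows = []
        for group, slope in groups_slopes.items():
            lam = 0.5 + slope * ages
            counts = rng.poisson(lam)
            for child, k in zip(children, counts):
                rows.extend([{"child": child, "motif": group}] * k)
        return pd.DataFrame(rows)

    def test_single_group_unadjusted(self, rng):
        children = [f"C{k}" for k in range(400)]
        ages = pd.Series(draw_ages(rng, 400), index=children)
        dnms = self._dnms(rng, children, ages.to_numpy(), {"AC": 0.05})
        out = subgroup_age_models(dnms, ages, "motif")
        assert len(out) == 1
        assert out["p_bonferroni"].item() == pytest.approx(out["p_raw"].item())

    def test_min_dnm_threshold_is_strict(self, rng):
        children = [f"C{k}" for k in range(50)]
        ages = pd.Series(np.linspace(20, 45, 50), index=children)
        rows = [{"child": children[k % 50], "motif": "AC"} for k in range(21)]
        rows += [{"child": children[k % 50], "motif": "AT"} for k in range(20)]
        out = subgroup_age_models(pd.DataFrame(rows), ages, "motif")
        assert set(out["group"]) == {"AC"}  # 21 DNMs in, 20 out

    def test_bonferroni_familywise_error(self, rng):
        """With k null groups, the familywise rejection rate after
        Bonferroni stays at or below ~5%."""
        k, reps, fw_rejections = 5, 150, 0
        children = [f"C{j}" for j in range(300)]
        for _ in range(reps):
            ages = pd.Series(draw_ages(rng, 300), index=children)
            dnms = self._dnms(rng, children, ages.to_numpy(),
                              {f"G{i}": 0.0 for i in range(k)})
            out = subgroup_age_models(dnms, ages, "motif")
            if (out["p_bonferroni"] < 0.05).any():
                fw_rejections += 1
        assert fw_rejections / reps <= 0.09


class TestExpansionDeletion:
    def test_no_difference_under_shared_process(self, rng):
        ages = draw_ages(rng, 1000)
        a = rng.poisson(1.0 + 0.05 * ages)
        b = rng.poisson(1.0 + 0.05 * ages)
        res = compare_expansion_deletion(a, b, ages)
        assert res["p_intercept_difference"] > 0.01
        assert res["p_slope_difference"] > 0.01

    def test_intercept_shift_detected(self, rng):
        ages = draw_ages(rng, 1000)
        a = rng.poisson(3.0 + 0.05 * ages)
        b = rng.poisson(1.0 + 0.05 * ages)
        res = compare_expansion_deletion(a, b, ages)
        assert res["p_intercept_difference"] < 0.01


class TestDFE:
    def test_identical_groups(self):
        s = [0.0, 0.01, 0.02, 0.3]
        stat, p = dfe_ks_test(s, s)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_same_distribution_p_roughly_uniform(self, rng):
        """Calibration: KS p-values under the null are roughly uniform."""
        ps = []
        for _ in range(300):
            a = rng.exponential(0.05, 80)
            b = rng.exponential(0.05, 80)
            ps.append(dfe_ks_test(a, b)[1])
        ps = np.asarray(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.12

    def test_empty_group_rejected(self):
        with pytest.raises(StrDenovoError):
            dfe_ks_test([], [0.1])

    def test_constraint_interaction_null(self, rng):
        ages = draw_ages(rng, 600, mean=31.0, sd=4.5)
        den_neutral, den_constrained = 5000.0, 500.0
        mu_n = den_neutral * np.exp(-9.0 + 0.03 * ages)
        mu_c = den_constrained * np.exp(-9.0 + 0.03 * ages)
        counts = np.concatenate([rng.poisson(mu_n), rng.poisson(mu_c)])
        fit = constraint_interaction_model(
            counts, np.concatenate([ages, ages]),
            np.concatenate([np.zeros(600), np.ones(600)]),
            np.concatenate([np.full(600, den_neutral),
                            np.full(600, den_constrained)]))
        lo, hi = fit.coef("age:class").ci()
        assert lo < 0 < hi
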