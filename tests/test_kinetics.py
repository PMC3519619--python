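"""Longitudinal fitting, percent change, and the statistical comparisons."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from margindrs.kinetics import (KineticsFit, compare_cautery,
                                contrast_decay_map,
                                first_measurement_correlation,
                                fit_longitudinal, interaction_lrt,
                                percent_change, rank_sum_test, spearman_test,
                                time_to_contrast_loss)
from margindrs.synthetic import (ClassConfig, EndpointModel, GeneratorConfig,
                                 LUMPECTOMY_CADENCE, calibrate_defaults,
                                 generate_cohort)

from _oracles import ranksum_enumeration, spearman_enumeration


def _single_site_obs(intercept, slope, times):
    return pd.DataFrame({
        "site_id": "s0", "t_min": times,
        "thb": intercept + slope * np.asarray(times),
        "histology": "adipose", "diagnosis": "benign"})


class TestFitLongitudinal:
    def test_single_noiseless_site_is_exact_ols(self):
        obs = _single_site_obs(3.0, -0.5, np.linspace(2, 14, 9))
        fit = fit_longitudinal(obs, "thb")
        assert fit.model == "ols"
        assert fit.per_site.slope.iloc[0] == pytest.approx(-0.5, abs=1e-10)
        assert fit.per_site.intercept.iloc[0] == pytest.approx(3.0,
                                                               abs=1e-9)

    def test_zero_random_slope_matches_pooled_ols(self):
        """Oracle: when every site shares one true line, the fixed-effect
        slope equals the pooled ordinary least squares slope."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            t = np.sort(rng.uniform(2, 20, 10))
            y = 5.0 - 0.3 * t + rng.normal(0, 0.01, t.size)
            rows.append(pd.DataFrame({
                "site_id": f"s{i}", "t_min": t, "thb": y,
                "histology": "adipose", "diagnosis": "benign"}))
        obs = pd.concat(rows, ignore_index=True)
        fit = fit_longitudinal(obs, "thb")
        slope_ols = np.polyfit(obs.t_min, obs.thb, 1)[0]
        # fixed effects live in the internally scaled fit space; the
        # per-site BLUP slopes are back-transformed to original units
        assert fit.per_site.slope.mean() == pytest.approx(slope_ols,
                                                          abs=1e-4)
        assert np.allclose(fit.per_site.slope, slope_ols, atol=5e-3)

    def test_blup_slopes_track_generating_truth(self):
        cohort = generate_cohort(calibrate_defaults(), seed=11,
                                 classes=(("lumpectomy", "benign"),))
        fit = fit_longitudinal(cohort.observations, "thb")
        truth = cohort.truth[cohort.truth.endpoint == "thb"]
        m = fit.per_site.merge(truth, on="site_id")
        rho = np.corrcoef(m.slope_x, m.slope_y)[0, 1]
        assert rho > 0.9


class TestPercentChange:
    def _fit(self, slopes, intercepts):
        ps = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(len(slopes))],
            "intercept": intercepts, "slope": slopes})
        return KineticsFit(endpoint="thb", per_site=ps,
                           fixed_effects=pd.Series(dtype=float), cov_re=None,
                           loglike=0.0, converged=True, singular=False,
                           n_sites=len(slopes))

    def test_zero_slope_gives_zero_percent_change(self):
        pc = percent_change(self._fit([0.0], [5.0]), 30.0)
        assert pc.median == 0.0

    def test_linear_in_horizon(self):
        fit = self._fit([-0.5, -0.2], [10.0, 4.0])
        pc10 = percent_change(fit, 10.0)
        pc30 = percent_change(fit, 30.0)
        assert pc30.median == pytest.approx(3.0 * pc10.median, rel=1e-12)

    def test_sign_convention_with_negative_intercept(self):
        pc = percent_change(self._fit([1.0], [-2.0]), 10.0)
        assert pc.median == pytest.approx(500.0)

    def test_zero_intercept_site_flagged_and_excluded(self):
        fit = self._fit([1.0, 1.0], [0.0, 2.0])
        with pytest.warns(UserWarning):
            pc = percent_change(fit, 10.0)
        assert pc.n_flagged == 1
        assert pc.median == pytest.approx(500.0)

    def test_table_row_linearity_10_vs_30_minutes(self):
        """A site at -44.2% by 30 minutes sits at -14.73% by 10 minutes."""
        fit = self._fit([-0.442 / 30.0], [1.0])
        assert percent_change(fit, 30.0).median == pytest.approx(-44.2)
        assert percent_change(fit, 10.0).median == pytest.approx(-14.73,
                                                                 abs=0.005)


class TestTimeToContrastLoss:
    def test_thb_benign_vs_positive_crossing(self):
        res = time_to_contrast_loss(-44.2, 30.0, -92.3)
        assert res["minutes_rounded"] == 63

    def test_beta_carotene_crossing(self):
        res = time_to_contrast_loss(-8.2, 30.0, 29.8)
        assert res["minutes_rounded"] == 109
        assert res["minutes"] == pytest.approx(30.0 * 29.8 / 8.2)

    def test_identity_horizon(self):
        assert time_to_contrast_loss(-20.0, 30.0, -20.0)["minutes"] == 30.0

    def test_zero_rate_flagged_infinite(self):
        res = time_to_contrast_loss(0.0, 30.0, -50.0)
        assert np.isinf(res["minutes"]) and res["flag"] == "zero-rate"


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        res = rank_sum_test(np.array([1.0, 2.0, 5.0]),
                            np.array([1.0, 2.0, 5.0]))
        assert res["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_all_tied_data_flagged(self):
        res = rank_sum_test(np.ones(4), np.ones(3))
        assert res["flag"] == "all-tied" and res["p_value"] == 1.0

    def test_separated_triples_exact_p(self):
        """Oracle: 1 favorable assignment out of C(6,3) = 20."""
        from scipy.stats import mannwhitneyu
        a, b = np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])
        one_sided = mannwhitneyu(a, b, alternative="less", method="exact")
        assert one_sided.pvalue == pytest.approx(1.0 / 20.0)
        assert rank_sum_test(a, b)["p_value"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 5), rng.integers(3, 5)
        a = rng.normal(0, 1, n)
        b = rng.normal(0.5, 1, m)
        res = rank_sum_test(a, b)
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(
            ranksum_enumeration(a, b), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone_gives_rho_one(self):
        res = spearman_test(np.arange(6.0), np.arange(6.0) ** 3)
        assert res["rho"] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1 = spearman_test(x, y)["rho"]
        r2 = spearman_test(np.exp(x), y ** 3)["rho"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        res = spearman_test(x, y)
        rho_o, p_o = spearman_enumeration(x, y)
        assert res["method"] == "exact"
        assert res["rho"] == pytest.approx(rho_o, abs=1e-12)
        assert res["p_value"] == pytest.approx(p_o, abs=1e-12)


def _two_class_cohort(slope_benign, slope_malignant, seed, n_per=8,
                      noise=0.01):
    """Small two-diagnosis cohort with controlled kinetic rates."""
    def model(mean, sd):
        return {ep: EndpointModel(intercept_median=30.0,
                                  intercept_sigma=0.3, mode="independent",
                                  rate_mean=mean, rate_sd=sd)
                for ep in ("thb", "beta_carotene", "mean_musp", "dye")}

    cadence = dataclasses.replace(LUMPECTOMY_CADENCE,
                                  interval_range=(0.8, 1.2),
                                  duration_range=(10.0, 14.0))
    classes = (
        ClassConfig("mastectomy", "benign", {"adipose": n_per}, cadence,
                    model(*slope_benign)),
        ClassConfig("mastectomy", "malignant", {"IDC": n_per}, cadence,
                    model(*slope_malignant)),
    )
    cfg = GeneratorConfig(classes=classes, noise_sd=noise)
    return generate_cohort(cfg, seed=seed)


class TestInteractionLrt:
    def test_extreme_separation_is_detected(self):
        cohort = _two_class_cohort((0.0, 0.02), (-1.0, 0.02), seed=0,
                                   noise=0.005)
        res = interaction_lrt(cohort.observations, "thb")
        assert res["p_value"] < 1e-3

    def test_single_class_rejected(self):
        cohort = generate_cohort(calibrate_defaults(), seed=0,
                                 classes=(("lumpectomy", "benign"),))
        with pytest.raises(ValueError):
            interaction_lrt(cohort.observations, "thb")


class TestCompareCautery:
    def test_detects_first_value_shift(self):
        """Groups generated with distinct baselines should reject."""
        a = _two_class_cohort((-0.05, 0.1), (-0.05, 0.1), seed=1)
        obs = a.observations
        benign = obs[obs.diagnosis == "benign"].copy()
        shifted = obs[obs.diagnosis == "malignant"].copy()
        shifted["thb"] = shifted["thb"] * 3.0
        res = compare_cautery(shifted, benign, "thb")
        assert res["first_value"]["p_value"] < 0.01

    def test_empty_group_rejected(self):
        obs = _two_class_cohort((0, 0.1), (0, 0.1), seed=2).observations
        with pytest.raises(ValueError):
            compare_cautery(obs.iloc[0:0], obs, "thb")


class TestFirstMeasurementCorrelation:
    def test_washout_endpoint_correlates_with_delay(self):
        cohort = generate_cohort(calibrate_defaults(), seed=5,
                                 classes=(("lumpectomy", "benign"),))
        res = first_measurement_correlation(cohort.observations, "dye")
        assert res["rho"] < 0 and res["p_value"] < 0.05

    def test_requires_three_sites(self):
        obs = _single_site_obs(3.0, 0.0, [2.0, 3.0])
        with pytest.raises(ValueError):
            first_measurement_correlation(obs, "thb")


class TestContrastDecayMap:
    def test_zero_change_leaves_map_untouched(self):
        m = np.linspace(1, 4, 16).reshape(4, 4)
        assert np.array_equal(contrast_decay_map(m, 0.0), m)

    def test_minus_fifty_percent_halves_pixels(self):
        m = np.full((3, 3), 8.0)
        np.testing.assert_allclose(contrast_decay_map(m, -50.0), 4.0)

    def test_below_minus_100_clips_at_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = contrast_decay_map(np.ones((2, 2)), -150.0)
        assert np.array_equal(out, np.zeros((2, 2)))

    def test_upsampling_scales_shape(self):
        out = contrast_decay_map(np.ones((4, 4)), -10.0, upsample=5)
        assert out.shape == (20, 20)
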