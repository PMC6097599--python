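import numpy as np
import pandas as pd
import pytest

from endophys.comparative_stats import (
    StatsError,
    ThermalResponseFit,
    anova_snk,
    compare_locations,
    estimate_prwe,
    fit_thermal_response,
    lrt_random_effect,
)
from endophys.synthetic_data import linear_rwe_cohort, quadratic_record_cohort


def exact_quadratic_records(coef=(2.0, -0.05, 0.004), n_indiv=3):
    """Noise-free records lying exactly on a quadratic in (Ta - 26)."""
    a, b, c = coef
    rows = []
    for i in range(n_indiv):
        for ta in (6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0):
            x = ta - 26.0
            rows.append(
                {
                    "population_id": "p1",
                    "animal_id": f"p1-{i}",
                    "ta_C": ta,
                    "y": a + b * x + c * x * x,
                }
            )
    return pd.DataFrame(rows)


class TestThermalResponseFit:
    def test_noise_free_quadratic_recovered_exactly(self):
        df = exact_quadratic_records()
        fit = fit_thermal_response(df, "y", "p1")
        for ta in (6.0, 15.5, 26.0, 34.0):
            x = ta - 26.0
            assert fit.predict(ta) == pytest.approx(
                2.0 - 0.05 * x + 0.004 * x * x, abs=1e-6
            )

    def test_single_individual_rejected(self):
        df = exact_quadratic_records(n_indiv=1)
        with pytest.raises(StatsError, match="individuals"):
            fit_thermal_response(df, "y", "p1")

    def test_predictions_invariant_to_ta_units(self):
        """Recoding Ta (affine transform) must not change fitted values."""
        df = exact_quadratic_records()
        noisy = df.copy()
        rng = np.random.default_rng(0)
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        fit = fit_thermal_response(noisy, "y", "p1")
        recoded = noisy.copy()
        recoded["ta_C"] = recoded["ta_C"] * 1.8 + 32.0  # degF
        fit_f = fit_thermal_response(recoded, "y", "p1")
        for ta in (6.0, 20.0, 34.0):
            assert fit_f.predict(ta * 1.8 + 32.0) == pytest.approx(
                fit.predict(ta), abs=1e-8
            )

    def test_refit_reproduces_coefficients(self):
        df = quadratic_record_cohort(n_populations=1, seed=11)
        a = fit_thermal_response(df, "mi_vo2", "pop1")
        b = fit_thermal_response(df, "mi_vo2", "pop1")
        assert np.allclose(a.coef, b.coef, atol=1e-8)


class TestLRT:
    def test_null_limit_statistic_near_zero(self):
        df = quadratic_record_cohort(n_populations=1, indiv_sd=0.0, seed=4)
        full = fit_thermal_response(df, "mi_vo2", "pop1")
        none = fit_thermal_response(df, "mi_vo2", "pop1", include_random=False)
        stat, p = lrt_random_effect(full, none)
        assert stat >= 0.0
        assert stat < 2.0 and p > 0.15

    def test_strong_random_effect_detected(self):
        df = quadratic_record_cohort(
            n_populations=1, n_individuals=8, indiv_sd=0.45, resid_sd=0.15, seed=4
        )
        full = fit_thermal_response(df, "mi_vo2", "pop1")
        none = fit_thermal_response(df, "mi_vo2", "pop1", include_random=False)
        stat, p = lrt_random_effect(full, none)
        assert p < 0.001

    def test_statistic_invariant_to_ta_recoding(self):
        df = quadratic_record_cohort(n_populations=1, seed=9)
        stat_a = lrt_random_effect(
            fit_thermal_response(df, "mi_vo2", "pop1"),
            fit_thermal_response(df, "mi_vo2", "pop1", include_random=False),
        )[0]
        df2 = df.copy()
        df2["ta_C"] = df2["ta_C"] * 2.0 - 7.0
        stat_b = lrt_random_effect(
            fit_thermal_response(df2, "mi_vo2", "pop1"),
            fit_thermal_response(df2, "mi_vo2", "pop1", include_random=False),
        )[0]
        assert stat_a == pytest.approx(stat_b, abs=1e-6)

    def test_mismatched_fits_rejected(self):
        df = quadratic_record_cohort(n_populations=1, seed=1)
        other = quadratic_record_cohort(n_populations=1, seed=2, ta_grid=(6.0, 20.0, 34.0))
        with pytest.raises(StatsError):
            lrt_random_effect(
                fit_thermal_response(df, "mi_vo2", "pop1"),
                fit_thermal_response(other, "mi_vo2", "pop1", include_random=False),
            )


class TestCompareLocations:
    def test_large_intercept_shift_detected(self):
        # one population offset by 5 residual SDs
        df = quadratic_record_cohort(seed=3, pop_effects=[0.0, 0.75, 0.0, 0.0])
        res = compare_locations(df, "mi_vo2", "pop1")
        assert res.main_effect.pvalue < 0.001
        assert res.main_effect.df == 3 and res.interaction.df == 6
        shifted = [c for c in res.contrasts if c.population_id == "pop2"][0]
        assert shifted.estimate == pytest.approx(0.75, abs=0.2)

    def test_permuting_labels_destroys_effect(self):
        df = quadratic_record_cohort(seed=3, pop_effects=[0.0, 0.75, 0.0, 0.0])
        p_true = compare_locations(df, "mi_vo2", "pop1").main_effect.pvalue
        rng = np.random.default_rng(0)
        perms = []
        animals = df["animal_id"].unique()
        for _ in range(8):
            # permute whole individuals across populations (keeps grouping)
            new_pop = dict(zip(animals, rng.permutation([a.split("-")[0] for a in animals])))
            shuffled = df.copy()
            shuffled["population_id"] = shuffled["animal_id"].map(new_pop)
            perms.append(compare_locations(shuffled, "mi_vo2", "pop1").main_effect.pvalue)
        assert p_true < 0.001
        assert np.median(perms) > 0.05

    def test_missing_reference_rejected(self):
        df = quadratic_record_cohort(seed=0)
        with pytest.raises(StatsError, match="reference"):
            compare_locations(df, "mi_vo2", "nowhere")

    def test_single_population_rejected(self):
        df = quadratic_record_cohort(n_populations=1, seed=0)
        with pytest.raises(StatsError):
            compare_locations(df, "mi_vo2", "pop1")


class TestPRWE:
    def test_linear_root(self):
        # fitted RWE = 2.5 - 0.10 * Ta crosses 1 at exactly 15 degC
        fit = ThermalResponseFit(
            population_id="p",
            variable="rwe",
            coef=np.array([2.5, -0.10, 0.0]),
            se=np.zeros(3),
            var_random=0.0,
            var_resid=0.0,
            n_individuals=2,
            n_obs=8,
            ta_center=0.0,
            ta_scale=1.0,
            loglik_ml=0.0,
            has_random=True,
            boundary=True,
            ta_range=(6.0, 34.0),
        )
        est = estimate_prwe(fit)
        assert est.found and not est.degenerate and not est.extrapolated
        assert est.prwe_C == pytest.approx(15.0, abs=1e-6)

    def test_constant_curve_is_degenerate(self):
        fit = ThermalResponseFit(
            population_id="p",
            variable="rwe",
            coef=np.array([1.0, 0.0, 0.0]),
            se=np.zeros(3),
            var_random=0.0,
            var_resid=0.0,
            n_individuals=2,
            n_obs=8,
            ta_center=0.0,
            ta_scale=1.0,
            loglik_ml=0.0,
            has_random=True,
            boundary=True,
            ta_range=(6.0, 34.0),
        )
        est = estimate_prwe(fit)
        assert est.degenerate and not est.found

    def test_no_real_root_flagged(self):
        fit = ThermalResponseFit(
            population_id="p",
            variable="rwe",
            coef=np.array([3.0, 0.0, 0.1]),  # min 3.0, never crosses 1
            se=np.zeros(3),
            var_random=0.0,
            var_resid=0.0,
            n_individuals=2,
            n_obs=8,
            ta_center=20.0,
            ta_scale=9.0,
            loglik_ml=0.0,
            has_random=True,
            boundary=True,
            ta_range=(6.0, 34.0),
        )
        est = estimate_prwe(fit)
        assert not est.found and est.prwe_C is None

    def test_recovery_from_simulated_cohort(self):
        est = estimate_prwe(linear_rwe_cohort(prwe_C=10.4, seed=0), "pop1")
        assert est.found
        assert est.prwe_C == pytest.approx(10.4, abs=1.0)


class TestAnovaSNK:
    def test_two_equal_one_distant_group(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, mu in zip(["g1", "g2", "g3"], [1.0, 1.0, 5.0]):
            for v in mu + rng.normal(0, 0.1, 6):
                rows.append({"population_id": g, "v": v})
        res = anova_snk(pd.DataFrame(rows), "v")
        letters = res.snk_letters
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] != letters["g1"]
        assert res.anova_p < 1e-10

    def test_letter_grouping_is_valid(self):
        """Every letter covers a contiguous span of ordered means whose
        extremes are non-significant under the studentized range at the
        span's size — the defining property of an SNK letter display."""
        from scipy import stats as ss

        rng = np.random.default_rng(2)
        rows = []
        for g, mu in zip(["a", "b", "c", "d"], [0.0, 0.3, 0.6, 2.0]):
            for v in mu + rng.normal(0, 0.4, 6):
                rows.append({"population_id": g, "v": v})
        df = pd.DataFrame(rows)
        res = anova_snk(df, "v")

        groups = sorted(df["population_id"].unique())
        means = {g: df.loc[df.population_id == g, "v"].mean() for g in groups}
        mse = np.mean([df.loc[df.population_id == g, "v"].var(ddof=1) for g in groups])
        ordered = sorted(groups, key=means.get)
        all_letters = sorted(set("".join(res.snk_letters.values())))
        assert all_letters  # at least one group letter
        for letter in all_letters:
            span = [i for i, g in enumerate(ordered) if letter in res.snk_letters[g]]
            assert span == list(range(span[0], span[-1] + 1))  # contiguous
            r = len(span)
            if r > 1:
                q = (means[ordered[span[-1]]] - means[ordered[span[0]]]) / np.sqrt(mse / 6)
                assert q <= ss.studentized_range.ppf(0.95, r, len(df) - len(groups))

    def test_single_group_rejected(self):
        df = pd.DataFrame({"population_id": ["g1"] * 4, "v": [1.0, 2.0, 1.5, 1.2]})
        with pytest.raises(StatsError):
            anova_snk(df, "v")

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            {"population_id": ["g1"] * 3 + ["g2"] * 3, "v": [1.0] * 3 + [5.0] * 3}
        )
        with pytest.raises(StatsError):
            anova_snk(df, "v")
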