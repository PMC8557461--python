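"""Allele-frequency tests: CMH against a hand-coded formula, bootstrap
calibration, HWE, binomial CIs, the variance test and power simulation."""

import numpy as np
import pytest

import fizsel as fz


def cmh_textbook(tables):
    """Independent CMH evaluation: χ² = (Σ(a − E[a]))² / ΣVar(a), with the
    conditional hypergeometric moments of the top-left cell per stratum."""
    num = 0.0
    var = 0.0
    for t in tables:
        a = t[0][0]
        r1, r2 = t[0][0] + t[0][1], t[1][0] + t[1][1]
        c1 = t[0][0] + t[1][0]
        n = r1 + r2
        num += a - r1 * c1 / n
        var += r1 * r2 * c1 * (n - c1) / (n**2 * (n - 1))
    return num**2 / var


def small_dataset(rows):
    months = ("June", "September")
    samples = []
    for i, (km, nm, cc, cg, gg) in enumerate(rows):
        samples.append(
            fz.CollectionSample(
                2016 + i // 2, months[i % 2], nm - km, km, cc, cg, gg
            )
        )
    return fz.CountsDataset(samples)


class TestCMH:
    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(100):
            k = rng.integers(1, 6)
            tables = rng.integers(1, 80, size=(k, 2, 2)).tolist()
            stat, _ = fz.cmh_test(fz.StratifiedTables(tables), continuity=False)
            assert stat == pytest.approx(cmh_textbook(tables), abs=1e-9)

    def test_no_association_gives_null_result(self):
        stat, p = fz.cmh_test(
            fz.StratifiedTables([[[10, 10], [10, 10]]] * 3), continuity=False
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_stratum_hand_value(self):
        tables = [[[30, 10], [10, 30]]]
        stat, p = fz.cmh_test(fz.StratifiedTables(tables), continuity=False)
        assert stat == pytest.approx(cmh_textbook(tables), abs=1e-9)
        assert p < 0.001

    def test_evidence_accumulates_across_strata(self):
        one, _ = fz.cmh_test(fz.StratifiedTables([[[30, 10], [10, 30]]]))
        two, _ = fz.cmh_test(fz.StratifiedTables([[[30, 10], [10, 30]]] * 2))
        assert two > one

    def test_zero_margin_stratum_dropped_with_warning(self):
        tables = [[[30, 10], [10, 30]], [[0, 0], [5, 5]]]
        with pytest.warns(RuntimeWarning):
            stat, _ = fz.cmh_test(fz.StratifiedTables(tables))
        ref, _ = fz.cmh_test(fz.StratifiedTables(tables[:1]))
        assert stat == pytest.approx(ref)


class TestBootstrapCumulativeDiff:
    def test_maximal_separation(self):
        ds = small_dataset([(0, 50, 0, 0, 50), (50, 50, 50, 0, 0)])
        # females all-G vs males all-C in collection 1 and the reverse in 2
        res = fz.bootstrap_cumulative_diff_test(ds, "sex", n_rep=4000, seed=0)
        assert res.statistic == pytest.approx(0.0)  # +1 and -1 cancel
        one = small_dataset([(0, 50, 0, 0, 50)])
        res = fz.bootstrap_cumulative_diff_test(one, "sex", n_rep=4000, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 1e-3

    def test_negative_observed_diff_gives_large_p(self):
        # fixed group order (F - M): male excess of G must NOT look significant
        ds = small_dataset([(40, 50, 30, 15, 5)] * 4)
        res = fz.bootstrap_cumulative_diff_test(ds, "sex", n_rep=4000, seed=1)
        assert res.statistic < 0
        assert res.p_value > 0.9

    def test_p_resolution_is_one_over_n_rep(self):
        ds = small_dataset([(25, 50, 30, 40, 30)] * 4)
        res = fz.bootstrap_cumulative_diff_test(ds, "season", sex="F", n_rep=1000, seed=2)
        assert (res.p_value * res.n_replicates) == pytest.approx(
            round(res.p_value * res.n_replicates)
        )

    def test_season_contrast_requires_paired_collections(self):
        ds = small_dataset([(25, 50, 30, 40, 30)])  # June only
        with pytest.raises(ValueError, match="2016"):
            fz.bootstrap_cumulative_diff_test(ds, "season", sex="F", n_rep=10, seed=0)

    def test_run_to_run_variation_small(self):
        ds = fz.simulate_counts(fz.preset_scenarios("field_survey", seed=21))
        ps = [
            fz.bootstrap_cumulative_diff_test(ds, "sex", n_rep=10_000, seed=s).p_value
            for s in range(8)
        ]
        assert max(ps) - min(ps) < 0.02


class TestHWE:
    def test_exact_hwe_counts(self):
        # 0.4^2, 2*0.4*0.6, 0.6^2 at n=100 with matching male frequency
        ds = small_dataset([(40, 100, 36, 48, 16)])
        res = fz.hwe_test(ds.samples[0])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_complete_heterozygote_deficit(self):
        s = fz.CollectionSample(2016, "June", 25, 25, 25, 0, 25)
        res = fz.hwe_test(s)
        assert res["chi2"] == pytest.approx(50.0)
        assert res["p"] < 1e-11

    def test_bonferroni_caps_at_one(self):
        s = fz.CollectionSample(2016, "June", 30, 20, 40, 40, 20)
        res = fz.hwe_test(s, n_tests=10)
        assert res["p_adjusted"] == min(1.0, res["p"] * 10)
        assert res["p_adjusted"] >= res["p"]

    def test_females_only_source(self):
        s = fz.CollectionSample(2016, "June", 50, 0, 25, 50, 25)
        res = fz.hwe_test(s, allele_freq_source="females_only")
        assert res["allele_freq"] == pytest.approx(0.5)
        all_flies = fz.hwe_test(s)
        assert all_flies["allele_freq"] < 0.5  # males drag the G frequency down


class TestBinomialCI:
    def test_boundaries(self):
        assert fz.binomial_ci(0, 10).lower == 0.0
        assert fz.binomial_ci(10, 10).upper == 1.0

    def test_wilson_closed_form(self):
        ci = fz.binomial_ci(50, 100)
        z = 1.959963984540054
        n, p = 100, 0.5
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        assert ci.lower == pytest.approx(centre - half, abs=1e-10)
        assert ci.upper == pytest.approx(centre + half, abs=1e-10)
        assert ci.lower + ci.upper == pytest.approx(1.0)

    def test_clopper_pearson_is_wider(self):
        w = fz.binomial_ci(5, 20)
        cp = fz.binomial_ci(5, 20, method="clopper_pearson")
        assert cp.upper - cp.lower > w.upper - w.lower

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fz.binomial_ci(1, 0)


class TestVarianceSexTest:
    def test_identical_counts_zero_statistic(self):
        ds = small_dataset([(20, 100, 60, 20, 20), (30, 100, 50, 20, 30), (10, 100, 80, 0, 20)])
        # females constructed with identical per-collection frequencies as males
        ds2 = small_dataset(
            [(20, 100, 80, 0, 20), (30, 100, 70, 0, 30), (10, 100, 90, 0, 10)]
        )
        res = fz.variance_sex_test(ds2, n_rep=100, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_strong_female_fluctuation_detected(self):
        rows = []
        for i in range(6):
            f = 0.2 if i % 2 == 0 else 0.6
            n = 500
            gg = round(f**2 * n)
            cg = round(2 * f * (1 - f) * n)
            rows.append((round(0.4 * n), n, n - gg - cg, cg, gg))
        ds = small_dataset(rows)
        res = fz.variance_sex_test(ds, n_rep=4000, seed=3)
        assert res.p_value < 0.01

    def test_requires_three_collections(self):
        ds = small_dataset([(20, 50, 30, 40, 30), (25, 50, 30, 40, 30)])
        with pytest.raises(ValueError):
            fz.variance_sex_test(ds, n_rep=10)


class TestSeasonalPower:
    SIZES = [(40, 60), (30, 50), (90, 22), (55, 45), (60, 68)]

    def test_null_effect_power_near_alpha(self):
        res = fz.seasonal_power(
            self.SIZES, effect=0.0, n_sim=400, n_rep=1000, seed=0
        )
        assert res["power"] == pytest.approx(0.05, abs=2.5 * max(res["se"], 0.011))

    def test_large_effect_high_power(self):
        res = fz.seasonal_power(
            [(200, 200)] * 5, effect=0.3, n_sim=100, n_rep=1000, seed=1
        )
        assert res["power"] > 0.95

    def test_power_nondecreasing_in_effect(self):
        powers = [
            fz.seasonal_power(
                [(60, 60)] * 5, effect=e, n_sim=150, n_rep=600, seed=7
            )["power"]
            for e in (0.0, 0.04, 0.1, 0.2)
        ]
        assert all(b >= a - 0.02 for a, b in zip(powers, powers[1:]))

    def test_effect_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fz.seasonal_power(self.SIZES, effect=0.8, base_freq=0.5)

    def test_cmh_variant_runs(self):
        res = fz.seasonal_power(self.SIZES, effect=0.1, n_sim=20, test="cmh", seed=2)
        assert 0.0 <= res["power"] <= 1.0
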