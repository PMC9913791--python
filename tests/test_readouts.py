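"""Bead-corrected counts, tumor-growth ratio, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank

from epidac import (absolute_cell_count, km_estimate, logrank_statistic,
                    logrank_test, normalized_tumor_growth, significance_band)


class TestAbsoluteCellCount:
    def test_unit_case(self):
        assert absolute_cell_count(5, 5, 7.0, 7.0, 1.0) == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        # (1000 x 10) / (500 x 30 x 0.5) = 10000 / 7500
        value = absolute_cell_count(1000, 500, 10.0, 30.0, 0.5)
        assert value == pytest.approx(10000 / 7500)

    def test_linear_in_cell_count_inverse_in_bead_count(self):
        base = absolute_cell_count(100, 50, 10.0, 30.0, 0.5)
        assert absolute_cell_count(200, 50, 10.0, 30.0, 0.5) == pytest.approx(2 * base)
        assert absolute_cell_count(100, 100, 10.0, 30.0, 0.5) == pytest.approx(base / 2)

    def test_zero_beads_is_an_error(self):
        with pytest.raises(ValueError, match="bead_count"):
            absolute_cell_count(100, 0, 10.0, 30.0, 0.5)

    def test_standard_variant_multiplies_concentration(self):
        published = absolute_cell_count(100, 50, 10.0, 30.0, 0.5)
        standard = absolute_cell_count(100, 50, 10.0, 30.0, 0.5, formula="standard")
        assert standard == pytest.approx(published * 0.5 ** 2)

    @given(st.floats(1, 1e6), st.floats(1, 1e6))
    def test_homogeneity_property(self, cells, beads):
        base = absolute_cell_count(cells, beads, 10.0, 30.0, 0.5)
        assert absolute_cell_count(3 * cells, beads, 10.0, 30.0, 0.5) == pytest.approx(3 * base)


def flow_frame(rows):
    return pd.DataFrame(rows, columns=["model", "arm", "day", "hcd45_count",
                                       "mcd45_count", "bead_count",
                                       "bead_volume_ul", "cell_volume_ul",
                                       "bead_concentration_per_ul"])


class TestTumorGrowth:
    def _arm(self, arm, day1, day5):
        return flow_frame([
            ("m", arm, 1, day1, 0, 1000, 50.0, 30.0, 1.0),
            ("m", arm, 5, day5, 0, 1000, 50.0, 30.0, 1.0),
        ])

    def test_equal_growth_gives_unity(self):
        assert normalized_tumor_growth(self._arm("DAC", 100, 300),
                                       self._arm("vehicle", 50, 150)) == pytest.approx(1.0)

    def test_halving_versus_doubling(self):
        assert normalized_tumor_growth(self._arm("DAC", 100, 50),
                                       self._arm("vehicle", 100, 200)) == pytest.approx(0.25)

    def test_missing_day_errors(self):
        treated = flow_frame([("m", "DAC", 1, 100, 0, 1000, 50.0, 30.0, 1.0)])
        with pytest.raises(ValueError, match="day-5"):
            normalized_tumor_growth(treated, self._arm("vehicle", 100, 200))

    def test_sensitive_models_grow_less_than_less_sensitive(self, default_cohort):
        cohort = default_cohort
        ratios = {}
        for model in cohort.config.model_names:
            f = cohort.flow[cohort.flow["model"] == model]
            ratios[model] = normalized_tumor_growth(f[f["arm"] == "DAC"],
                                                    f[f["arm"] == "vehicle"])
        for s in cohort.config.sensitive_models:
            for l in cohort.config.less_sensitive_models:
                assert ratios[s] < ratios[l]


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([10, 20], [1, 1])
        assert km.values.tolist() == [[0.0, 1.0], [10.0, 0.5], [20.0, 0.0]]

    def test_all_censored_stays_at_one(self):
        km = km_estimate([5, 9, 12], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_event_steps_to_zero(self):
        km = km_estimate([7], [1])
        assert km["survival"].iloc[-1] == 0.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=25).round(2)
        km = km_estimate(times, np.ones_like(times, dtype=int))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 5.0], [1, 1])


class TestLogrank:
    def test_identical_arms_give_zero_statistic_p_one(self):
        stat, p = logrank_test([5, 8, 13], [1, 1, 1], [5, 8, 13], [1, 1, 1])
        assert stat == 0.0 and p == 1.0

    def test_label_swap_invariance(self):
        a = ([3, 6, 9, 14], [1, 1, 0, 1])
        b = ([10, 12, 20], [1, 1, 1])
        s1, p1 = logrank_test(*a, *b)
        s2, p2 = logrank_test(*b, *a)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 12), rng.exponential(25, 12)
        ea = (rng.random(12) > 0.2).astype(int)
        eb = (rng.random(12) > 0.2).astype(int)
        stat, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [5], [1])

    def test_null_pvalues_approximately_uniform(self):
        """Chi-square p under exchangeable exponential arms (5 vs 5)."""
        from scipy import stats
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            t = rng.exponential(20, size=10)
            _, p = logrank_test(t[:5], np.ones(5, int), t[5:], np.ones(5, int))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_statistic_invariant_under_time_rescaling(self):
        a = ([3, 6, 9], [1, 1, 1])
        b = ([12, 15, 30], [1, 1, 1])
        s1 = logrank_statistic(*a, *b)
        s2 = logrank_statistic(np.array(a[0]) * 7.0, a[1], np.array(b[0]) * 7.0, b[1])
        assert s1 == pytest.approx(s2)

    def test_treated_arms_separate_from_vehicle(self, default_cohort):
        surv = default_cohort.survival
        worse = 0
        for model in default_cohort.config.model_names:
            sm = surv[surv["model"] == model]
            v = sm[sm["arm"] == "vehicle"]
            d2 = sm[sm["arm"] == "DAC_2cycle"]
            if d2["time_days"].median() > v["time_days"].median():
                worse += 1
        assert worse >= 4  # treated arms live longer in nearly every model


class TestSignificanceBands:
    @pytest.mark.parametrize("p,band", [
        (0.1234, "ns"), (0.0332, "*"), (0.0021, "**"), (0.0002, "***"),
        (0.05, "ns"), (0.049999, "*"),
    ])
    def test_prism_bands(self, p, band):
        assert significance_band(p) == band
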