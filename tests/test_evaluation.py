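"""Evaluation statistics: AUC, exact binomial CIs, band diagnostics,
effect sizes, group tests, hospital-free days, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mechanosep import (
    BandContingency,
    band_diagnostics,
    band_trend_report,
    bootstrap_auc_ci,
    clopper_pearson,
    cohens_d,
    group_tests,
    hospital_free_days,
    km_logrank,
    roc_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3], [1, 1, 0]) == 1.0

    def test_chance_by_pair_counting(self):
        # positives (0.7, 0.4) vs negatives (0.2, 0.8): 2 of 4 pairs concordant
        assert roc_auc([0.2, 0.7, 0.8, 0.4], [0, 1, 0, 1]) == 0.5

    def test_all_ties(self):
        assert roc_auc([1.0] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_trapezoidal(self, rng):
        """Pair counting equals trapezoidal ROC integration."""
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            y = rng.integers(0, 2, 80)
            if y.min() == y.max():
                continue
            s = np.round(rng.standard_normal(80), 1)  # force ties
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_bootstrap_ci_contains_point(self, rng):
        y = rng.integers(0, 2, 150)
        s = y + rng.standard_normal(150)
        auc = roc_auc(s, y)
        lo, hi = bootstrap_auc_ci(s, y, n_boot=500, rng=rng)
        assert lo <= auc <= hi


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    def test_contains_point_estimate(self):
        lo, hi = clopper_pearson(185, 195)
        assert lo < 185 / 195 < hi

    def test_bisection_oracle(self):
        """Invert the binomial tails directly and compare."""
        from scipy.optimize import brentq
        for k, n in [(185, 195), (10, 195), (3, 50), (1, 10)]:
            lo, hi = clopper_pearson(k, n)
            lo_o = brentq(lambda p: stats.binom.sf(k - 1, n, p) - 0.025, 1e-12, 1 - 1e-12)
            hi_o = brentq(lambda p: stats.binom.cdf(k, n, p) - 0.025, 1e-12, 1 - 1e-12)
            assert lo == pytest.approx(lo_o, abs=1e-9)
            assert hi == pytest.approx(hi_o, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestBandDiagnostics:
    def test_published_contingency(self):
        """Green 10/195 septic, Red 50/59 septic reproduces the published
        NPV ~95% and diagnostic odds ratio ~102.8."""
        ct = BandContingency(n_green=195, septic_green=10,
                             n_red=59, septic_red=50)
        d = band_diagnostics(ct)
        assert d["npv"] == pytest.approx(0.9487, abs=5e-4)
        assert d["green_septic_fraction"] == pytest.approx(0.051, abs=5e-3)
        assert d["diagnostic_odds_ratio"] == pytest.approx(102.8, abs=0.1)
        assert not d["dor_haldane_corrected"]

    def test_all_negative_green(self):
        ct = BandContingency(n_green=100, septic_green=0, n_red=20, septic_red=15)
        d = band_diagnostics(ct)
        assert d["npv"] == 1.0
        assert d["dor_haldane_corrected"]

    def test_identities(self):
        ct = BandContingency(n_green=80, septic_green=8, n_red=40, septic_red=30)
        d = band_diagnostics(ct)
        tp, fp, fn, tn = 30, 10, 8, 72
        assert d["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert d["specificity"] == pytest.approx(tn / (tn + fp))
        assert d["diagnostic_odds_ratio"] == pytest.approx((tp * tn) / (fp * fn))


class TestCohensD:
    def _with_moments(self, mean, sd, n, rng):
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        return mean + sd * z

    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_published_monocyte_effect(self, rng):
        """Printed monocyte VEIR means/SDs give d ~ 2.54."""
        x = self._with_moments(8.26, 0.79, 5000, rng)
        y = self._with_moments(10.41, 0.90, 5000, rng)
        assert cohens_d(x, y) == pytest.approx(2.539, abs=0.01)

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_degenerate(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))


class TestGroupTests:
    def test_identical_groups(self):
        t, p = group_tests(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]),
                           kind="welch_t")
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_welch_hand_computation(self):
        """Direct Satterthwaite formula as the independent oracle."""
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 6, 8])
        vx, vy = x.var(ddof=1) / 4, y.var(ddof=1) / 4
        t_manual = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 3 + vy**2 / 3)
        p_manual = 2 * stats.t.sf(abs(t_manual), df)
        t, p = group_tests(x, y, kind="welch_t")
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)

    def test_mann_whitney_and_anova_run(self, rng):
        x, y, z = (rng.normal(m, 1, 30) for m in (0, 0.5, 1.0))
        _, p_mw = group_tests(x, y, kind="mann_whitney")
        assert 0 <= p_mw <= 1
        _, p_an = group_tests(x, y, z, kind="anova")
        assert p_an < 0.05

    def test_empty_group(self):
        with pytest.raises(ValueError):
            group_tests(np.array([]), np.array([1.0]), kind="welch_t")


class TestHospitalFreeDays:
    def test_definition(self):
        assert hospital_free_days(4, False) == 24.0
        assert hospital_free_days(3, True) == 0.0
        assert hospital_free_days(30, False) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hospital_free_days(-1, False)


class TestKmLogrank:
    def test_identical_groups_zero_statistic(self):
        times = np.array([2.0, 5, 9, 30, 2, 5, 9, 30])
        events = np.array([1, 1, 1, 0, 1, 1, 1, 0])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = km_logrank(times, events, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_flat_curve(self):
        times = np.array([30.0] * 6)
        events = np.zeros(6, dtype=int)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="censored"):
            res = km_logrank(times, events, groups)
        assert res["statistic"] == 0.0
        for curve in res["curves"].values():
            assert (curve["survival"] == 1.0).all()

    def test_hand_computed_toy_table(self):
        """O-E table by hand: A deaths at 1 and 2; B death at 10, censor 30."""
        times = np.array([1.0, 2.0, 10.0, 30.0])
        events = np.array([1, 1, 1, 0])
        groups = np.array(["A", "A", "B", "B"])
        # t=1: E_A=0.5 V=0.25 ; t=2: E_A=1/3 V=2/9 ; t=10: E_A=0
        o_minus_e = 2 - (0.5 + 1 / 3)
        var = 0.25 + 2 / 9
        expected = o_minus_e**2 / var
        res = km_logrank(times, events, groups)
        assert res["statistic"] == pytest.approx(expected, abs=1e-9)


class TestBandTrends:
    def _subjects(self, rng, n=240):
        sev = np.sort(rng.normal(1.3, 1.0, n))
        band = np.array(["Green"] * (n // 2) + ["Yellow"] * (n // 4)
                        + ["Red"] * (n - n // 2 - n // 4))
        return pd.DataFrame({
            "band": band,
            "sofa_3day_max": np.round(np.clip(1 + 2 * sev + rng.normal(0, 1, n), 0, 24)),
            "apache2": np.round(10 + 3.5 * sev + rng.normal(0, 3, n)),
            "hospital_los": np.clip(np.round(np.exp(0.7 + 0.4 * sev)), 0, 60),
            "in_hospital_death": rng.random(n) < 0.05,
            "icu_admit": rng.random(n) < 1 / (1 + np.exp(-(sev - 2))),
        })

    def test_monotone_severity_across_bands(self, rng):
        rep = band_trend_report(self._subjects(rng))
        med = [rep["bands"][b]["sofa_3day_max"]["median"]
               for b in ("Green", "Yellow", "Red")]
        assert med[0] < med[1] < med[2]
        for b in rep["bands"]:
            lo, hi = rep["bands"][b]["icu_rate_ci"]
            assert lo <= rep["bands"][b]["icu_rate"] <= hi

    def test_single_band_rejected(self, rng):
        df = self._subjects(rng)
        df["band"] = "Green"
        with pytest.raises(ValueError, match="bands"):
            band_trend_report(df)
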