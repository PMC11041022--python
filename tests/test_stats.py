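"""Mixed model, t-tests, Cohen's d, vector-strength ANOVA."""

import numpy as np
import pandas as pd
import pytest

from lamcsd import (
    LmmSpec,
    cohens_d,
    default_family,
    fit_lmm,
    run_ttest_family,
    ttest_bonferroni,
    vs_anova,
)


def make_feature_frame(cell_means, n_trials=20, noise_sd=0.0, seed=0,
                       groups=("treated", "naive_control"),
                       measurements=("pre_laser", "post_laser")):
    """Balanced synthetic feature table with log-RMS cell means on demand.

    ``cell_means[(group, measurement)]`` is the mean of log RMS; per-animal
    and per-trial deviations are optional Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for a in range(2):
            animal = f"{g}_{a:02d}"
            for m in measurements:
                mu = cell_means[(g, m)]
                for tr in range(n_trials):
                    log_rms = mu + (noise_sd * rng.standard_normal() if noise_sd else 0.0)
                    rows.append({"group": g, "animal_id": animal, "measurement": m,
                                 "trial": tr, "rms": float(np.exp(log_rms))})
    return pd.DataFrame(rows)


class TestTtestBonferroni:
    def test_identical_samples_adjusted_p_one(self):
        res = ttest_bonferroni([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_adjusted == 1.0

    def test_cap_at_one(self):
        rng = np.random.default_rng(0)
        res = ttest_bonferroni(rng.normal(0, 1, 30), rng.normal(0, 1, 30), n_tests=14)
        assert res.p_adjusted == min(1.0, 14 * res.p_raw)
        assert res.p_adjusted <= 1.0

    def test_hand_computed_pooled_t(self):
        """{1,2,3} vs {4,5,6}: pooled variance 1, t = -3/sqrt(2/3) = -3.674,
        raw p ~= 0.0214 on 4 df."""
        res = ttest_bonferroni([1, 2, 3], [4, 5, 6], n_tests=1)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p_raw == pytest.approx(0.0214, abs=5e-4)

    def test_degenerate_zero_variance_flagged(self):
        res = ttest_bonferroni([2.0, 2.0], [2.0, 2.0])
        assert res.flagged and res.p_adjusted == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_bonferroni([1.0], [1.0, 2.0])


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_half(self):
        """{2,4,6} vs {1,3,5}: mean difference 1, pooled SD 2, d = 0.5."""
        assert cohens_d([2, 4, 6], [1, 3, 5]) == pytest.approx(0.5, abs=1e-12)

    def test_unit_difference_unit_sd(self, rng):
        a = rng.normal(1.0, 1.0, 20000)
        b = rng.normal(0.0, 1.0, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_antisymmetry_shift_and_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.5, 35)
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, abs=1e-12)
        assert cohens_d(a + 3.3, b + 3.3) == pytest.approx(d, abs=1e-12)
        assert cohens_d(2.0 * a, 2.0 * b) == pytest.approx(d, abs=1e-12)

    def test_zero_pooled_sd_flagged_nan(self):
        assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestFitLmm:
    def test_ols_limit_balanced_zero_random_variance(self):
        """With no animal or trial variance and a balanced design, the LMM
        fixed effects must match the saturated-cell-mean (OLS) solution."""
        cells = {("treated", "post_laser"): 0.0,
                 ("treated", "pre_laser"): 0.13,
                 ("naive_control", "post_laser"): 0.4,
                 ("naive_control", "pre_laser"): 0.45}
        df = make_feature_frame(cells, n_trials=10, noise_sd=1e-6, seed=1)
        tab = fit_lmm(df, LmmSpec())
        est = dict(zip(tab.term, tab.estimate))
        assert est["Intercept"] == pytest.approx(0.0, abs=1e-4)
        pre = [v for k, v in est.items() if "pre_laser" in k and ":" not in k]
        assert pre[0] == pytest.approx(0.13, abs=1e-4)
        grp = [v for k, v in est.items() if "naive_control" in k and ":" not in k]
        assert grp[0] == pytest.approx(0.4, abs=1e-4)
        inter = [v for k, v in est.items() if ":" in k]
        assert inter[0] == pytest.approx(0.45 - 0.4 - 0.13, abs=1e-4)

    def test_null_simulation_estimates_near_zero(self):
        """No injected effects: contrasts stay within 3 SE of zero in at
        least 95% of seeded replicates."""
        ok = 0
        reps = 40
        for seed in range(reps):
            cells = {(g, m): 0.0 for g in ("treated", "naive_control")
                     for m in ("pre_laser", "post_laser")}
            df = make_feature_frame(cells, n_trials=10, noise_sd=0.3, seed=seed)
            tab = fit_lmm(df, LmmSpec())
            sub = tab[tab.term != "Intercept"]
            if np.all(np.abs(sub.estimate) <= 3 * sub.se):
                ok += 1
        assert ok >= int(0.95 * reps) - 2  # binomial slack at 40 reps

    def test_multiplicative_gain_recovered_as_log_contrast(self):
        """A multiplicative post/pre gain of exp(-0.13) in the treated group
        appears as a +0.13 pre-vs-post(reference) fixed effect."""
        cells = {("treated", "post_laser"): -0.13,
                 ("treated", "pre_laser"): 0.0,
                 ("naive_control", "post_laser"): 0.0,
                 ("naive_control", "pre_laser"): 0.0}
        df = make_feature_frame(cells, n_trials=40, noise_sd=0.2, seed=7)
        tab = fit_lmm(df, LmmSpec())
        pre = tab[tab.term.str.contains("pre_laser", regex=False)
                  & ~tab.term.str.contains(":")].iloc[0]
        assert pre.estimate == pytest.approx(0.13, abs=3 * pre.se)

    def test_nonpositive_rms_dropped(self):
        cells = {(g, m): 0.0 for g in ("treated", "naive_control")
                 for m in ("pre_laser", "post_laser")}
        df = make_feature_frame(cells, n_trials=5, noise_sd=0.1, seed=3)
        df.loc[df.index[:4], "rms"] = 0.0
        tab = fit_lmm(df, LmmSpec())
        assert np.all(np.isfinite(tab.estimate))

    def test_unknown_reference_level_errors(self):
        cells = {(g, m): 0.0 for g in ("treated", "naive_control")
                 for m in ("pre_laser", "post_laser")}
        df = make_feature_frame(cells, n_trials=3, noise_sd=0.1)
        with pytest.raises(ValueError, match="reference group"):
            fit_lmm(df, LmmSpec(reference_group="cry2"))


class TestVsAnova:
    @staticmethod
    def balanced_2x2(values):
        rows = []
        for (g, m), vs in values.items():
            for i, v in enumerate(vs):
                rows.append({"group": g, "measurement": m, "animal_id": f"{g}{i}",
                             "vector_strength": v})
        return pd.DataFrame(rows)

    def test_no_effect_limit_small_sums_of_squares(self):
        rng = np.random.default_rng(0)
        eps = 1e-9
        values = {(g, m): 0.5 + eps * rng.standard_normal(4)
                  for g in ("a", "b") for m in ("pre", "post")}
        tab = vs_anova(self.balanced_2x2(values))
        between = tab[tab.factor != "Residual"]["sum_sq"]
        assert (between < 1e-15).all()

    def test_hand_computed_2x2_decomposition(self):
        """Balanced 2x2 with two observations per cell; sums of squares
        computed by hand from the cell means."""
        values = {("a", "pre"): [1.0, 3.0], ("a", "post"): [2.0, 4.0],
                  ("b", "pre"): [5.0, 7.0], ("b", "post"): [4.0, 6.0]}
        tab = vs_anova(self.balanced_2x2(values)).set_index("factor")
        # cell means: 2,3,6,5; grand 4; group means a=2.5,b=5.5; meas pre=4,post=4
        # SS_group = 8*(1.5^2) = 18; SS_meas = 0; SS_inter = sum 2*(cell-g-m+grand)^2
        # a,pre: 2-2.5-4+4 = -0.5 -> 0.25*2 ... all four cells 0.5^2*2 = 2.0
        assert tab.loc["C(group)", "sum_sq"] == pytest.approx(18.0, abs=1e-10)
        assert tab.loc["C(measurement)", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["C(group):C(measurement)", "sum_sq"] == pytest.approx(2.0, abs=1e-10)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(8.0, abs=1e-10)

    def test_power_group_effect_detected_measurement_null(self):
        """Injected group effect, no measurement effect: the group term is
        significant and the measurement term null in >= 90% of replicates."""
        rng = np.random.default_rng(5)
        group_sig = meas_sig = 0
        reps = 50
        for _ in range(reps):
            values = {}
            for g, shift in (("a", 0.0), ("b", 0.3)):
                for m in ("pre", "post"):
                    values[(g, m)] = shift + 0.05 * rng.standard_normal(6)
            tab = vs_anova(self.balanced_2x2(values)).set_index("factor")
            group_sig += tab.loc["C(group)", "p"] < 0.05
            meas_sig += tab.loc["C(measurement)", "p"] < 0.05
        assert group_sig >= int(0.9 * reps)
        assert meas_sig <= int(0.2 * reps)

    def test_empty_cell_errors(self):
        df = self.balanced_2x2({("a", "pre"): [0.1, 0.2], ("a", "post"): [0.3, 0.1],
                                ("b", "pre"): [0.2, 0.2]})
        with pytest.raises(ValueError, match="empty"):
            vs_anova(df)


class TestFamily:
    def test_default_family_has_14_members(self):
        assert len(default_family()) == 14

    def test_family_runs_on_feature_table(self):
        cells = {(g, m): 0.0
                 for g in ("treated", "naive_control", "viral_control")
                 for m in ("pre_laser", "post_laser")}
        df = make_feature_frame(cells, n_trials=6, noise_sd=0.2, seed=9,
                                groups=("treated", "naive_control", "viral_control"))
        df["trace"] = "AVREC"
        df["window"] = 0
        df2 = df.copy()
        df2["trace"] = "IV"
        df3 = df.copy()
        df3["trace"] = "V"
        table = pd.concat([df, df2, df3], ignore_index=True)
        out = run_ttest_family(table)
        assert len(out) == 14
        assert (out.p_adjusted >= out.p_raw - 1e-15).all()
        assert (out.p_adjusted <= 1.0).all()
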