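"""Statistical stages: treatment comparisons, set-point regression, ICC,
difference smoothing, ZIP EM and the surfacing-odds GLM, each checked
against an independent oracle (hand computation, brute-force grid, or a
closed form)."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuttlesim import ASRTrial
from shuttlesim.inference import (
    _icc_anova,
    asr_glm,
    compare_treatments,
    ramping_test_model,
    repeatability,
    smooth_difference,
    zip_compare,
    zip_fit,
    zip_loglik,
)


def summary_frame(rows):
    """rows: (fish_id, treatment, phase, value) -> minimal summary frame."""
    df = pd.DataFrame(rows, columns=["fish_id", "treatment", "phase", "mean_TB_C"])
    for col in ["side_pref", "shuttle_rate_per_min", "LET_C", "UET_C",
                "mean_log_vel", "asr_fraction", "terminated_s"]:
        df[col] = np.nan
    return df


class TestCompareTreatments:
    def test_difference_of_means_by_hand(self):
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate([1, 2, 3])]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate([4, 5, 6])]
        res = compare_treatments(summary_frame(rows), "mean_T_B", "test")
        assert res.estimate == pytest.approx(3.0)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_identical_groups_null(self):
        vals = [26.5, 27.0, 27.5, 28.0]
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate(vals)]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate(vals)]
        res = compare_treatments(summary_frame(rows), "mean_T_B", "test")
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.05

    def test_welch_matches_scipy_pvalue(self):
        from scipy import stats

        a = [25.1, 26.2, 27.3, 25.9]
        b = [21.0, 20.1, 22.4, 23.3, 19.9]
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate(a)]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate(b)]
        res = compare_treatments(summary_frame(rows), "mean_T_B", "test",
                                 welch=True)
        ref = stats.ttest_ind(b, a, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.estimate == pytest.approx(np.mean(b) - np.mean(a))

    def test_one_tailed_halves_p(self):
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate([1, 2, 3])]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate([2, 3, 4])]
        two = compare_treatments(summary_frame(rows), "mean_T_B", "test")
        one = compare_treatments(summary_frame(rows), "mean_T_B", "test",
                                 tails="one")
        assert one.p_value == pytest.approx(two.p_value / 2)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_log_transform_scale_equivariance(self, scale):
        """Scaling all values by c shifts only the intercept on the log
        scale: the treatment effect is unchanged."""
        rng = np.random.default_rng(12)
        a = rng.lognormal(0.0, 0.3, 6)
        b = rng.lognormal(0.5, 0.3, 6)
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate(a)]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate(b)]
        base = compare_treatments(summary_frame(rows), "mean_T_B", "test",
                                  transform="log")
        rows2 = [(f"c{i}", "control", "test", v * scale)
                 for i, v in enumerate(a)]
        rows2 += [(f"t{i}", "h2s", "test", v * scale)
                  for i, v in enumerate(b)]
        scaled = compare_treatments(summary_frame(rows2), "mean_T_B", "test",
                                    transform="log")
        assert scaled.estimate == pytest.approx(base.estimate, abs=1e-9)

    def test_log_transform_rejects_nonpositive(self):
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate([0.0, 1, 2])]
        rows += [(f"t{i}", "h2s", "test", v) for i, v in enumerate([1, 2, 3])]
        with pytest.raises(ValueError, match="control"):
            compare_treatments(summary_frame(rows), "mean_T_B", "test",
                               transform="log")

    def test_empty_group_named_in_error(self):
        rows = [(f"c{i}", "control", "test", v) for i, v in enumerate([1, 2, 3])]
        rows += [("t0", "h2s", "test", np.nan), ("t1", "h2s", "test", np.nan)]
        with pytest.raises(ValueError, match="h2s"):
            compare_treatments(summary_frame(rows), "mean_T_B", "test")


class TestRampingTestModel:
    @staticmethod
    def _frame(ramping, test, treatments):
        rows = []
        for i, (r, t, g) in enumerate(zip(ramping, test, treatments)):
            rows.append((f"f{i}", g, "ramping", r))
            rows.append((f"f{i}", g, "test", t))
        return summary_frame(rows)

    def test_identity_line(self):
        r = np.array([24.0, 25.5, 27.0, 28.5, 30.0])
        df = self._frame(r, r, ["control"] * 5)
        reg = ramping_test_model(df)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.set_point_shift_verdict is None

    def test_constructed_shift_recovered_exactly(self):
        rng = np.random.default_rng(5)
        r = rng.normal(27, 1.5, 12)
        g = ["control"] * 6 + ["h2s"] * 6
        t = np.where(np.array(g) == "h2s", r - 6.0, r)
        reg = ramping_test_model(self._frame(r, t, g))
        assert reg.slope == pytest.approx(1.0, abs=1e-9)
        assert reg.treatment_shift == pytest.approx(-6.0, abs=1e-9)
        assert reg.interaction == pytest.approx(0.0, abs=1e-9)
        assert reg.set_point_shift_verdict is True

    def test_missing_phase_mean_lists_fish(self):
        df = self._frame([25.0, 26.0], [25.0, np.nan], ["control"] * 2)
        with pytest.raises(ValueError, match="f1"):
            ramping_test_model(df)


class TestRepeatability:
    def test_anova_by_hand(self):
        # MSB = 8, MSW = 0.5 -> R = 7.5/8.5
        res = repeatability([(25, 26), (27, 28), (29, 30)], n_boot=0, n_perm=0)
        assert res.R == pytest.approx(7.5 / 8.5)

    def test_perfect_repeatability(self):
        res = repeatability([(25, 25), (27, 27), (29, 29), (31, 31), (26, 26)],
                            n_boot=0, n_perm=0)
        assert res.R == pytest.approx(1.0)

    def test_no_signal_truncates_to_zero(self):
        """With zero between-fish variance the raw ICC is centred on zero and
        negative draws truncate to exactly 0."""
        raw, truncated = [], []
        for seed in range(41):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, (50, 2))  # no fish effect at all
            res = repeatability(a, n_boot=0, n_perm=0)
            raw.append(res.R_raw)
            truncated.append(res.R)
        assert abs(float(np.median(raw))) < 0.15
        assert min(truncated) == 0.0  # negatives mapped to the boundary
        assert sum(t == 0.0 for t in truncated) >= 5

    def test_permutation_p_small_for_strong_signal(self):
        rng = np.random.default_rng(3)
        base = rng.normal(27, 2.0, 15)
        a = base[:, None] + rng.normal(0, 0.3, (15, 2))
        res = repeatability(a, n_boot=200, n_perm=400, seed=0)
        assert res.p_value < 0.01
        assert res.ci_low <= res.R <= res.ci_high
        assert 0 <= res.ci_low and res.ci_high <= 1

    def test_bootstrap_and_permutation_reproducible(self):
        rng = np.random.default_rng(4)
        a = rng.normal(27, 1.5, (10, 2))
        r1 = repeatability(a, n_boot=100, n_perm=100, seed=42)
        r2 = repeatability(a, n_boot=100, n_perm=100, seed=42)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (
            r2.ci_low, r2.ci_high, r2.p_value
        )

    @settings(max_examples=40, derandomize=True)
    @given(
        n=st.integers(3, 10),
        k=st.integers(2, 4),
        seed=st.integers(0, 1000),
    )
    def test_matches_bruteforce_variance_components(self, n, k, seed):
        """ICC agrees to 1e-10 with an explicit sums-of-squares oracle."""
        rng = np.random.default_rng(seed)
        a = rng.normal(27, 2, (n, 1)) + rng.normal(0, 1, (n, k))
        r_raw, _, _ = _icc_anova(a)
        # oracle: explicit loops
        grand = sum(a[i, j] for i in range(n) for j in range(k)) / (n * k)
        mi = [sum(a[i, j] for j in range(k)) / k for i in range(n)]
        ssb = k * sum((m - grand) ** 2 for m in mi)
        ssw = sum((a[i, j] - mi[i]) ** 2 for i in range(n) for j in range(k))
        msb = ssb / (n - 1)
        msw = ssw / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert r_raw == pytest.approx(expected, abs=1e-10)


class TestSmoothDifference:
    @staticmethod
    def _series(n_fish, t, curve, noise_sd, rho, rng):
        out = []
        for _ in range(n_fish):
            e = np.empty(len(t))
            e[0] = rng.normal(0, noise_sd / math.sqrt(1 - rho**2))
            for i in range(1, len(t)):
                e[i] = rho * e[i - 1] + rng.normal(0, noise_sd)
            out.append(curve + e)
        return np.vstack(out)

    def test_constant_offset_recovered(self):
        t = np.arange(0, 900, 15.0)
        curve = 27 + 1.5 * np.sin(t / 150)
        rng = np.random.default_rng(0)
        ctl = self._series(6, t, curve, 0.1, 0.95, rng)
        trt = self._series(6, t, curve - 6.0, 0.1, 0.95, rng)
        fit = smooth_difference(
            np.vstack([ctl, trt]), ["control"] * 6 + ["h2s"] * 6, t
        )
        assert np.max(np.abs(fit.difference + 6.0)) < 0.5
        assert np.all(fit.band_low <= fit.difference)
        assert np.all(fit.difference <= fit.band_high)

    def test_null_band_covers_zero(self):
        """Same generating curve for both groups: pointwise 95% band contains
        zero at >= 90% of grid points (median over 10 seeds)."""
        t = np.arange(0, 600, 15.0)
        curve = 27 + np.cos(t / 120)
        coverage = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ctl = self._series(5, t, curve, 0.15, 0.9, rng)
            trt = self._series(5, t, curve, 0.15, 0.9, rng)
            fit = smooth_difference(
                np.vstack([ctl, trt]), ["control"] * 5 + ["h2s"] * 5, t,
                rho=0.9,
            )
            coverage.append(
                np.mean((fit.band_low <= 0) & (0 <= fit.band_high))
            )
        assert float(np.median(coverage)) >= 0.9

    def test_rho_zero_is_identity_filter(self):
        from shuttlesim.inference import _prewhiten

        y = np.random.default_rng(1).normal(size=50)
        np.testing.assert_allclose(_prewhiten(y, 0.0), y)

    def test_degenerate_constant_input(self):
        t = np.arange(0, 300, 10.0)
        tb = np.full((6, len(t)), 27.0)
        fit = smooth_difference(tb, ["control"] * 3 + ["h2s"] * 3, t)
        np.testing.assert_allclose(fit.difference, 0.0, atol=1e-6)
        np.testing.assert_allclose(fit.curve_reference, 27.0, atol=1e-6)

    def test_small_basis_rejected(self):
        t = np.arange(0, 100, 10.0)
        tb = np.zeros((4, len(t)))
        with pytest.raises(ValueError):
            smooth_difference(tb, ["control"] * 2 + ["h2s"] * 2, t,
                              basis_dim=3)


class TestZip:
    def test_em_monotone_loglikelihood(self):
        rng = np.random.default_rng(0)
        y = np.where(rng.random(400) < 0.4, 0, rng.poisson(3, 400))
        fit = zip_fit(y)
        assert np.all(np.diff(fit.loglik_path) >= -1e-9)
        assert fit.converged

    def test_pure_poisson_recovery(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(2.0, 1000)
        fit = zip_fit(y)
        assert fit.pi < 0.05
        assert fit.lam == pytest.approx(2.0, abs=0.15)

    def test_mixture_recovery(self):
        rng = np.random.default_rng(2)
        y = np.where(rng.random(1000) < 0.5, 0, rng.poisson(4.0, 1000))
        fit = zip_fit(y)
        assert fit.pi == pytest.approx(0.5, abs=0.05)
        assert fit.lam == pytest.approx(4.0, abs=0.3)
        assert fit.pi_ci[0] <= fit.pi <= fit.pi_ci[1]
        assert fit.lam_ci[0] <= fit.lam <= fit.lam_ci[1]

    def test_zip_beats_poisson_on_inflated_counts(self):
        y = np.array([0, 0, 0, 0, 3, 3])
        fit = zip_fit(y)
        # plain-Poisson profile: best lambda is the sample mean
        ll_pois = zip_loglik(y, 0.0, float(np.mean(y)))
        assert fit.loglik > ll_pois

    def test_matches_grid_search_oracle(self):
        y = np.array([0] * 12 + [1, 1, 2, 2, 2, 3, 3, 4, 5, 1, 2, 0, 0, 6])
        fit = zip_fit(y)
        pis = np.linspace(0.001, 0.999, 200)
        lams = np.linspace(0.05, 10.0, 200)
        grid = np.array([[zip_loglik(y, p, l) for l in lams] for p in pis])
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        assert fit.pi == pytest.approx(pis[i], abs=(pis[1] - pis[0]) * 1.5)
        assert fit.lam == pytest.approx(lams[j], abs=(lams[1] - lams[0]) * 1.5)
        assert fit.loglik >= grid[i, j] - 1e-9

    def test_matches_statsmodels_mle(self):
        """Independent cross-check: statsmodels' ZeroInflatedPoisson MLE on
        the same counts."""
        import statsmodels.api as sm
        from scipy.special import expit

        rng = np.random.default_rng(7)
        y = np.where(rng.random(500) < 0.3, 0, rng.poisson(2.5, 500))
        fit = zip_fit(y)
        smf = sm.ZeroInflatedPoisson(y, np.ones((len(y), 1))).fit(disp=0)
        assert fit.pi == pytest.approx(float(expit(smf.params[0])), abs=1e-4)
        assert fit.lam == pytest.approx(float(np.exp(smf.params[1])), abs=1e-4)

    def test_all_zero_flagged(self):
        fit = zip_fit([0, 0, 0, 0])
        assert fit.pi == 1.0
        assert "lambda_unidentifiable" in fit.flags

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            zip_fit([1.5, 2.0])
        with pytest.raises(ValueError):
            zip_fit([-1, 2])

    def test_group_comparison_detects_difference(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(2.0, 300)
        b = np.where(rng.random(300) < 0.5, 0, rng.poisson(2.0, 300))
        res = zip_compare({"control": a, "h2s": b})
        assert res.df == 2
        assert res.p_value < 0.001
        null = zip_compare({"g1": a[:150], "g2": a[150:]})
        assert null.p_value > 0.01


class TestAsrGlm:
    def test_closed_form_odds_ratio_2x2(self):
        trials = [
            ASRTrial("a", 0.02, 21.0, 100, 20),
            ASRTrial("b", 0.0, 21.0, 100, 2),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saturated fit warnings
            res = asr_glm(trials, include_temp=False,
                          include_interaction=False)
        assert float(res.odds_ratios[1]) == pytest.approx(
            (20 / 80) / (2 / 98), abs=1e-6
        )

    @settings(max_examples=25, derandomize=True)
    @given(
        s=st.tuples(*(st.integers(5, 95) for _ in range(4))),
        seed=st.integers(0, 100),
    )
    def test_saturated_design_reproduces_log_odds(self, s, seed):
        """On a saturated 2x2 design the GLM coefficients equal the closed
        form log odds ratios to optimizer tolerance."""
        n = 100
        cells = [(0.0, 21.0), (0.0, 28.0), (0.02, 21.0), (0.02, 28.0)]
        trials = [
            ASRTrial(f"f{i}", h, t, n, si)
            for i, ((h, t), si) in enumerate(zip(cells, s))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = asr_glm(trials)
        p = [si / n for si in s]
        logit = lambda q: math.log(q / (1 - q))  # noqa: E731
        assert res.coefficient("intercept") == pytest.approx(
            logit(p[0]), abs=1e-8
        )
        assert res.coefficient("h2s") == pytest.approx(
            logit(p[2]) - logit(p[0]), abs=1e-8
        )
        assert res.coefficient("temp") == pytest.approx(
            logit(p[1]) - logit(p[0]), abs=1e-8
        )
        assert res.coefficient("h2s:temp") == pytest.approx(
            logit(p[3]) - logit(p[2]) - logit(p[1]) + logit(p[0]), abs=1e-8
        )

    def test_equal_proportions_null(self):
        trials = [
            ASRTrial(f"f{i}", h, t, 1000, 100)
            for i, (h, t) in enumerate(
                [(0.0, 21.0), (0.0, 28.0), (0.02, 21.0), (0.02, 28.0)] * 2
            )
        ]
        res = asr_glm(trials)
        for term in ("h2s", "temp", "h2s:temp"):
            assert res.coefficient(term) == pytest.approx(0.0, abs=1e-8)

    def test_separation_triggers_ridge_fallback(self):
        trials = [
            ASRTrial("a", 0.0, 21.0, 100, 0),   # empty cell: separation
            ASRTrial("b", 0.0, 28.0, 100, 10),
            ASRTrial("c", 0.02, 21.0, 100, 20),
            ASRTrial("d", 0.02, 28.0, 100, 60),
        ]
        with pytest.warns(UserWarning, match="separation"):
            res = asr_glm(trials)
        assert "ridge" in res.flags
        assert np.all(np.isfinite(res.coef))

    def test_rank_deficient_design_rejected(self):
        trials = [
            ASRTrial("a", 0.02, 21.0, 100, 20),
            ASRTrial("b", 0.0, 21.0, 100, 2),
        ]
        with pytest.raises(ValueError, match="rank"):
            asr_glm(trials)
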