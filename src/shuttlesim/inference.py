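"""Statistical analyses for shuttlebox experiments.

Treatment comparisons by linear model or Welch t-test, the ramping-vs-test
set-point regression, ANOVA-based repeatability (intraclass correlation) with
parametric-bootstrap intervals and permutation p-values, penalized-spline
difference smoothing of AR(1)-autocorrelated body-temperature time courses,
zero-inflated Poisson (ZIP) shuttle-count models fitted by EM, and the
binomial logistic model of aquatic surface respiration odds.

Standard linear/GLM fits go through statsmodels; the ICC machinery, the ZIP
EM and the penalized smoother are implemented here because their interval
constructions (parametric bootstrap, permutation, observed-information Wald
on transformed scales, GCV-penalized GLS) are the quantities under test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline
from scipy.special import gammaln

from .metrics import BehaviourSummary, summaries_to_frame

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "RepeatabilityResult",
    "SmoothDiffFit",
    "ZIPFit",
    "ZIPComparison",
    "AsrGlmResult",
    "compare_treatments",
    "ramping_test_model",
    "repeatability",
    "smooth_difference",
    "zip_loglik",
    "zip_fit",
    "zip_compare",
    "asr_glm",
]

#: Water temperature separating the assay's cool (21 °C) and warm (28 °C)
#: levels when coding the ASR design matrix.
WARM_SPLIT_C = 24.5

_METRIC_COLUMNS = {
    "mean_T_B": "mean_TB_C",
    "side_preference": "side_pref",
    "shuttle_rate": "shuttle_rate_per_min",
    "LET": "LET_C",
    "UET": "UET_C",
    "mean_log_velocity": "mean_log_vel",
    "asr_fraction": "asr_fraction",
}


def _as_summary_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    if summaries and isinstance(summaries[0], BehaviourSummary):
        return summaries_to_frame(list(summaries))
    raise TypeError("summaries must be a DataFrame or list of BehaviourSummary")


def _reference_level(labels) -> str:
    levels = sorted(set(labels))
    return "control" if "control" in levels else levels[0]


# ---------------------------------------------------------------------------
# Treatment comparisons
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Treatment effect on one metric: estimate, 95% CI and p-value.

    ``estimate`` is treated minus reference, in the metric's units (log units
    when ``transform="log"``).
    """

    metric: str
    phase: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    tails: str
    transform: str
    n_reference: int
    n_treated: int
    reference: str
    treated: str


def compare_treatments(
    summaries,
    metric: str,
    phase: str,
    tails: str = "two",
    transform: str = "identity",
    welch: bool = False,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare a behavioural metric between treatments within one phase.

    Fits ``metric ~ treatment`` by OLS (equivalently a pooled-variance
    two-sample t-test); ``welch=True`` switches to the unequal-variance Welch
    t-test, the form used for one-tailed pilot contrasts.  ``transform="log"``
    log-transforms the metric first (shuttle rates and velocities are analysed
    on the log scale).  One-tailed p-values test in the direction of the
    observed effect.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if transform not in ("identity", "log"):
        raise ValueError("transform must be 'identity' or 'log'")
    df = _as_summary_frame(summaries)
    col = _METRIC_COLUMNS.get(metric, metric)
    if col not in df.columns:
        raise ValueError(f"unknown metric {metric!r}")
    sub = df[df["phase"] == phase]
    levels = sorted(sub["treatment"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 treatment groups, found {levels}")
    ref = _reference_level(levels)
    trt = next(l for l in levels if l != ref)
    groups = {}
    for name in (ref, trt):
        vals = sub.loc[sub["treatment"] == name, col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has fewer than 2 defined values for "
                f"{metric!r} in phase {phase!r}"
            )
        if transform == "log":
            if np.any(vals <= 0):
                raise ValueError(
                    f"log transform requires positive values (group {name!r})"
                )
            vals = np.log(vals)
        groups[name] = vals
    y0, y1 = groups[ref], groups[trt]
    if welch:
        res = stats.ttest_ind(y1, y0, equal_var=False)
        est = float(np.mean(y1) - np.mean(y0))
        ci = res.confidence_interval(confidence_level=1 - alpha)
        lo, hi = float(ci.low), float(ci.high)
        p = float(res.pvalue)
    else:
        y = np.concatenate([y0, y1])
        g = np.concatenate([np.zeros(len(y0)), np.ones(len(y1))])
        X = sm.add_constant(g)
        fit = sm.OLS(y, X).fit()
        est = float(fit.params[1])
        lo, hi = (float(v) for v in fit.conf_int(alpha)[1])
        p = float(fit.pvalues[1])
    if tails == "one":
        p = p / 2.0
    return ComparisonResult(
        metric=metric,
        phase=phase,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        tails=tails,
        transform=transform,
        n_reference=len(y0),
        n_treated=len(y1),
        reference=ref,
        treated=trt,
    )


# ---------------------------------------------------------------------------
# Ramping-vs-test set-point regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Fit of test-phase on ramping-phase per-fish means.

    A pure set-point shift predicts a common slope (near one) with an
    intercept offset for the treated group and no slope-by-treatment
    interaction; a distress/escape response would instead produce an
    interaction.  ``set_point_shift_verdict`` is True when the intercept
    shift is significant and the interaction is not (α = 0.05); None for
    single-group fits.
    """

    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    intercept: float
    treatment_shift: float
    shift_ci: tuple[float, float]
    shift_p: float
    interaction: float
    interaction_ci: tuple[float, float]
    interaction_p: float
    set_point_shift_verdict: bool | None
    n: int
    reference: str | None


def ramping_test_model(
    summaries, metric: str = "mean_T_B", alpha: float = 0.05
) -> RegressionResult:
    """Regress per-fish test-phase means on ramping-phase means.

    With two treatment groups fits ``test ~ ramping * treatment``; with a
    single group fits the plain ``test ~ ramping`` line (slope only).
    """
    df = _as_summary_frame(summaries)
    col = _METRIC_COLUMNS.get(metric, metric)
    wide = df.pivot_table(index="fish_id", columns="phase", values=col,
                          aggfunc="first")
    treat = df.groupby("fish_id")["treatment"].first()
    for need in ("ramping", "test"):
        if need not in wide.columns:
            raise ValueError(f"missing {need!r} phase means")
    bad = wide.index[wide[["ramping", "test"]].isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"fish missing ramping/test means: {bad}")
    r = wide["ramping"].to_numpy(dtype=float)
    te = wide["test"].to_numpy(dtype=float)
    labels = treat.loc[wide.index]
    levels = sorted(labels.unique())
    nan_ci = (math.nan, math.nan)
    if len(levels) == 1:
        X = sm.add_constant(r)
        fit = sm.OLS(te, X).fit()
        ci = fit.conf_int(alpha)
        return RegressionResult(
            slope=float(fit.params[1]),
            slope_ci=(float(ci[1][0]), float(ci[1][1])),
            slope_p=float(fit.pvalues[1]),
            intercept=float(fit.params[0]),
            treatment_shift=math.nan,
            shift_ci=nan_ci,
            shift_p=math.nan,
            interaction=math.nan,
            interaction_ci=nan_ci,
            interaction_p=math.nan,
            set_point_shift_verdict=None,
            n=len(r),
            reference=None,
        )
    if len(levels) != 2:
        raise ValueError(f"expected at most 2 treatment groups, found {levels}")
    ref = _reference_level(levels)
    z = (labels != ref).to_numpy(dtype=float)
    # Interaction tested in the full model; slope and intercept shift taken
    # from the additive model so the shift is not the meaningless
    # extrapolation to a ramping mean of 0 °C.
    X_full = np.column_stack([np.ones_like(r), r, z, r * z])
    full = sm.OLS(te, X_full).fit()
    ci_full = full.conf_int(alpha)
    X_add = np.column_stack([np.ones_like(r), r, z])
    add = sm.OLS(te, X_add).fit()
    ci_add = add.conf_int(alpha)
    verdict = bool(add.pvalues[2] < alpha and full.pvalues[3] >= alpha)
    return RegressionResult(
        slope=float(add.params[1]),
        slope_ci=(float(ci_add[1][0]), float(ci_add[1][1])),
        slope_p=float(add.pvalues[1]),
        intercept=float(add.params[0]),
        treatment_shift=float(add.params[2]),
        shift_ci=(float(ci_add[2][0]), float(ci_add[2][1])),
        shift_p=float(add.pvalues[2]),
        interaction=float(full.params[3]),
        interaction_ci=(float(ci_full[3][0]), float(ci_full[3][1])),
        interaction_p=float(full.pvalues[3]),
        set_point_shift_verdict=verdict,
        n=len(r),
        reference=ref,
    )


# ---------------------------------------------------------------------------
# Repeatability (intraclass correlation)
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    """One-way random-effects ICC with bootstrap CI and permutation p.

    ``R`` is the truncated-at-zero estimate, ``R_raw`` the untruncated ANOVA
    value.  The CI comes from a parametric bootstrap of the fitted variance
    components; the p-value from permuting measurements across individuals.
    """

    R: float
    R_raw: float
    ci_low: float
    ci_high: float
    p_value: float
    sigma2_between: float
    sigma2_within: float
    n_individuals: int
    n_measurements: int
    n_boot: int
    n_perm: int


def _icc_anova(a: np.ndarray) -> tuple[float, float, float]:
    """Raw one-way ANOVA ICC and its (MSB, MSW) from an (n, k) array."""
    n, k = a.shape
    fish_means = a.mean(axis=1)
    grand = a.mean()
    ssb = k * np.sum((fish_means - grand) ** 2)
    ssw = np.sum((a - fish_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    r_raw = (msb - msw) / denom if denom > 0 else math.nan
    return r_raw, msb, msw


def repeatability(
    values,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed=None,
) -> RepeatabilityResult:
    """Repeatability of per-fish measurements across phases.

    ``values`` is an (n_individuals, k) array (k ≥ 2 balanced measurements
    per individual, typically the ramping- and test-phase means).  The ICC is
    the one-way random-effects estimator
    ``R = (MSB - MSW) / (MSB + (k-1) MSW)``, truncated at zero.
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("values must be (n_individuals, k>=2)")
    if not np.all(np.isfinite(a)):
        raise ValueError("all measurements must be finite")
    n, k = a.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    r_raw, msb, msw = _icc_anova(a)
    r = max(r_raw, 0.0) if math.isfinite(r_raw) else math.nan
    sigma2_b = max((msb - msw) / k, 0.0)
    sigma2_w = msw

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        seed if seed is not None else 0
    )
    boot_rng, perm_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    if n_boot > 0 and math.isfinite(r):
        effects = boot_rng.normal(0.0, math.sqrt(sigma2_b), (n_boot, n, 1))
        noise = boot_rng.normal(0.0, math.sqrt(sigma2_w), (n_boot, n, k))
        sims = effects + noise
        r_boot = np.empty(n_boot)
        for b in range(n_boot):
            rb, _, _ = _icc_anova(sims[b])
            r_boot[b] = max(rb, 0.0) if math.isfinite(rb) else 0.0
        lo, hi = np.percentile(r_boot, [2.5, 97.5])
        lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    else:
        lo = hi = math.nan

    if n_perm > 0 and math.isfinite(r_raw):
        flat = a.ravel()
        exceed = 0
        for _ in range(n_perm):
            perm = perm_rng.permutation(flat).reshape(n, k)
            rp, _, _ = _icc_anova(perm)
            if math.isfinite(rp) and rp >= r_raw:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
    else:
        p = math.nan

    return RepeatabilityResult(
        R=r,
        R_raw=r_raw,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        sigma2_between=sigma2_b,
        sigma2_within=sigma2_w,
        n_individuals=n,
        n_measurements=k,
        n_boot=n_boot,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Penalized-spline difference smoothing with AR(1) prewhitening
# ---------------------------------------------------------------------------


@dataclass
class SmoothDiffFit:
    """Reference and treatment body-temperature curves over time.

    ``difference`` is the treated-minus-reference curve with a pointwise 95%
    Wald band; ``rho`` is the AR(1) coefficient used for prewhitening and
    ``lam`` the GCV-selected smoothing penalty.
    """

    times: np.ndarray
    curve_reference: np.ndarray
    curve_treated: np.ndarray
    difference: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    rho: float
    lam: float
    edf: float
    gcv: float


def _prewhiten(y: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening transform of a series (identity at rho=0)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    out[0] = math.sqrt(max(1.0 - rho * rho, 0.0)) * y[0]
    out[1:] = y[1:] - rho * y[:-1]
    return out


def _bspline_basis(times: np.ndarray, basis_dim: int) -> np.ndarray:
    """Cubic B-spline design matrix with uniformly spaced interior knots."""
    k = 3
    t0, t1 = float(times[0]), float(times[-1])
    n_interior = basis_dim - (k + 1)
    interior = np.linspace(t0, t1, n_interior + 2)[1:-1]
    knots = np.concatenate([[t0] * (k + 1), interior, [t1] * (k + 1)])
    x = np.clip(times, t0, t1 - 1e-12 * max(abs(t1), 1.0))
    return BSpline.design_matrix(x, knots, k).toarray()


def smooth_difference(
    tb: np.ndarray,
    treatments,
    times: np.ndarray,
    rho: float = 0.95,
    basis_dim: int = 20,
    lambdas: np.ndarray | None = None,
) -> SmoothDiffFit:
    """Smooth treatment difference in the body-temperature time course.

    ``tb`` is an (n_fish, n_time) array of body-temperature series on a
    common time grid with per-fish treatment ``treatments`` labels.  Each
    series is AR(1)-prewhitened with coefficient ``rho`` (the same transform
    applied to the design), then a reference curve plus a treated-difference
    curve, both penalized cubic B-splines with second-difference penalties,
    are fitted by penalized least squares with the penalty chosen by
    generalized cross-validation (GCV).
    """
    tb = np.asarray(tb, dtype=float)
    times = np.asarray(times, dtype=float)
    if basis_dim < 4:
        raise ValueError("basis_dim must be >= 4 for a cubic basis")
    if tb.ndim != 2 or tb.shape[1] != len(times):
        raise ValueError("tb must be (n_fish, n_time) matching times")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    labels = np.asarray(treatments)
    if len(labels) != tb.shape[0]:
        raise ValueError("one treatment label per fish required")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 treatment groups, found {levels}")
    ref = _reference_level(levels)
    treated_mask = labels != ref
    if treated_mask.sum() < 2 or (~treated_mask).sum() < 2:
        raise ValueError("need at least 2 fish per treatment")

    K = basis_dim
    B = _bspline_basis(times, K)
    Bw = np.empty_like(B)
    Bw[0] = math.sqrt(max(1.0 - rho * rho, 0.0)) * B[0]
    Bw[1:] = B[1:] - rho * B[:-1]

    G = Bw.T @ Bw
    n_all = tb.shape[0]
    n_trt = int(treated_mask.sum())
    yw = np.apply_along_axis(_prewhiten, 1, tb, rho)
    s_all = yw.sum(axis=0)
    s_trt = yw[treated_mask].sum(axis=0)
    XtX = np.block([[n_all * G, n_trt * G], [n_trt * G, n_trt * G]])
    Xty = np.concatenate([Bw.T @ s_all, Bw.T @ s_trt])
    yty = float(np.sum(yw * yw))
    n_obs = yw.size

    D = np.diff(np.eye(K), n=2, axis=0)
    P1 = D.T @ D
    Pen = np.zeros((2 * K, 2 * K))
    Pen[:K, :K] = P1
    Pen[K:, K:] = P1

    if lambdas is None:
        lambdas = np.logspace(-3, 8, 34)
    best = None
    for lam in lambdas:
        A = XtX + lam * Pen
        try:
            beta = np.linalg.solve(A, Xty)
            edf = float(np.trace(np.linalg.solve(A, XtX)))
        except np.linalg.LinAlgError:
            continue
        rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
        denom = max(n_obs - edf, 1.0)
        gcv = n_obs * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf, rss)
    if best is None:
        raise np.linalg.LinAlgError("penalized system singular for all lambdas")
    gcv, lam, beta, edf, rss = best
    A = XtX + lam * Pen
    sigma2 = rss / max(n_obs - edf, 1.0)
    Ainv = np.linalg.inv(A)
    cov = sigma2 * (Ainv @ XtX @ Ainv)
    b_ref, b_diff = beta[:K], beta[K:]
    cov_dd = cov[K:, K:]
    curve_ref = B @ b_ref
    diff = B @ b_diff
    var_d = np.einsum("ij,jk,ik->i", B, cov_dd, B)
    sd = np.sqrt(np.maximum(var_d, 0.0))
    z = stats.norm.ppf(0.975)
    return SmoothDiffFit(
        times=times,
        curve_reference=curve_ref,
        curve_treated=curve_ref + diff,
        difference=diff,
        band_low=diff - z * sd,
        band_high=diff + z * sd,
        rho=rho,
        lam=float(lam),
        edf=edf,
        gcv=float(gcv),
    )


# ---------------------------------------------------------------------------
# Zero-inflated Poisson shuttle-count model
# ---------------------------------------------------------------------------


@dataclass
class ZIPFit:
    """Zero-inflated Poisson fit: structural-zero probability and Poisson mean.

    ``loglik_path`` records the EM log-likelihood trajectory (monotone
    non-decreasing).  Boundary estimates (π at 0 or 1) are flagged and carry
    NaN intervals rather than fabricated ones.
    """

    lam: float
    pi: float
    lam_ci: tuple[float, float]
    pi_ci: tuple[float, float]
    loglik: float
    n: int
    n_iter: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    loglik_path: np.ndarray | None = None


@dataclass
class ZIPComparison:
    """Likelihood-ratio comparison of shared vs per-group ZIP parameters."""

    fits: dict
    pooled: ZIPFit
    lr_stat: float
    df: int
    p_value: float


def zip_loglik(counts: np.ndarray, pi: float, lam: float) -> float:
    """Log-likelihood of counts under ZIP(π, λ).

    ``P(0) = π + (1-π) e^{-λ}``; positive counts are Poisson scaled by
    ``1-π``.  π = 0 gives the plain Poisson likelihood.
    """
    y = np.asarray(counts)
    if not 0.0 <= pi < 1.0 or lam <= 0:
        return -math.inf
    n0 = int(np.sum(y == 0))
    pos = y[y > 0]
    ll = 0.0
    if n0:
        ll += n0 * math.log(pi + (1.0 - pi) * math.exp(-lam))
    if len(pos):
        ll += float(
            np.sum(
                math.log(1.0 - pi)
                - lam
                + pos * math.log(lam)
                - gammaln(pos + 1.0)
            )
        )
    return ll


def zip_fit(
    counts,
    tol: float = 1e-10,
    max_iter: int = 2000,
    keep_path: bool = True,
) -> ZIPFit:
    """Maximum-likelihood ZIP fit via EM over latent structural-zero labels.

    E-step: each observed zero is a structural zero with posterior weight
    ``π / (π + (1-π) e^{-λ})``.  M-step: π is the mean structural-zero weight,
    λ the Poisson mean over the non-structural mass.  Standard errors come
    from the observed information (numerical Hessian on the (logit π, log λ)
    scale), mapped back to Wald 95% intervals.
    """
    y = np.asarray(counts)
    if y.size < 2:
        raise ValueError("need at least 2 count bins")
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    y = y.astype(np.int64)
    n = y.size
    n0 = int(np.sum(y == 0))
    nan_ci = (math.nan, math.nan)
    if n0 == n:
        return ZIPFit(
            lam=math.nan,
            pi=1.0,
            lam_ci=nan_ci,
            pi_ci=nan_ci,
            loglik=0.0,
            n=n,
            n_iter=0,
            converged=True,
            flags=["all_zero", "lambda_unidentifiable", "pi_boundary"],
        )
    total = float(y.sum())
    pi = min(max(0.5 * n0 / n, 1e-6), 1 - 1e-6)
    lam = max(total / n, 1e-8)
    path = [zip_loglik(y, pi, lam)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p0 = pi + (1.0 - pi) * math.exp(-lam)
        w = pi / p0 if p0 > 0 else 1.0  # posterior structural-zero weight
        sum_w = n0 * w
        pi = sum_w / n
        denom = n - sum_w
        lam = total / denom if denom > 0 else math.nan
        ll = zip_loglik(y, pi, lam)
        path.append(ll)
        if abs(path[-1] - path[-2]) < tol:
            converged = True
            break
    flags: list[str] = []
    if pi < 1e-8:
        flags.append("pi_boundary")
    lam_ci, pi_ci = nan_ci, nan_ci
    if math.isfinite(lam) and lam > 0 and 1e-8 < pi < 1 - 1e-8:
        theta = np.array([math.log(pi / (1 - pi)), math.log(lam)])

        def nll(th):
            p = 1.0 / (1.0 + math.exp(-th[0]))
            return -zip_loglik(y, p, math.exp(th[1]))

        h = 1e-5
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                H[i, j] = (
                    nll(theta + ei + ej)
                    - nll(theta + ei - ej)
                    - nll(theta - ei + ej)
                    + nll(theta - ei - ej)
                ) / (4 * h * h)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            z = stats.norm.ppf(0.975)
            lo_p = 1.0 / (1.0 + math.exp(-(theta[0] - z * se[0])))
            hi_p = 1.0 / (1.0 + math.exp(-(theta[0] + z * se[0])))
            pi_ci = (lo_p, hi_p)
            lam_ci = (
                math.exp(theta[1] - z * se[1]),
                math.exp(theta[1] + z * se[1]),
            )
        except np.linalg.LinAlgError:
            flags.append("information_singular")
    elif "pi_boundary" in flags:
        # π at the boundary: Wald machinery undefined for π, λ interval from
        # the plain Poisson information.
        se_log_lam = 1.0 / math.sqrt(total) if total > 0 else math.nan
        z = stats.norm.ppf(0.975)
        lam_ci = (
            lam * math.exp(-z * se_log_lam),
            lam * math.exp(z * se_log_lam),
        )
    return ZIPFit(
        lam=float(lam),
        pi=float(pi),
        lam_ci=lam_ci,
        pi_ci=pi_ci,
        loglik=float(path[-1]),
        n=n,
        n_iter=it,
        converged=converged,
        flags=flags,
        loglik_path=np.asarray(path) if keep_path else None,
    )


def zip_compare(counts_by_group: dict) -> ZIPComparison:
    """Likelihood-ratio test of shared vs per-group (π, λ).

    The null model fits one ZIP to the pooled counts; the alternative fits
    each group separately.  2·Δloglik ~ χ² with 2·(g-1) degrees of freedom.
    """
    if len(counts_by_group) < 2:
        raise ValueError("need at least 2 groups")
    fits = {k: zip_fit(v, keep_path=False) for k, v in counts_by_group.items()}
    pooled = zip_fit(np.concatenate([np.asarray(v) for v in counts_by_group.values()]),
                     keep_path=False)
    ll_sep = sum(f.loglik for f in fits.values())
    lr = 2.0 * (ll_sep - pooled.loglik)
    dof = 2 * (len(fits) - 1)
    p = float(stats.chi2.sf(max(lr, 0.0), dof))
    return ZIPComparison(fits=fits, pooled=pooled, lr_stat=float(lr), df=dof,
                         p_value=p)


# ---------------------------------------------------------------------------
# Binomial GLM of aquatic surface respiration
# ---------------------------------------------------------------------------


@dataclass
class AsrGlmResult:
    """Logistic model of surfacing odds in the 2x2 H2S x temperature design.

    Coefficients on the log-odds scale with Wald 95% intervals; odds ratios
    are their exponentials.  Reference cell: 0% H2S at the cool temperature.
    """

    terms: list[str]
    coef: np.ndarray
    ci: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def or_ci(self) -> np.ndarray:
        return np.exp(self.ci)

    def coefficient(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
                "se": self.se,
                "p": self.p_values,
                "odds_ratio": self.odds_ratios,
            }
        )


def _ridge_logistic(X, succ, fail, ridge: float, max_iter: int = 100):
    """Newton fit of a binomial GLM with a small L2 penalty (separation
    fallback); returns (beta, cov)."""
    n_tot = succ + fail
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        wvec = n_tot * p * (1 - p)
        grad = X.T @ (succ - n_tot * p) - ridge * beta
        H = X.T @ (X * wvec[:, None]) + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    wvec = n_tot * p * (1 - p)
    H = X.T @ (X * wvec[:, None]) + ridge * np.eye(X.shape[1])
    return beta, np.linalg.inv(H)


def asr_glm(
    trials,
    include_temp: bool = True,
    include_interaction: bool = True,
    alpha: float = 0.05,
    ridge: float = 1e-4,
) -> AsrGlmResult:
    """Binomial logistic regression of surfacing-frame counts.

    Models ``logit P(surface) = β0 + β_h2s·1[H2S] + β_temp·1[warm] +
    β_int·1[both]`` (treatment coding; reference is 0% H2S at the cool
    temperature) by maximum likelihood with Wald 95% intervals.  A design cell
    with all or no frames at the surface (separation) triggers a warning and
    a lightly ridge-penalized fit.
    """
    from .params import ASRTrial, asr_trials_to_frame

    if isinstance(trials, pd.DataFrame):
        df = trials
    elif trials and isinstance(trials[0], ASRTrial):
        df = asr_trials_to_frame(list(trials))
    else:
        raise TypeError("trials must be a DataFrame or list of ASRTrial")
    if df.empty:
        raise ValueError("no ASR trials provided")
    h = (df["h2s_pct"].to_numpy(dtype=float) > 0).astype(float)
    w = (df["temp_C"].to_numpy(dtype=float) > WARM_SPLIT_C).astype(float)
    succ = df["n_surface"].to_numpy(dtype=float)
    n_tot = df["n_frames"].to_numpy(dtype=float)
    if np.any(n_tot <= 0):
        raise ValueError("n_frames must be positive")
    fail = n_tot - succ

    cols = [np.ones_like(h)]
    terms = ["intercept"]
    cols.append(h)
    terms.append("h2s")
    if include_temp:
        cols.append(w)
        terms.append("temp")
    if include_interaction:
        if not include_temp:
            raise ValueError("interaction requires the temperature term")
        cols.append(h * w)
        terms.append("h2s:temp")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design is rank-deficient; drop the temperature/interaction "
            "terms for single-temperature data"
        )

    # Separation: a design cell with pooled surfacing fraction of 0 or 1.
    cell = pd.DataFrame({"h": h, "w": w, "s": succ, "n": n_tot})
    pooled = cell.groupby(["h", "w"]).sum()
    frac = pooled["s"] / pooled["n"]
    flags: list[str] = []
    if np.any(frac <= 0) or np.any(frac >= 1):
        flags.append("separation")
        warnings.warn(
            "complete/quasi-separation in the ASR design; "
            "using a ridge-penalized fit",
            stacklevel=2,
        )
        beta, cov = _ridge_logistic(X, succ, fail, ridge)
        flags.append("ridge")
        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(1 - alpha / 2)
        ci = np.column_stack([beta - z * se, beta + z * se])
        pv = 2 * stats.norm.sf(np.abs(beta / se))
        return AsrGlmResult(terms=terms, coef=beta, ci=ci, se=se,
                            p_values=pv, flags=flags)
    endog = np.column_stack([succ, fail])
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    ci = np.asarray(res.conf_int(alpha))
    return AsrGlmResult(
        terms=terms,
        coef=np.asarray(res.params, dtype=float),
        ci=ci,
        se=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        flags=flags,
    )
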