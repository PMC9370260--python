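"""Causal-effect estimators for two-sample Mendelian randomization.

Every estimator consumes harmonized per-SNP effects (β̂_Xj, σ_Xj) on the
exposure and (β̂_Yj, σ_Yj) on the outcome, and estimates the causal effect θ
(a log odds ratio for binary outcomes) under the instrumental-variable
assumptions. The per-SNP building block is the Wald ratio θ_j = β_Yj/β_Xj
with first-order standard error σ_Yj/|β_Xj|; the estimators differ in how
they combine the ratios and which assumption violations they tolerate:

- ``ivw``: inverse-variance weighted mean of the ratios; efficient when all
  instruments are valid, biased by any directional pleiotropy.
- ``max_likelihood``: joint-normal maximum likelihood with per-SNP nuisance
  means; accounts for uncertainty in the exposure associations.
- ``egger``: weighted regression with a free intercept; the slope is
  consistent under directional pleiotropy if instrument strength is
  independent of the direct effects (InSIDE); the intercept tests for
  directional pleiotropy.
- ``weighted_median``: consistent when at least half the weight comes from
  valid instruments.
- ``penalized_weighted_median``: downweights SNPs with outlying ratios via a
  chi-square heterogeneity penalty before taking the weighted median.

Heterogeneity across ratios is quantified by Cochran's Q and I².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .summary_io import HarmonizedInstrument

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for all confidence intervals.
Z95 = 1.959964

_P_FLOOR = 1e-300

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw": "Inverse-variance weighted",
    "max_likelihood": "Maximum likelihood",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
    "penalized_weighted_median": "Penalized weighted median",
}


class EstimationError(RuntimeError):
    """An estimator could not produce a valid estimate."""


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(EstimationError):
    """Regressors carry no variation (all exposure effects equal)."""


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect estimate on the log-OR scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    model: str = "not_applicable"  # fixed | random | not_applicable

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


@dataclass(frozen=True)
class DiagnosticsBundle:
    """Heterogeneity and pleiotropy diagnostics for one instrument set."""

    q: float
    q_df: int
    q_pvalue: float
    i2: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger fit: slope estimate plus the intercept (pleiotropy) test.

    Analytic standard errors use the t-distribution with J−2 degrees of
    freedom; when bootstrapping was requested the headline ``estimate`` and
    intercept SE/p use the bootstrap, with the analytic values retained in
    ``slope_se_analytic``/``intercept_se_analytic`` for side-by-side report.
    """

    estimate: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    slope_se_analytic: float
    intercept_se_analytic: float
    bootstrap_reps: int = 0


def _arrays(insts: Sequence[HarmonizedInstrument]):
    """Usable instruments as (beta_exp, se_exp, beta_out, se_out) arrays."""
    use = [h for h in insts if not h.dropped]
    bx = np.array([h.beta_exp for h in use], dtype=float)
    sx = np.array([h.se_exp for h in use], dtype=float)
    by = np.array([h.beta_out for h in use], dtype=float)
    sy = np.array([h.se_out for h in use], dtype=float)
    ids = [h.snp_id for h in use]
    return bx, sx, by, sy, ids


def _require(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {minimum} instruments, got {n}"
        )


def _norm_p(beta: float, se: float) -> float:
    if se == 0.0:  # degenerate (noiseless) fit
        return 1.0 if beta == 0.0 else _P_FLOOR
    return float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), _P_FLOOR, 1.0))


def _t_p(value: float, se: float, df: int) -> float:
    if se == 0.0:
        return 1.0 if value == 0.0 else _P_FLOOR
    return float(np.clip(2.0 * stats.t.sf(abs(value) / se, df), _P_FLOOR, 1.0))


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate: θ = β_Y/β_X, SE = σ_Y/|β_X| (first order)."""
    if inst.beta_exp == 0:
        raise EstimationError(f"{inst.snp_id}: exposure effect is zero; Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return MREstimate("wald", beta, se, _norm_p(beta, se), 1)


def cochran_q(
    insts: Sequence[HarmonizedInstrument], beta: float
) -> tuple[float, int, float, float]:
    """Cochran's Q of the per-SNP ratios around ``beta``, with df, p, and I².

    Q = Σ w_j (θ_j − β)² with w_j = (β_Xj/σ_Yj)²; p from chi-square(J−1);
    I² = max(0, (Q − df)/Q)·100.
    """
    bx, _, by, sy, _ = _arrays(insts)
    _require(bx.size, 2, "cochran_q")
    theta = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (theta - beta) ** 2))
    df = bx.size - 1
    pvalue = float(np.clip(stats.chi2.sf(q, df), _P_FLOOR, 1.0))
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, pvalue, i2


def ivw(
    insts: Sequence[HarmonizedInstrument], model: str = "auto"
) -> tuple[MREstimate, DiagnosticsBundle]:
    """Inverse-variance weighted estimate of the causal effect.

    Weights w_j = (β_Xj/σ_Yj)² are the inverse first-order variances of the
    Wald ratios. The fixed-effect SE is (Σw)^(−1/2); the multiplicative
    random-effects model inflates it by max(1, sqrt(Q/(J−1))). ``model`` is
    ``fixed``, ``random``, or ``auto`` (random iff the heterogeneity p < 0.05).
    """
    bx, _, by, sy, _ = _arrays(insts)
    _require(bx.size, 2, "ivw")
    if model not in {"fixed", "random", "auto"}:
        raise ValueError(f"unknown IVW model {model!r}")
    theta = by / bx
    w = (bx / sy) ** 2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q, df, q_p, i2 = cochran_q(insts, beta)
    resolved = model
    if model == "auto":
        resolved = "random" if q_p < 0.05 else "fixed"
    se = se_fixed
    if resolved == "random":
        se = se_fixed * max(1.0, math.sqrt(q / df))
    est = MREstimate("ivw", beta, se, _norm_p(beta, se), bx.size, resolved)
    return est, DiagnosticsBundle(q, df, q_p, i2)


def _profile_neg2ll(theta, bx, sx, by, sy):
    """−2 × profile log-likelihood (constants dropped).

    The per-SNP nuisance means γ_j maximize out in closed form, leaving
    Σ (β_Yj − θ β_Xj)² / (σ_Yj² + θ² σ_Xj²). The log-variance terms do not
    depend on θ and are omitted.
    """
    denom = sy**2 + theta**2 * sx**2
    return float(np.sum((by - theta * bx) ** 2 / denom))


def max_likelihood(
    insts: Sequence[HarmonizedInstrument], max_restarts: int = 5
) -> MREstimate:
    """Likelihood-based causal estimate under a joint normal model.

    Models β̂_Xj ~ N(γ_j, σ_Xj²) and β̂_Yj ~ N(θγ_j, σ_Yj²) with independent
    errors, profiles out the γ_j, and maximizes over θ starting from the IVW
    estimate. The SE comes from the curvature of the profile likelihood at
    the optimum, which unlike IVW propagates the exposure-side uncertainty.
    """
    bx, sx, by, sy, _ = _arrays(insts)
    _require(bx.size, 2, "max_likelihood")
    ivw_est, _ = ivw(insts, model="fixed")
    start, scale = ivw_est.beta, max(ivw_est.se, 1e-8)

    theta_hat = None
    for attempt in range(max_restarts + 1):
        width = scale * 10.0 ** (attempt + 1)
        res = optimize.minimize_scalar(
            _profile_neg2ll,
            bounds=(start - width, start + width),
            args=(bx, sx, by, sy),
            method="bounded",
            options={"xatol": 1e-12},
        )
        at_edge = min(res.x - (start - width), (start + width) - res.x) < 1e-6 * width
        if res.success and np.isfinite(res.fun) and not at_edge:
            theta_hat = float(res.x)
            break
    if theta_hat is None:
        raise EstimationError(
            f"maximum-likelihood optimizer failed to converge after {max_restarts} restarts"
        )

    # Observed information from the profile curvature: I(θ) = ½ d²(−2ℓ)/dθ².
    h = max(1e-6, 1e-3 * scale)
    f = lambda t: _profile_neg2ll(t, bx, sx, by, sy)
    d2 = (f(theta_hat + h) - 2.0 * f(theta_hat) + f(theta_hat - h)) / (h * h)
    if d2 <= 0 or not np.isfinite(d2):
        raise EstimationError(
            f"profile likelihood not locally convex at θ={theta_hat:.4g} (d2={d2:.4g})"
        )
    se = math.sqrt(2.0 / d2)
    return MREstimate("max_likelihood", theta_hat, se, _norm_p(theta_hat, se), bx.size)


def _egger_wls(bx, by, sy):
    """Weighted least squares of oriented β_Y on β_X with a free intercept."""
    import statsmodels.api as sm

    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    if np.ptp(x) < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise CollinearityError(
            "all exposure effects equal after orientation; Egger slope unidentified"
        )
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=1.0 / sy**2).fit()
    return fit, x, y


def egger(
    insts: Sequence[HarmonizedInstrument],
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> tuple[MREstimate, DiagnosticsBundle]:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    SNPs are oriented so every exposure effect is positive (both betas negated
    when β_Xj < 0), then β_Yj is regressed on β_Xj with weights σ_Yj⁻² and a
    free intercept α. The slope estimates θ under InSIDE; α ≠ 0 indicates
    directional pleiotropy. Analytic inference uses t(J−2); with
    ``bootstrap_reps`` > 0 the slope/intercept SEs are replaced by the
    standard deviation over residual-resampled refits (normal reference).
    """
    bx, _, by, sy, _ = _arrays(insts)
    _require(bx.size, 3, "egger")
    fit, x, y = _egger_wls(bx, by, sy)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    int_se_a, slope_se_a = float(fit.bse[0]), float(fit.bse[1])
    df = bx.size - 2
    slope_p_a = _t_p(slope, slope_se_a, df)
    int_p_a = _t_p(intercept, int_se_a, df)

    slope_se, int_se = slope_se_a, int_se_a
    slope_p, int_p = slope_p_a, int_p_a
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        w = 1.0 / sy**2
        fitted = intercept + slope * x
        resid_std = (y - fitted) * np.sqrt(w)  # homoscedastic on the weighted scale
        idx = rng.integers(0, x.size, size=(bootstrap_reps, x.size))
        ystar = fitted + resid_std[idx] / np.sqrt(w)
        # closed-form WLS per replicate
        sw = np.sum(w)
        mx = np.sum(w * x) / sw
        sxx = np.sum(w * (x - mx) ** 2)
        my = np.sum(w * ystar, axis=1) / sw
        slopes = np.sum(w * (x - mx) * ystar, axis=1) / sxx
        intercepts = my - slopes * mx
        slope_se = float(np.std(slopes, ddof=1))
        int_se = float(np.std(intercepts, ddof=1))
        slope_p = _norm_p(slope, slope_se)
        int_p = _norm_p(intercept, int_se)

    est = MREstimate("egger", slope, slope_se, slope_p, bx.size)
    # Q of residuals about the Egger fit is not reported here; the pipeline's
    # heterogeneity gate uses the IVW Q. The bundle carries the intercept test.
    q, qdf, q_p, i2 = cochran_q(insts, slope)
    diags = DiagnosticsBundle(q, qdf, q_p, i2, intercept, int_se, int_p)
    est_full = EggerResult(est, intercept, int_se, int_p, slope_se_a, int_se_a, bootstrap_reps)
    return est, diags, est_full


def egger_intercept_test(
    insts: Sequence[HarmonizedInstrument],
) -> tuple[float, float, float]:
    """The (intercept, SE, two-sided p) triple from the analytic Egger fit.

    The pipeline's pleiotropy gate: p < 0.05 promotes MR-Egger to the primary
    method, otherwise IVW is primary.
    """
    bx, _, by, sy, _ = _arrays(insts)
    _require(bx.size, 3, "egger_intercept_test")
    fit, _, _ = _egger_wls(bx, by, sy)
    intercept, int_se = float(fit.params[0]), float(fit.bse[0])
    return intercept, int_se, _t_p(intercept, int_se, bx.size - 2)


def _weighted_median_batch(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted medians row-wise for (B, J) ratio/weight arrays.

    Per row: sort ratios ascending (stable), normalize weights, form
    S_j = cumsum(w')_j − w'_j/2, and linearly interpolate θ across S at
    S = 0.5, clamping at the extreme order statistics.
    """
    order = np.argsort(theta, axis=-1, kind="stable")
    th = np.take_along_axis(theta, order, -1)
    w = np.take_along_axis(weights, order, -1)
    wn = w / np.sum(w, axis=-1, keepdims=True)
    s = np.cumsum(wn, axis=-1) - wn / 2.0
    below = np.sum(s < 0.5, axis=-1)  # index of first S >= 0.5
    j = theta.shape[-1]
    out = np.empty(theta.shape[:-1], dtype=float)
    rows = np.arange(theta.shape[0]) if theta.ndim == 2 else None
    lo_clip = below == 0
    hi_clip = below == j
    mid = ~(lo_clip | hi_clip)
    if theta.ndim == 1:
        if lo_clip:
            return th[0]
        if hi_clip:
            return th[-1]
        k = int(below)
        frac = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        return th[k - 1] + frac * (th[k] - th[k - 1])
    out[lo_clip] = th[lo_clip, 0]
    out[hi_clip] = th[hi_clip, -1]
    if np.any(mid):
        r = rows[mid]
        k = below[mid]
        s0, s1 = s[r, k - 1], s[r, k]
        frac = (0.5 - s0) / (s1 - s0)
        out[mid] = th[r, k - 1] + frac * (th[r, k] - th[r, k - 1])
    return out


def weighted_median_value(theta: np.ndarray, weights: np.ndarray) -> float:
    """Point value of the weighted median of per-SNP ratios."""
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(_weighted_median_batch(theta, weights))


def _parametric_bootstrap_ratios(bx, sx, by, sy, reps, rng):
    bxs = rng.normal(bx, sx, size=(reps, bx.size))
    bys = rng.normal(by, sy, size=(reps, by.size))
    # guard: a resampled exposure effect through zero makes the ratio explode;
    # weights (β*_X/σ_Y)² then vanish, so the median is essentially unaffected.
    bxs = np.where(bxs == 0.0, 1e-300, bxs)
    theta = bys / bxs
    w = (bxs / sy) ** 2
    return theta, w


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    bootstrap_reps: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate (valid if ≥ half the weight is valid).

    Ratios are ordered ascending (ties broken by snp_id via a pre-sort) and
    the inverse-variance weights interpolated to the 50% point. The SE is the
    standard deviation of the estimate over parametric-bootstrap resamples of
    (β̂_Xj, β̂_Yj); p is two-sided normal.
    """
    bx, sx, by, sy, ids = _arrays(insts)
    _require(bx.size, 3, "weighted_median")
    if bootstrap_reps < 1:
        raise ValueError("bootstrap_reps must be positive")
    # stable tie-break on snp_id
    pre = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    bx, sx, by, sy = bx[pre], sx[pre], by[pre], sy[pre]
    theta = by / bx
    w = (bx / sy) ** 2
    beta = weighted_median_value(theta, w)
    rng = np.random.default_rng(seed)
    th_b, w_b = _parametric_bootstrap_ratios(bx, sx, by, sy, bootstrap_reps, rng)
    se = float(np.std(_weighted_median_batch(th_b, w_b), ddof=1))
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), bx.size)


def _penalized_weights(theta: np.ndarray, w: np.ndarray, penalty: float) -> np.ndarray:
    """Downweight outlying ratios: w* = w · min(1, penalty · p_j).

    p_j is the upper chi-square(1) tail of Q_j = w_j (θ_j − θ_WM)², the SNP's
    heterogeneity contribution about the plain weighted median θ_WM.
    """
    wm = _weighted_median_batch(theta, w)
    diff = theta - (np.expand_dims(wm, -1) if theta.ndim == 2 else wm)
    qj = w * diff**2
    pj = stats.chi2.sf(qj, 1)
    return w * np.minimum(1.0, penalty * pj)


def penalized_weighted_median(
    insts: Sequence[HarmonizedInstrument],
    penalty: float = 20.0,
    bootstrap_reps: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median with chi-square-penalized weights.

    SNPs whose ratio is far from the plain weighted median receive weight
    w_j · min(1, penalty·p_j), shrinking the influence of invalid instruments;
    with no outliers all p_j are large and the estimate equals the plain
    weighted median. SE by parametric bootstrap with the penalization
    recomputed inside each resample.
    """
    bx, sx, by, sy, ids = _arrays(insts)
    _require(bx.size, 3, "penalized_weighted_median")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    pre = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    bx, sx, by, sy = bx[pre], sx[pre], by[pre], sy[pre]
    theta = by / bx
    w = (bx / sy) ** 2
    beta = weighted_median_value(theta, _penalized_weights(theta, w, penalty))
    rng = np.random.default_rng(seed)
    th_b, w_b = _parametric_bootstrap_ratios(bx, sx, by, sy, bootstrap_reps, rng)
    w_b_pen = _penalized_weights(th_b, w_b, penalty)
    se = float(np.std(_weighted_median_batch(th_b, w_b_pen), ddof=1))
    return MREstimate("penalized_weighted_median", beta, se, _norm_p(beta, se), bx.size)
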