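"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

A resampling test for horizontal pleiotropy. The observed leave-one-out
residual sum of squares of the per-SNP Wald ratios is compared against a
parametric null in which every instrument is valid; a small global p-value
indicates that at least one SNP's outcome effect is inconsistent with the
common causal effect. Individual outliers are then flagged by their per-SNP
residuals, removed, and the IVW estimate recomputed; a distortion test asks
whether removal moved the estimate more than removing random SNPs would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mr_estimators import (
    DiagnosticsBundle,
    InsufficientInstrumentsError,
    MREstimate,
    _arrays,
    ivw,
)
from .summary_io import HarmonizedInstrument

logger = logging.getLogger(__name__)


class PressoError(RuntimeError):
    pass


class DegenerateCorrectionError(PressoError):
    """Every instrument was flagged as an outlier; no corrected estimate exists."""


@dataclass(frozen=True)
class PressoResult:
    """Outcome of the MR-PRESSO global, outlier, and distortion tests."""

    rss_obs: float
    global_pvalue: float
    outlier_indices: tuple[int, ...]
    outlier_snps: tuple[str, ...]
    outlier_pvalues: tuple[float, ...]  # Bonferroni-adjusted, one per instrument
    n_sim: int
    outlier_alpha: float
    corrected: MREstimate | None = None
    corrected_diagnostics: DiagnosticsBundle | None = None
    distortion_pvalue: float | None = None
    distortion_percent: float | None = None

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_indices) > 0


def _loo_ivw(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates θ̂_(−j), vectorized over trailing axis."""
    sw = np.sum(w, axis=-1, keepdims=True)
    swt = np.sum(w * theta, axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def _rss_and_residuals(theta, w):
    loo = _loo_ivw(theta, w)
    resid = w * (theta - loo) ** 2
    return np.sum(resid, axis=-1), resid


def presso(
    insts: list[HarmonizedInstrument],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is RSS = Σ_j w_j (θ_j − θ̂_(−j))² with θ_j the
    Wald ratio, w_j = (β_Xj/σ_Yj)², and θ̂_(−j) the IVW estimate without SNP
    j (so each SNP is judged against the effect implied by the others). The
    null distribution is built from ``n_sim`` parametric draws
    β̂*_Xj ~ N(β̂_Xj, σ_Xj²), β̂*_Yj ~ N(θ̂_(−j) β̂_Xj, σ_Yj²); empirical
    p-values use the +1 correction so they are never zero.

    When the global test is significant (p < 0.05), each SNP's observed
    residual is compared with its simulated residuals; Bonferroni-adjusted
    empirical p-values below ``outlier_alpha`` flag the SNP as an outlier.
    The corrected estimate is plain IVW on the retained subset. The
    distortion test (informational; it gates nothing) compares the corrected
    estimate's displacement against removing equally many random SNPs.

    Requires at least 4 instruments.
    """
    bx, sx, by, sy, ids = _arrays(insts)
    j = bx.size
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires at least 4 instruments, got {j}")
    rng = np.random.default_rng(seed)

    theta = by / bx
    w = (bx / sy) ** 2
    loo = _loo_ivw(theta, w)
    rss_obs, resid_obs = _rss_and_residuals(theta, w)
    rss_obs = float(rss_obs)

    # parametric null: every SNP consistent with its leave-one-out estimate
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, j))
    bx_star = np.where(bx_star == 0.0, 1e-300, bx_star)
    theta_star = by_star / bx_star
    w_star = (bx_star / sy) ** 2
    rss_star, resid_star = _rss_and_residuals(theta_star, w_star)
    global_pvalue = float((1 + np.sum(rss_star >= rss_obs)) / (1 + n_sim))

    outlier_idx: tuple[int, ...] = ()
    outlier_p = tuple(np.ones(j))
    if global_pvalue < 0.05:
        per_snp = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (1 + n_sim)
        adj = np.minimum(1.0, per_snp * j)  # Bonferroni across instruments
        outlier_p = tuple(float(p) for p in adj)
        outlier_idx = tuple(int(i) for i in np.nonzero(adj < outlier_alpha)[0])
        logger.info(
            "MR-PRESSO global p=%.4g; %d outlier(s): %s",
            global_pvalue, len(outlier_idx), [ids[i] for i in outlier_idx],
        )

    corrected = corrected_diag = None
    distortion_p = distortion_pct = None
    if outlier_idx:
        keep_mask = np.ones(j, dtype=bool)
        keep_mask[list(outlier_idx)] = False
        if not keep_mask.any() or keep_mask.sum() < 2:
            raise DegenerateCorrectionError(
                f"{j - int(keep_mask.sum())}/{j} instruments flagged; corrected IVW undefined"
            )
        kept = [h for h, k in zip([h for h in insts if not h.dropped], keep_mask) if k]
        corrected, corrected_diag = ivw(kept, model="fixed")

        full_beta = float(np.sum(w * theta) / np.sum(w))
        if full_beta != 0.0:
            distortion_pct = 100.0 * (corrected.beta - full_beta) / abs(full_beta)
            n_out = len(outlier_idx)
            d_null = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(j, size=n_out, replace=False)
                m = np.ones(j, dtype=bool)
                m[drop] = False
                b_sub = np.sum(w[m] * theta[m]) / np.sum(w[m])
                d_null[b] = 100.0 * (b_sub - full_beta) / abs(full_beta)
            distortion_p = float(
                (1 + np.sum(np.abs(d_null) >= abs(distortion_pct))) / (1 + n_sim)
            )

    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=global_pvalue,
        outlier_indices=outlier_idx,
        outlier_snps=tuple(ids[i] for i in outlier_idx),
        outlier_pvalues=outlier_p,
        n_sim=n_sim,
        outlier_alpha=outlier_alpha,
        corrected=corrected,
        corrected_diagnostics=corrected_diag,
        distortion_pvalue=distortion_p,
        distortion_percent=distortion_pct,
    )
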