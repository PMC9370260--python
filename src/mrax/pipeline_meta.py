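"""Per-cohort MR decision tree, cross-cohort meta-analysis, and tiering.

The analysis protocol, per exposure–outcome pair and cohort:

1. Harmonize exposure and outcome summary statistics and filter instruments.
2. Run every estimator the SNP count J supports: J = 1 → Wald ratio only;
   J = 2 → IVW and maximum likelihood; J ≥ 3 → plus MR-Egger and both
   medians; J ≥ 4 → plus MR-PRESSO.
3. Choose the primary method by the MR-Egger intercept test: significant
   directional pleiotropy (p < 0.05) promotes MR-Egger, otherwise IVW.
4. Pick fixed- vs random-effects IVW by the Cochran's Q p-value (< 0.05 →
   random).

Cohort estimates are then combined by inverse-variance meta-analysis (fixed
effect, switching to DerSimonian–Laird random effects when the cross-cohort
heterogeneity p < 0.05), and the combined p-value is tiered against a
Bonferroni threshold of 0.01 (five outcomes) with 0.01–0.05 counted as
suggestive evidence. Every gate decision is recorded in a decision trace.

When only the published OR and 95% CI of a cohort are available, the log-OR
and its SE are reconstructed as β = ln(OR), SE = [ln(CI_hi) − ln(CI_lo)]/(2z)
with z = 1.959964, enabling meta-analysis of printed results.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import mr_estimators as est
from .instruments import (
    DEFAULT_F_MIN,
    NoValidInstrumentsError,
    scale_exposure,
    select_instruments,
)
from .mr_estimators import (
    DiagnosticsBundle,
    EggerResult,
    InsufficientInstrumentsError,
    MREstimate,
    Z95,
)
from .mr_presso import PressoResult, presso
from .summary_io import (
    HarmonizedInstrument,
    SummaryStat,
    harmonize,
    read_summary_stats,
    usable,
)

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


class PipelineError(RuntimeError):
    pass


def classify_tier(pvalue: float, significant: float = 0.01, suggestive: float = 0.05) -> str:
    """Bonferroni tier: p < 0.01 significant, 0.01 ≤ p < 0.05 suggestive, else null."""
    if not (0.0 < pvalue <= 1.0):
        raise ValueError(f"invalid p-value {pvalue}")
    if pvalue < significant:
        return "significant"
    if pvalue < suggestive:
        return "suggestive"
    return "null"


@dataclass(frozen=True)
class CohortEstimate:
    """One cohort's causal estimate for one exposure–outcome pair."""

    cohort: str
    exposure: str
    outcome: str
    beta: float
    se: float
    pvalue: float
    source: str = "computed"  # computed | reconstructed_from_ci
    method: str = ""
    model: str = "not_applicable"
    n_snps: int = 0

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def estimate_from_ci(
    or_: float,
    ci_low: float,
    ci_high: float,
    cohort: str = "",
    exposure: str = "",
    outcome: str = "",
) -> CohortEstimate:
    """Reconstruct a log-OR and SE from a printed OR with symmetric 95% CI.

    β = ln(OR); SE = [ln(CI_high) − ln(CI_low)] / (2·1.959964). Warns when the
    reconstructed interval disagrees with the printed bounds by more than 1%
    relative (an asymmetric interval, e.g. from a profile likelihood, is not
    faithfully represented by this normal approximation).
    """
    if not (0.0 < ci_low < or_ < ci_high):
        raise ValueError(f"CI ordering violated: {ci_low} < {or_} < {ci_high} expected")
    beta = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    lo_back, hi_back = math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)
    if abs(lo_back - ci_low) / ci_low > 0.01 or abs(hi_back - ci_high) / ci_high > 0.01:
        logger.warning(
            "asymmetric CI (%.3g, %.3g) around OR %.3g; normal reconstruction inexact",
            ci_low, ci_high, or_,
        )
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), _P_FLOOR, 1.0))
    return CohortEstimate(
        cohort=cohort, exposure=exposure, outcome=outcome,
        beta=beta, se=se, pvalue=p, source="reconstructed_from_ci",
    )


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance combined estimate across cohorts."""

    beta: float
    se: float
    pvalue: float
    q: float
    q_df: int
    q_pvalue: float
    i2: float
    model: str
    tier: str
    n_cohorts: int
    tau2: float = 0.0

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def meta_combine(
    cohorts: Sequence[CohortEstimate], model: str = "auto"
) -> MetaResult:
    """Inverse-variance meta-analysis of per-cohort log-ORs.

    Fixed effect: weights 1/SE², combined SE (Σw)^(−1/2). Heterogeneity by
    Cochran's Q across cohorts. ``auto`` switches to DerSimonian–Laird
    random effects (additive τ²) when the heterogeneity p < 0.05. A single
    cohort passes through with a warning.
    """
    if model not in {"fixed", "random", "auto"}:
        raise ValueError(f"unknown meta model {model!r}")
    if not cohorts:
        raise PipelineError("meta_combine requires at least one cohort estimate")
    b = np.array([c.beta for c in cohorts])
    se = np.array([c.se for c in cohorts])
    if len(cohorts) == 1:
        logger.warning("single cohort: meta-analysis is a passthrough")
        p = float(np.clip(2.0 * stats.norm.sf(abs(b[0]) / se[0]), _P_FLOOR, 1.0))
        return MetaResult(
            beta=float(b[0]), se=float(se[0]), pvalue=p,
            q=0.0, q_df=0, q_pvalue=1.0, i2=0.0,
            model="not_applicable", tier=classify_tier(p), n_cohorts=1,
        )
    w = 1.0 / se**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_fe) ** 2))
    df = len(cohorts) - 1
    q_p = float(np.clip(stats.chi2.sf(q, df), _P_FLOOR, 1.0))
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    resolved = model if model != "auto" else ("random" if q_p < 0.05 else "fixed")
    tau2 = 0.0
    if resolved == "fixed":
        beta_hat, se_hat = beta_fe, float(np.sum(w) ** -0.5)
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        beta_hat = float(np.sum(w_star * b) / np.sum(w_star))
        se_hat = float(np.sum(w_star) ** -0.5)
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta_hat) / se_hat), _P_FLOOR, 1.0))
    return MetaResult(
        beta=beta_hat, se=se_hat, pvalue=p,
        q=q, q_df=df, q_pvalue=q_p, i2=i2,
        model=resolved, tier=classify_tier(p), n_cohorts=len(cohorts), tau2=tau2,
    )


@dataclass
class PipelineConfig:
    """Knobs for :func:`run_pipeline`. ``seed`` drives every resampling step."""

    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    phenotype_class: str = "absolute"
    palindromic_window: float = 0.08
    p_threshold: float | None = None  # None: inputs are pre-selected instruments
    f_min: float = DEFAULT_F_MIN
    scale_factor: float = 1.0
    pleiotropy_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    bootstrap_reps_median: int = 5000
    bootstrap_reps_egger: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0
    delimiter: str = "\t"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known - {"exposure_file", "outcome_files"}
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})


@dataclass
class CohortAnalysis:
    """Everything computed for one cohort: all estimates, diagnostics, trace."""

    cohort: str
    n_snps: int
    estimates: dict[str, MREstimate]
    primary: str
    diagnostics: DiagnosticsBundle | None
    egger_full: EggerResult | None
    presso: PressoResult | None
    trace: list[str]

    @property
    def primary_estimate(self) -> MREstimate:
        return self.estimates[self.primary]


def analyze_cohort(
    harmonized: Sequence[HarmonizedInstrument],
    config: PipelineConfig,
    cohort: str = "",
) -> CohortAnalysis:
    """Run the J-gated estimator battery and the model-selection gates.

    The decision trace records the SNP count, which methods ran or were
    suppressed and why, the pleiotropy-gate outcome, and the heterogeneity-
    gate outcome, so every reported number is justified by an explicit line.
    """
    insts = usable(harmonized)
    j = len(insts)
    trace = [f"[{cohort}] {j} usable instrument(s) "
             f"({len(harmonized) - j} dropped during harmonization)"]
    if j == 0:
        raise NoValidInstrumentsError(f"{cohort}: no usable instruments after harmonization")

    estimates: dict[str, MREstimate] = {}
    diagnostics = None
    egger_full = None
    presso_result = None

    if j == 1:
        estimates["wald"] = est.wald_ratio(insts[0])
        trace.append(f"[{cohort}] J=1: Wald ratio only; all multi-SNP methods suppressed")
        primary = "wald"
    else:
        ivw_est, diagnostics = est.ivw(insts, model="auto")
        estimates["ivw"] = ivw_est
        trace.append(
            f"[{cohort}] heterogeneity gate: Q={diagnostics.q:.3f} "
            f"(df={diagnostics.q_df}, p={diagnostics.q_pvalue:.3f}, I²={diagnostics.i2:.1f}%) → "
            f"{ivw_est.model}-effect IVW"
        )
        estimates["max_likelihood"] = est.max_likelihood(insts)
        primary = "ivw"
        if j >= 3:
            try:
                _, ediags, egger_full = est.egger(
                    insts, bootstrap_reps=config.bootstrap_reps_egger,
                    seed=config.seed,
                )
                estimates["egger"] = egger_full.estimate
                diagnostics = DiagnosticsBundle(
                    diagnostics.q, diagnostics.q_df, diagnostics.q_pvalue, diagnostics.i2,
                    egger_full.intercept, egger_full.intercept_se, egger_full.intercept_pvalue,
                )
                if egger_full.intercept_pvalue < config.pleiotropy_alpha:
                    primary = "egger"
                    trace.append(
                        f"[{cohort}] pleiotropy gate: Egger intercept "
                        f"{egger_full.intercept:.4f} (p={egger_full.intercept_pvalue:.3f}) "
                        f"< {config.pleiotropy_alpha} → MR-Egger primary"
                    )
                else:
                    trace.append(
                        f"[{cohort}] pleiotropy gate: Egger intercept "
                        f"{egger_full.intercept:.4f} (p={egger_full.intercept_pvalue:.3f}) "
                        f"≥ {config.pleiotropy_alpha} → IVW primary"
                    )
            except est.CollinearityError as exc:
                trace.append(f"[{cohort}] MR-Egger skipped: {exc}")
            estimates["weighted_median"] = est.weighted_median(
                insts, bootstrap_reps=config.bootstrap_reps_median, seed=config.seed
            )
            estimates["penalized_weighted_median"] = est.penalized_weighted_median(
                insts, bootstrap_reps=config.bootstrap_reps_median, seed=config.seed
            )
        else:
            trace.append(
                f"[{cohort}] J=2: Egger/median methods require > 2 SNPs; suppressed. "
                f"Pleiotropy gate unavailable → IVW primary"
            )
        if j >= 4:
            presso_result = presso(
                insts, n_sim=config.presso_n_sim,
                outlier_alpha=config.presso_outlier_alpha, seed=config.seed,
            )
            if presso_result.has_outliers:
                trace.append(
                    f"[{cohort}] MR-PRESSO global p={presso_result.global_pvalue:.4f}; "
                    f"outliers {list(presso_result.outlier_snps)} removed; "
                    f"corrected IVW OR={presso_result.corrected.or_:.3f}"
                )
            else:
                trace.append(
                    f"[{cohort}] MR-PRESSO global p={presso_result.global_pvalue:.4f}; "
                    f"no outliers; no correction required"
                )
        else:
            trace.append(f"[{cohort}] J={j} ≤ 3: MR-PRESSO suppressed (requires > 3 SNPs)")

    trace.append(f"[{cohort}] primary method: {primary}")
    return CohortAnalysis(
        cohort=cohort, n_snps=j, estimates=estimates, primary=primary,
        diagnostics=diagnostics, egger_full=egger_full,
        presso=presso_result, trace=trace,
    )


@dataclass
class PipelineReport:
    """Structured output of :func:`run_pipeline`."""

    exposure: str
    outcome: str
    cohorts: dict[str, CohortAnalysis]
    cohort_estimates: list[CohortEstimate]
    meta: MetaResult | None
    skipped_cohorts: dict[str, str]
    trace: list[str]

    def to_dict(self) -> dict:
        def est_row(e: MREstimate) -> dict:
            return {
                "beta": e.beta, "se": e.se, "or": e.or_,
                "ci_low": e.ci_low, "ci_high": e.ci_high,
                "pvalue": e.pvalue, "n_snps": e.n_snps, "model": e.model,
            }

        out = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "cohorts": {},
            "meta": None,
            "skipped_cohorts": self.skipped_cohorts,
            "trace": self.trace,
        }
        for name, ana in self.cohorts.items():
            diag = ana.diagnostics
            out["cohorts"][name] = {
                "n_snps": ana.n_snps,
                "primary": ana.primary,
                "estimates": {m: est_row(e) for m, e in ana.estimates.items()},
                "diagnostics": None if diag is None else asdict(diag),
                "presso": None
                if ana.presso is None
                else {
                    "rss_obs": ana.presso.rss_obs,
                    "global_pvalue": ana.presso.global_pvalue,
                    "outlier_snps": list(ana.presso.outlier_snps),
                    "distortion_pvalue": ana.presso.distortion_pvalue,
                    "corrected": None
                    if ana.presso.corrected is None
                    else est_row(ana.presso.corrected),
                },
            }
        if self.meta is not None:
            m = self.meta
            out["meta"] = {
                "beta": m.beta, "se": m.se, "or": m.or_,
                "ci_low": m.ci_low, "ci_high": m.ci_high, "pvalue": m.pvalue,
                "q": m.q, "q_pvalue": m.q_pvalue, "i2": m.i2, "tau2": m.tau2,
                "model": m.model, "tier": m.tier, "n_cohorts": m.n_cohorts,
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(
    exposure: str | Path | Sequence[SummaryStat],
    outcome_files: Mapping[str, str | Path | Sequence[SummaryStat]],
    config: PipelineConfig | None = None,
    proxies: Mapping[str, str] | None = None,
) -> PipelineReport:
    """Full per-cohort analysis followed by cross-cohort meta-analysis.

    ``exposure`` and the values of ``outcome_files`` may be file paths (read
    with the canonical column map) or in-memory record collections. Cohorts
    whose instrument set is unusable are skipped with an explicit report
    entry; if every cohort is skipped the pipeline errors.
    """
    config = config or PipelineConfig()
    exp_stats = (
        read_summary_stats(exposure, delimiter=config.delimiter)
        if isinstance(exposure, (str, Path))
        else list(exposure)
    )
    if config.p_threshold is not None:
        exp_stats = select_instruments(
            exp_stats, p_threshold=config.p_threshold, f_min=config.f_min,
            phenotype_class=config.phenotype_class,
        )
    else:
        # inputs are pre-selected instruments; apply only the weak-instrument filter
        from .instruments import compute_f

        n0 = len(exp_stats)
        exp_stats = [r for r in exp_stats if compute_f(r.beta, r.se) > config.f_min]
        if not exp_stats:
            raise NoValidInstrumentsError(f"all {n0} instruments weak (F <= {config.f_min:g})")

    cohorts: dict[str, CohortAnalysis] = {}
    cohort_estimates: list[CohortEstimate] = []
    skipped: dict[str, str] = {}
    trace: list[str] = [
        f"exposure {config.exposure_name}: {len(exp_stats)} candidate instrument(s) "
        f"after p/F filtering (F > {config.f_min:g})"
    ]
    for cohort, src in outcome_files.items():
        out_stats = (
            read_summary_stats(src, delimiter=config.delimiter)
            if isinstance(src, (str, Path))
            else list(src)
        )
        try:
            harmonized = harmonize(
                exp_stats, out_stats,
                palindromic_eaf_window=config.palindromic_window,
                proxies=proxies,
            )
            harmonized = scale_exposure(harmonized, config.scale_factor)
            if config.scale_factor != 1.0:
                trace.append(
                    f"[{cohort}] exposure rescaled: estimates per "
                    f"{config.scale_factor:g} exposure unit(s)"
                )
            ana = analyze_cohort(harmonized, config, cohort=cohort)
        except (NoValidInstrumentsError, InsufficientInstrumentsError, est.EstimationError) as exc:
            skipped[cohort] = str(exc)
            trace.append(f"[{cohort}] skipped: {exc}")
            continue
        cohorts[cohort] = ana
        trace.extend(ana.trace)
        e = ana.primary_estimate
        cohort_estimates.append(
            CohortEstimate(
                cohort=cohort, exposure=config.exposure_name,
                outcome=config.outcome_name, beta=e.beta, se=e.se,
                pvalue=e.pvalue, source="computed", method=e.method,
                model=e.model, n_snps=e.n_snps,
            )
        )
    if not cohorts:
        raise PipelineError(f"all cohorts skipped: {skipped}")

    meta = meta_combine(cohort_estimates, model="auto")
    trace.append(
        f"meta-analysis ({meta.model}): OR={meta.or_:.3f} "
        f"({meta.ci_low:.3f}–{meta.ci_high:.3f}), p={meta.pvalue:.3f}, "
        f"Q p={meta.q_pvalue:.3f}, I²={meta.i2:.1f}% → tier={meta.tier}"
    )
    return PipelineReport(
        exposure=config.exposure_name, outcome=config.outcome_name,
        cohorts=cohorts, cohort_estimates=cohort_estimates,
        meta=meta, skipped_cohorts=skipped, trace=trace,
    )
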