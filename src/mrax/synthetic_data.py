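"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the data regime of a two-sample MR study of circulating exposures on
binary disease outcomes: a handful of strong, independent instruments (the
post-clumping regime, so no LD between SNPs), an exposure GWAS of a few
thousand to ~100k samples, and large biobank-style case–control outcome GWAS
with low case fractions. The generator draws per-SNP true exposure effects
sized to hit a target total explained variance, adds configurable horizontal
pleiotropy, and emits both GWAS files in the package's summary-statistics
format together with a truth record that estimators never see.

Model (standardized exposure X, binary outcome Y on the log-odds scale):

    β̂_Xj ~ Normal(γ_j, σ_Xj²),   σ_Xj ≈ [2 MAF_j (1−MAF_j) · n_exp]^(−1/2)
    β̂_Yj ~ Normal(θ γ_j + α_j, σ_Yj²),
    σ_Yj ≈ [2 MAF_j (1−MAF_j) · n_out · cf (1−cf)]^(−1/2)

with γ_j chosen so Σ 2 MAF(1−MAF) γ² equals the target R², and α_j the
per-SNP direct (pleiotropic) effect: zero, balanced (mean 0), directional
(non-zero mean), or correlated with instrument strength (violating InSIDE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import stats

from .summary_io import SummaryStat

#: Non-palindromic allele pairs used for simulated variants.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator settings. Defaults mirror an ascorbate-on-colon-cancer-like
    design: 10 instruments explaining 1.7% of a 52k-sample exposure GWAS,
    against a 420k-sample biobank outcome GWAS with ~0.9% cases, and a
    protective causal log-OR of −0.25 per exposure unit."""

    n_snps: int = 10
    theta: float = -0.25
    n_exp: int = 52_018
    n_out: int = 420_531
    case_fraction: float = 0.00894
    maf_range: tuple[float, float] = (0.1, 0.5)
    exposure_r2_total: float = 0.017
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_rho: float = 0.5
    outlier_spec: tuple[int, float] | None = None  # (index, offset in ratio-SE units)
    flip_fraction: float = 0.5  # outcome rows reported on the opposite effect allele
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise SimulationConfigError("n_snps must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise SimulationConfigError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.exposure_r2_total < 1.0):
            raise SimulationConfigError("exposure_r2_total must be in [0, 1)")
        if self.exposure_r2_total / self.n_snps >= 2 * lo * (1 - lo):
            raise SimulationConfigError(
                f"per-SNP R² {self.exposure_r2_total / self.n_snps:.3g} infeasible "
                f"for MAF ≥ {lo}"
            )
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise SimulationConfigError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.outlier_spec is not None and not (0 <= self.outlier_spec[0] < self.n_snps):
            raise SimulationConfigError("outlier index out of range")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated dataset; estimators never read this."""

    theta: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    maf: tuple[float, ...]
    sigma_x: tuple[float, ...]
    sigma_y: tuple[float, ...]
    snp_ids: tuple[str, ...]
    outlier_index: int | None = None


def _draw_pleiotropy(cfg: SimConfig, gamma: np.ndarray, rng: np.random.Generator):
    j = gamma.size
    if cfg.pleiotropy_mode == "none":
        return np.zeros(j)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_sd, j)
    # Allele labels are arbitrary, so "directional" pleiotropy is defined
    # relative to the exposure-increasing allele: orienting a SNP flips the
    # direct effect along with gamma.
    sign = np.where(gamma < 0, -1.0, 1.0)
    if cfg.pleiotropy_mode == "directional":
        return sign * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, j)
    # inside_violating: direct effects correlated with instrument strength
    g = np.abs(gamma)
    z = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(j)
    noise = rng.normal(0.0, 1.0, j)
    mix = cfg.inside_rho * z + math.sqrt(max(0.0, 1 - cfg.inside_rho**2)) * noise
    return sign * (cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix)


def _stat_rows(snp_ids, pairs, eafs, betas, ses, n) -> list[SummaryStat]:
    rows = []
    for i in range(len(snp_ids)):
        ea, oa = pairs[i]
        p = float(np.clip(2.0 * stats.norm.sf(abs(betas[i]) / ses[i]), 1e-300, 1.0))
        rows.append(
            SummaryStat(
                snp_id=snp_ids[i], effect_allele=ea, other_allele=oa,
                eaf=float(eafs[i]), beta=float(betas[i]), se=float(ses[i]),
                pvalue=p, n=n,
            )
        )
    return rows


def simulate_multi_cohort(
    config: SimConfig, n_cohorts: int = 1
) -> tuple[list[SummaryStat], list[list[SummaryStat]], TruthRecord]:
    """One exposure GWAS and ``n_cohorts`` independent outcome GWAS.

    All cohorts share the same variants, alleles, true per-SNP effects, and
    direct (pleiotropic) effects — only the outcome sampling noise (and the
    reported allele orientation) differs, mirroring the same instruments
    looked up in two biobanks. Deterministic given ``config``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snps

    maf = rng.uniform(*config.maf_range, j)
    het = 2.0 * maf * (1.0 - maf)
    # Heterogeneous per-SNP R² shares, as in real instrument sets (a lead SNP
    # plus weaker secondary hits): half the total split equally as a floor so
    # no instrument degenerates, half by a flat Dirichlet draw.
    shares = 0.5 / j + 0.5 * rng.dirichlet(np.ones(j)) if j > 1 else np.ones(1)
    gamma = np.sqrt(config.exposure_r2_total * shares / het) * rng.choice([-1.0, 1.0], j)
    sigma_x = 1.0 / np.sqrt(het * config.n_exp)
    cf = config.case_fraction
    sigma_y = 1.0 / np.sqrt(het * config.n_out * cf * (1.0 - cf))
    alpha = _draw_pleiotropy(config, gamma, rng)

    beta_x = rng.normal(gamma, sigma_x)

    snp_ids = tuple(f"rs{1_000_001 + i}" for i in range(j))
    n_pal = int(round(config.palindromic_fraction * j))
    pal_mask = np.zeros(j, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(j, n_pal, replace=False)] = True
    pairs = [
        _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
        if pal_mask[i]
        else _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        for i in range(j)
    ]

    exposure = _stat_rows(snp_ids, pairs, maf, beta_x, sigma_x, config.n_exp)

    outcomes: list[list[SummaryStat]] = []
    outlier_index = None
    for _ in range(n_cohorts):
        beta_y = rng.normal(config.theta * gamma + alpha, sigma_y)
        if config.outlier_spec is not None:
            idx, offset = config.outlier_spec
            beta_y[idx] += offset * sigma_y[idx] * math.copysign(1.0, gamma[idx])
            outlier_index = idx
        flip_mask = rng.uniform(size=j) < config.flip_fraction
        swapped = [(oa, ea) if flip_mask[i] else (ea, oa)
                   for i, (ea, oa) in enumerate(pairs)]
        eaf_out = np.where(flip_mask, 1.0 - maf, maf)
        beta_out = np.where(flip_mask, -beta_y, beta_y)
        outcomes.append(
            _stat_rows(snp_ids, swapped, eaf_out, beta_out, sigma_y, config.n_out)
        )

    truth = TruthRecord(
        theta=config.theta,
        gamma=tuple(map(float, gamma)),
        alpha=tuple(map(float, alpha)),
        maf=tuple(map(float, maf)),
        sigma_x=tuple(map(float, sigma_x)),
        sigma_y=tuple(map(float, sigma_y)),
        snp_ids=snp_ids,
        outlier_index=outlier_index,
    )
    return exposure, outcomes, truth


def simulate_two_sample(
    config: SimConfig,
) -> tuple[list[SummaryStat], list[SummaryStat], TruthRecord]:
    """Generate one exposure GWAS, one outcome GWAS, and the truth record.

    Deterministic given ``config`` (including its seed): the same
    configuration always produces byte-identical collections. A configurable
    fraction of outcome rows is reported on the swapped effect allele (beta
    negated, EAF complemented) and a fraction of variants is made
    palindromic, so harmonization is exercised end to end.
    """
    exposure, outcomes, truth = simulate_multi_cohort(config, n_cohorts=1)
    return exposure, outcomes[0], truth


#: Instrument regimes of the absolute-level exposures studied in the source
#: design: (n_snps, total R², exposure GWAS n). Outcome defaults stay
#: biobank-like (420k samples, ~0.9% cases).
PAPER_LIKE_REGIMES: dict[str, tuple[int, float, int]] = {
    "alpha_tocopherol_like": (3, 0.017, 4_014),
    "ascorbate_like": (10, 0.017, 52_018),
    "retinol_like": (2, 0.023, 5_006),
    "beta_carotene_like": (2, 0.048, 2_344),
    "lycopene_like": (5, 0.301, 441),
    "urate_like": (27, 0.037, 110_347),
}


def make_paper_like_fixtures(
    theta: float = -0.25, base_seed: int = 20_220_808
) -> dict[str, tuple[list[SummaryStat], list[SummaryStat], TruthRecord]]:
    """One fixture per studied instrument regime, with fixed seeds.

    The SNP counts span every gate of the analysis pipeline: 2 SNPs restrict
    the method set to Wald/IVW/maximum likelihood, 3 adds Egger and the
    medians, and ≥ 4 adds MR-PRESSO.
    """
    fixtures = {}
    for k, (name, (n_snps, r2, n_exp)) in enumerate(sorted(PAPER_LIKE_REGIMES.items())):
        cfg = SimConfig(
            n_snps=n_snps,
            theta=theta,
            n_exp=n_exp,
            exposure_r2_total=r2,
            seed=base_seed + k,
        )
        fixtures[name] = simulate_two_sample(cfg)
    return fixtures
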