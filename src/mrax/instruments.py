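"""Instrument selection: significance thresholds, clumping, R² and F statistics.

A genetic instrument must be robustly associated with the exposure. Selection
here follows standard two-sample MR practice: genome-wide significance
(p < 5e-8 for absolute trait levels, relaxed to p < 1e-5 for metabolite
concentrations), greedy LD/distance clumping (r² <= 0.001 within 10,000 kb),
and removal of weak instruments (per-SNP F-statistic <= 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .summary_io import HarmonizedInstrument, SummaryStat

logger = logging.getLogger(__name__)

#: Default p-value thresholds per phenotype class.
P_THRESHOLDS = {"absolute": 5e-8, "metabolite": 1e-5}
DEFAULT_F_MIN = 10.0
DEFAULT_R2_MAX = 0.001
DEFAULT_WINDOW_KB = 10_000


class InstrumentError(ValueError):
    """Instrument selection failed (e.g. no variant survived the filters)."""


class NoValidInstrumentsError(InstrumentError):
    """Every candidate variant was removed; estimators must not run."""


def compute_r2(eaf: float, beta: float, se: float, n: float) -> float:
    """Proportion of exposure variance explained by one SNP.

    R² = 2·EAF·(1−EAF)·β² / [2·EAF·(1−EAF)·β² + 2·EAF·(1−EAF)·N·SE²],
    which simplifies to F/(F+N) with F = β²/SE². Requires 0 < eaf < 1; the
    allele-frequency factor cancels but a monomorphic variant is degenerate.
    """
    if not (0.0 < eaf < 1.0):
        raise InstrumentError(f"degenerate variant: eaf={eaf}")
    if se <= 0:
        raise InstrumentError("se must be positive")
    if n < 2:
        raise InstrumentError("sample size must be at least 2")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta * beta
    return num / (num + het * n * se * se)


def compute_f(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F-statistic, β²/SE²."""
    if se <= 0:
        raise InstrumentError("se must be positive")
    return (beta / se) ** 2


def select_instruments(
    stats: Sequence[SummaryStat],
    p_threshold: float | None = None,
    f_min: float = DEFAULT_F_MIN,
    phenotype_class: str = "absolute",
) -> list[SummaryStat]:
    """Retain variants with p < threshold and F > f_min (both strict).

    ``p_threshold`` defaults by ``phenotype_class`` (5e-8 absolute, 1e-5
    metabolite). Raises :class:`NoValidInstrumentsError` when nothing
    survives, so downstream estimators never run on an empty set.
    """
    if p_threshold is None:
        try:
            p_threshold = P_THRESHOLDS[phenotype_class]
        except KeyError:
            raise InstrumentError(
                f"unknown phenotype class {phenotype_class!r}; expected absolute/metabolite"
            ) from None
    kept: list[SummaryStat] = []
    n_p, n_weak = 0, 0
    for rec in stats:
        p = rec.pvalue
        if p is None or not (p < p_threshold):
            n_p += 1
            continue
        if not (compute_f(rec.beta, rec.se) > f_min):
            n_weak += 1
            logger.info("%s removed as weak instrument (F <= %g)", rec.snp_id, f_min)
            continue
        kept.append(rec)
    logger.info(
        "instrument selection: %d kept, %d failed p < %g, %d weak (F <= %g)",
        len(kept), n_p, p_threshold, n_weak, f_min,
    )
    if not kept:
        raise NoValidInstrumentsError(
            f"no valid instruments: {n_p} failed p < {p_threshold:g}, {n_weak} weak"
        )
    return kept


def clump_greedy(
    stats: Sequence[SummaryStat],
    positions: Mapping[str, tuple[str | int, int]] | None = None,
    ld: Mapping[frozenset, float] | None = None,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: int = DEFAULT_WINDOW_KB,
) -> list[SummaryStat]:
    """Greedy p-value clumping so retained instruments are near-independent.

    Candidates are visited in ascending p-value order (ties broken by snp_id,
    so the result is deterministic and independent of input row order). A
    candidate is removed when it lies within ``window_kb`` of an already-kept
    SNP on the same chromosome AND its pairwise r² with that SNP either
    exceeds ``r2_max`` or is unknown. Pairs with known r² <= r2_max are kept
    regardless of distance. A candidate with neither position nor any LD
    information is dropped conservatively with a warning.
    """
    def sort_key(rec: SummaryStat):
        p = rec.pvalue if rec.pvalue is not None else 1.0
        return (p, rec.snp_id)

    ld = ld or {}
    kept: list[SummaryStat] = []
    for cand in sorted(stats, key=sort_key):
        pos = positions.get(cand.snp_id) if positions else None
        removed = False
        for keep in kept:
            pair = frozenset((cand.snp_id, keep.snp_id))
            r2 = ld.get(pair)
            if r2 is not None:
                if r2 > r2_max:
                    removed = True
                    break
                continue  # known independence overrides distance
            kpos = positions.get(keep.snp_id) if positions else None
            if pos is None or kpos is None:
                logger.warning(
                    "clumping: no position or LD for pair (%s, %s); dropping %s",
                    cand.snp_id, keep.snp_id, cand.snp_id,
                )
                removed = True
                break
            if str(pos[0]) == str(kpos[0]) and abs(pos[1] - kpos[1]) <= window_kb * 1000:
                removed = True
                break
        if not removed:
            kept.append(cand)
    logger.info("clumping kept %d/%d variants", len(kept), len(stats))
    return kept


@dataclass(frozen=True)
class InstrumentSet:
    """A filtered, harmonized instrument collection for one exposure.

    ``r2_total`` is the summed per-SNP explained variance (a proportion);
    ``min_f`` the weakest retained instrument's F-statistic.
    """

    exposure_name: str
    phenotype_class: str
    unit_label: str
    instruments: tuple[HarmonizedInstrument, ...]
    r2_total: float
    min_f: float

    @property
    def r2_percent(self) -> float:
        """Explained variance as a percentage, one decimal."""
        return round(100.0 * self.r2_total, 1)


def build_instrument_set(
    exposure_name: str,
    instruments: Sequence[HarmonizedInstrument],
    exposure_n: float | None = None,
    phenotype_class: str = "absolute",
    unit_label: str = "",
) -> InstrumentSet:
    """Assemble an :class:`InstrumentSet`, computing R² totals and min F.

    R² contributions require EAF and exposure sample size; SNPs lacking either
    contribute 0 and are logged.
    """
    r2_total = 0.0
    min_f = float("inf")
    for h in instruments:
        if h.dropped:
            continue
        f = compute_f(h.beta_exp, h.se_exp)
        min_f = min(min_f, f)
        if h.eaf_exp is not None and exposure_n is not None and 0 < h.eaf_exp < 1:
            r2_total += compute_r2(h.eaf_exp, h.beta_exp, h.se_exp, exposure_n)
        else:
            logger.info("%s: missing EAF or N; R² contribution omitted", h.snp_id)
    return InstrumentSet(
        exposure_name=exposure_name,
        phenotype_class=phenotype_class,
        unit_label=unit_label,
        instruments=tuple(instruments),
        r2_total=min(r2_total, 1.0),
        min_f=0.0 if min_f == float("inf") else min_f,
    )


def scale_exposure(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument], factor: float
):
    """Rescale exposure units so causal estimates are reported per ``factor`` units.

    Multiplying each exposure beta and SE by 1/factor makes every downstream
    Wald ratio — and hence every estimator — scale by ``factor``: with
    factor=0.1 the reported OR is per 0.1 units of the exposure (e.g. per 10%
    increase of an ln-transformed trait). F-statistics and R² are unchanged
    (the scaling cancels in β/SE). Accepts either an :class:`InstrumentSet`
    (returned as a rescaled set) or a plain instrument sequence.
    """
    if not (factor > 0):
        raise InstrumentError("scale factor must be positive")
    if isinstance(instruments, InstrumentSet):
        return replace(
            instruments,
            instruments=tuple(scale_exposure(instruments.instruments, factor)),
        )
    if factor == 1.0:
        return list(instruments)
    return [
        replace(h, beta_exp=h.beta_exp / factor, se_exp=h.se_exp / factor)
        if not h.dropped else h
        for h in instruments
    ]
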