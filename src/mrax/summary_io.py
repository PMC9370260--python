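"""Reading, writing, and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-SNP association records from
an exposure GWAS and an outcome GWAS. Before any estimation, both effects must
refer to the same effect allele at every variant; this module performs that
harmonization, including sign-flipping swapped-allele records, resolving
strand-ambiguous (palindromic) variants by allele frequency, and substituting
user-supplied proxy variants for SNPs missing from the outcome GWAS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical output column order used by :func:`write_summary_stats`.
CANONICAL_COLUMNS = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

#: Default mapping from canonical header names to record roles.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "SNP": "snp_id",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
}

MANDATORY_ROLES = ("snp_id", "effect_allele", "other_allele", "beta", "se")


class SummaryStatError(ValueError):
    """Invalid or unusable summary-statistics input."""


class ColumnMapError(SummaryStatError):
    """A mandatory column role is not covered by the column map."""


@dataclass(frozen=True)
class SummaryStat:
    """One SNP's association record in one GWAS.

    ``beta`` is the additive per-effect-allele effect: a log odds ratio for a
    binary trait, trait units for a quantitative trait. ``eaf`` and ``n`` may
    be missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SummaryStatError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise SummaryStatError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryStatError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SummaryStatError(f"{self.snp_id}: se must be a positive finite number")
        if not math.isfinite(self.beta):
            raise SummaryStatError(f"{self.snp_id}: beta must be finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if self.n is not None and not (self.n > 0):
            raise SummaryStatError(f"{self.snp_id}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return self.other_allele == COMPLEMENT[self.effect_allele]

    def check_p_consistency(self, factor: float = 10.0) -> bool:
        """Check the reported p against the two-sided normal |beta/se| p.

        Returns True when consistent (within ``factor`` either way) or when no
        p-value is present; logs a warning otherwise. Never raises — reported
        p-values in published summary data frequently come from non-Wald tests.
        """
        if self.pvalue is None:
            return True
        implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if implied == 0.0:
            return True
        lo, hi = implied / factor, min(1.0, implied * factor)
        if not (lo <= self.pvalue <= hi):
            logger.warning(
                "%s: reported p=%.3g disagrees with |beta/se| normal p=%.3g",
                self.snp_id, self.pvalue, implied,
            )
            return False
        return True


#: Harmonization outcomes. Statuses beginning with ``dropped`` exclude the
#: record from all downstream estimation.
HARMONIZE_STATUSES = (
    "kept",
    "flipped",
    "palindromic_resolved",
    "dropped_palindromic",
    "dropped_missing",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP with exposure and outcome effects on the same effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    status: str = "kept"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in HARMONIZE_STATUSES:
            raise SummaryStatError(f"unknown harmonization status {self.status!r}")
        if not self.dropped and (self.se_exp <= 0 or self.se_out <= 0):
            raise SummaryStatError(f"{self.snp_id}: standard errors must be positive")

    @property
    def dropped(self) -> bool:
        return self.status.startswith("dropped")


def _coerce_float(value, allow_missing: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValueError("missing value")
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.upper() in {"NA", "NAN", "."}:
            if allow_missing:
                return None
            raise ValueError("missing value")
    return float(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[SummaryStat]:
    """Read one GWAS's summary statistics from a delimited text file.

    Parameters
    ----------
    path:
        TSV (default) or CSV file with a header row.
    column_map:
        Mapping from file column names to roles (``snp_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se`` mandatory; ``eaf``, ``pvalue``, ``n``
        optional). Defaults to the canonical SNP/EA/OA/EAF/BETA/SE/P/N header.
    delimiter:
        Field separator.

    Rows whose beta or se cannot be parsed, or that violate record invariants
    (e.g. se = 0), are skipped with a logged warning rather than aborting the
    read. A duplicated snp_id keeps the record with the smallest p-value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMN_MAP)
    roles = set(cmap.values())
    for role in MANDATORY_ROLES:
        if role not in roles:
            raise ColumnMapError(f"column map does not cover mandatory role {role!r}")

    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    if df.empty:
        raise SummaryStatError(f"{path}: no data rows")
    missing_cols = [c for c in cmap if c not in df.columns and cmap[c] in MANDATORY_ROLES]
    if missing_cols:
        raise ColumnMapError(f"{path}: mandatory column(s) {missing_cols} absent from header")

    role_to_col = {role: col for col, role in cmap.items() if col in df.columns}
    records: list[SummaryStat] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            rec = SummaryStat(
                snp_id=str(row[role_to_col["snp_id"]]).strip(),
                effect_allele=str(row[role_to_col["effect_allele"]]).strip().upper(),
                other_allele=str(row[role_to_col["other_allele"]]).strip().upper(),
                beta=_coerce_float(row[role_to_col["beta"]]),
                se=_coerce_float(row[role_to_col["se"]]),
                eaf=_coerce_float(row.get(role_to_col.get("eaf")), allow_missing=True)
                if "eaf" in role_to_col else None,
                pvalue=_coerce_float(row.get(role_to_col.get("pvalue")), allow_missing=True)
                if "pvalue" in role_to_col else None,
                n=_coerce_float(row.get(role_to_col.get("n")), allow_missing=True)
                if "n" in role_to_col else None,
            )
        except (ValueError, SummaryStatError) as exc:
            n_skipped += 1
            logger.warning("%s row %d skipped: %s", path.name, idx + 2, exc)
            continue
        rec.check_p_consistency()
        records.append(rec)
    if n_skipped:
        logger.warning("%s: skipped %d unparseable/invalid row(s)", path.name, n_skipped)
    return dedupe_by_pvalue(records)


def dedupe_by_pvalue(records: Sequence[SummaryStat]) -> list[SummaryStat]:
    """Collapse duplicated snp_ids, keeping the record with the smallest p.

    Records without a p-value rank last; the first occurrence wins ties.
    """
    best: dict[str, SummaryStat] = {}
    order: list[str] = []
    for rec in records:
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
            continue
        logger.warning("duplicated snp_id %s: keeping smallest p-value", rec.snp_id)
        old = best[rec.snp_id]
        old_p = old.pvalue if old.pvalue is not None else math.inf
        new_p = rec.pvalue if rec.pvalue is not None else math.inf
        if new_p < old_p:
            best[rec.snp_id] = rec
    return [best[s] for s in order]


def write_summary_stats(
    records: Sequence[SummaryStat],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write records in the canonical SNP/EA/OA/EAF/BETA/SE/P/N column order.

    A file written here and reread by :func:`read_summary_stats` reproduces
    the input collection. An empty collection produces a header-only file with
    a warning.
    """
    if not records:
        logger.warning("writing header-only summary-statistics file %s", path)
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pvalue for r in records],
            "N": [r.n for r in records],
        },
        columns=list(CANONICAL_COLUMNS),
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def apply_proxy_table(
    outcome: Sequence[SummaryStat],
    proxies: Mapping[str, str],
    exposure_ids: Iterable[str],
) -> list[SummaryStat]:
    """Substitute proxy variants for exposure SNPs missing from the outcome.

    ``proxies`` maps a missing exposure snp_id to a proxy snp_id expected to be
    in LD with it (the lookup against an LD reference is the user's
    responsibility). The proxy's outcome record is relabelled with the missing
    SNP's id so the downstream join succeeds; alleles are taken from the proxy
    record and harmonized as usual.
    """
    by_id = {r.snp_id: r for r in outcome}
    out = list(outcome)
    for missing_id in exposure_ids:
        if missing_id in by_id:
            continue
        proxy_id = proxies.get(missing_id)
        if proxy_id is None:
            continue
        proxy_rec = by_id.get(proxy_id)
        if proxy_rec is None:
            logger.warning("proxy %s for %s not found in outcome data", proxy_id, missing_id)
            continue
        logger.info("using proxy %s for missing outcome SNP %s", proxy_id, missing_id)
        out.append(replace(proxy_rec, snp_id=missing_id))
    return out


def _alleles(rec: SummaryStat) -> tuple[str, str]:
    return rec.effect_allele, rec.other_allele


def harmonize(
    exposure: Sequence[SummaryStat],
    outcome: Sequence[SummaryStat],
    palindromic_eaf_window: float = 0.08,
    proxies: Mapping[str, str] | None = None,
) -> list[HarmonizedInstrument]:
    """Join exposure and outcome records and align them on one effect allele.

    The join is an inner join on ``snp_id``. At each shared SNP the outcome
    record is reconciled to the exposure's effect allele:

    - identical allele pair: kept as-is;
    - swapped alleles (outcome EA = exposure OA): outcome beta negated,
      status ``flipped``;
    - strand-complemented pair (non-palindromic): treated as the same variant
      reported on the opposite strand, aligned with the same rules;
    - palindromic variants (A/T or C/G): the allele labels cannot distinguish
      strands, so the effect-allele frequencies must agree. When both EAFs are
      present and both lie outside ``[0.5 - window, 0.5 + window]``, the record
      is kept (sign-flipped if the frequencies sit on opposite sides of 0.5)
      with status ``palindromic_resolved``; otherwise ``dropped_palindromic``;
    - alleles irreconcilable by swap/complement, or SNP absent from the
      outcome: ``dropped_missing`` with the reason recorded.

    Dropped records are returned (for the audit trail) but carry a status
    beginning with ``dropped`` and are excluded from all estimation.
    """
    if not exposure or not outcome:
        raise SummaryStatError("harmonize requires non-empty exposure and outcome collections")
    exposure = dedupe_by_pvalue(exposure)
    outcome = dedupe_by_pvalue(outcome)
    if proxies:
        outcome = apply_proxy_table(outcome, proxies, [r.snp_id for r in exposure])
    out_by_id = {r.snp_id: r for r in outcome}

    result: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            logger.info("%s absent from outcome GWAS: excluded", exp.snp_id)
            result.append(
                HarmonizedInstrument(
                    snp_id=exp.snp_id, beta_exp=exp.beta, se_exp=exp.se,
                    beta_out=math.nan, se_out=math.nan, eaf_exp=exp.eaf,
                    status="dropped_missing", reason="absent from outcome",
                )
            )
            continue
        result.append(_harmonize_pair(exp, out, palindromic_eaf_window))
    n_usable = sum(not h.dropped for h in result)
    logger.info("harmonized %d/%d SNPs usable", n_usable, len(result))
    return result


def _harmonize_pair(
    exp: SummaryStat, out: SummaryStat, window: float
) -> HarmonizedInstrument:
    ea, oa = _alleles(exp)
    base = dict(snp_id=exp.snp_id, beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf)

    if exp.is_palindromic:
        if _alleles(out) not in {(ea, oa), (oa, ea)}:
            return HarmonizedInstrument(
                **base, beta_out=math.nan, se_out=math.nan,
                status="dropped_missing", reason="allele mismatch at palindromic SNP",
            )
        if exp.eaf is None or out.eaf is None:
            return HarmonizedInstrument(
                **base, beta_out=math.nan, se_out=math.nan,
                status="dropped_palindromic", reason="missing EAF at palindromic SNP",
            )
        # Express the outcome EAF on the exposure's effect allele before
        # comparing sides of 0.5; labels alone carry no strand information.
        out_eaf = out.eaf if _alleles(out) == (ea, oa) else 1.0 - out.eaf
        lo, hi = 0.5 - window, 0.5 + window
        if lo <= exp.eaf <= hi or lo <= out_eaf <= hi:
            return HarmonizedInstrument(
                **base, beta_out=math.nan, se_out=math.nan,
                status="dropped_palindromic", reason="EAF within ambiguity window of 0.5",
            )
        same_side = (exp.eaf < 0.5) == (out_eaf < 0.5)
        sign = 1.0 if same_side else -1.0
        raw_beta = out.beta if _alleles(out) == (ea, oa) else -out.beta
        return HarmonizedInstrument(
            **base, beta_out=sign * raw_beta, se_out=out.se, status="palindromic_resolved",
        )

    out_pair = _alleles(out)
    comp_pair = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if out_pair == (ea, oa) or comp_pair == (ea, oa):
        return HarmonizedInstrument(**base, beta_out=out.beta, se_out=out.se, status="kept")
    if out_pair == (oa, ea) or comp_pair == (oa, ea):
        return HarmonizedInstrument(**base, beta_out=-out.beta, se_out=out.se, status="flipped")
    return HarmonizedInstrument(
        **base, beta_out=math.nan, se_out=math.nan,
        status="dropped_missing",
        reason=f"alleles {out_pair[0]}/{out_pair[1]} irreconcilable with {ea}/{oa}",
    )


def usable(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The non-dropped subset, i.e. what estimators may consume."""
    return [h for h in instruments if not h.dropped]


def write_harmonized(
    instruments: Sequence[HarmonizedInstrument], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write harmonized instruments (including dropped ones) as delimited text."""
    df = pd.DataFrame(
        {
            "SNP": [h.snp_id for h in instruments],
            "BETA_EXP": [h.beta_exp for h in instruments],
            "SE_EXP": [h.se_exp for h in instruments],
            "BETA_OUT": [h.beta_out for h in instruments],
            "SE_OUT": [h.se_out for h in instruments],
            "EAF_EXP": [h.eaf_exp for h in instruments],
            "STATUS": [h.status for h in instruments],
            "REASON": [h.reason for h in instruments],
        }
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_harmonized(path: str | Path, delimiter: str = "\t") -> list[HarmonizedInstrument]:
    """Read a file written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep=delimiter)
    out = []
    for _, row in df.iterrows():
        out.append(
            HarmonizedInstrument(
                snp_id=str(row["SNP"]),
                beta_exp=float(row["BETA_EXP"]),
                se_exp=float(row["SE_EXP"]),
                beta_out=float(row["BETA_OUT"]),
                se_out=float(row["SE_OUT"]),
                eaf_exp=None if pd.isna(row.get("EAF_EXP")) else float(row["EAF_EXP"]),
                status=str(row["STATUS"]),
                reason="" if pd.isna(row.get("REASON")) else str(row["REASON"]),
            )
        )
    return out
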