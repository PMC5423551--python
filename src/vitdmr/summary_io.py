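"""GWAS summary-statistic records, TSV I/O, unit conversion and allele harmonization.

Summary associations are exchanged as tab-separated tables with a fixed
header vocabulary (``rsid``, ``effect_allele``, ``other_allele``, ``eaf``,
``beta``, ``se``, ``or``, ``ci_lower``, ``ci_upper``, ``p``, ``n``).  Binary
traits are stored internally on the log-odds scale; odds ratios and 95%
confidence intervals from published tables are converted on read with
:func:`beta_from_or` and :func:`se_from_ci`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

import pandas as pd
from scipy.stats import norm

from .errors import (
    HarmonizationError,
    ProxyError,
    SchemaError,
    StrandAmbiguityError,
    TableParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Scale = Literal["log_odds", "linear"]

#: Column order of the on-disk dialect.
TSV_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "or",
    "ci_lower",
    "ci_upper",
    "p",
    "n",
)

#: Strand-ambiguous allele pairs.
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}

#: EAF window in which a palindromic SNP cannot be resolved from frequency.
_AMBIGUOUS_EAF = (0.42, 0.58)


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(norm.ppf((1.0 + level) / 2.0))


def beta_from_or(odds_ratio: float) -> float:
    """Natural log of an odds ratio (log-odds effect size).

    Raises :class:`ValueError` for a non-positive odds ratio.
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def se_from_ci(lower: float, upper: float, level: float = 0.95,
               scale: Scale = "log_odds") -> float:
    """Recover a standard error from a symmetric confidence interval.

    For ``scale='log_odds'`` the bounds are odds ratios and the SE is
    ``(ln upper - ln lower) / (2 z)``; for ``scale='linear'`` it is
    ``(upper - lower) / (2 z)``, with ``z`` the standard-normal quantile
    at ``(1 + level) / 2``.
    """
    if lower >= upper:
        raise ValueError(f"CI bounds must satisfy lower < upper, got ({lower}, {upper})")
    z = _z(level)
    if scale == "log_odds":
        if lower <= 0:
            raise ValueError(f"odds-ratio CI bounds must be positive, got ({lower}, {upper})")
        return (math.log(upper) - math.log(lower)) / (2.0 * z)
    if scale == "linear":
        return (upper - lower) / (2.0 * z)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait in one study.

    ``beta`` is on the log-odds scale for binary traits (``scale='log_odds'``)
    and in trait units for continuous traits (``scale='linear'``).
    """

    rsid: str
    effect_allele: str
    beta: float
    se: float
    trait: str = ""
    scale: Scale = "log_odds"
    other_allele: Optional[str] = None
    eaf: Optional[float] = None
    p: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se is not None and self.se <= 0:
            raise ValidationError(f"{self.rsid}: se must be positive, got {self.se}")
        if self.p is not None and not 0.0 < self.p <= 1.0:
            raise ValidationError(f"{self.rsid}: p must be in (0, 1], got {self.p}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def odds_ratio(self) -> float:
        if self.scale != "log_odds":
            raise ValueError(f"{self.rsid}: trait is not on the log-odds scale")
        return math.exp(self.beta)


@dataclass
class StudyTable:
    """Ordered collection of :class:`SnpAssociation` from one study for one trait."""

    study_id: str
    trait: str
    records: list[SnpAssociation] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dup = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsid(s) in {self.study_id}: {', '.join(dup)}")
        scales = {r.scale for r in self.records}
        if len(scales) > 1:
            raise ValidationError(f"mixed effect scales in {self.study_id}: {scales}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return any(r.rsid == rsid for r in self.records)

    def get(self, rsid: str) -> SnpAssociation:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(f"rsid {rsid} not in table {self.study_id}")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations aligned to the same effect allele."""

    rsid: str
    exposure: SnpAssociation
    outcome: SnpAssociation
    flipped: bool

    def __post_init__(self) -> None:
        if self.exposure.effect_allele != self.outcome.effect_allele:
            raise ValidationError(
                f"{self.rsid}: harmonized pair must share the effect allele")


def _is_palindromic(a: str, b: Optional[str]) -> bool:
    return b is not None and frozenset((a.upper(), b.upper())) in _PALINDROMIC


def harmonize_pair(exposure: SnpAssociation, outcome: SnpAssociation) -> HarmonizedPair:
    """Align the outcome association to the exposure's effect allele.

    If the outcome reports the opposite allele, its effect sign is inverted
    and its allele frequency complemented.  Palindromic SNPs (A/T or C/G)
    whose frequencies on both sides sit near 0.5 cannot be strand-resolved
    and raise :class:`StrandAmbiguityError`.
    """
    if exposure.rsid != outcome.rsid:
        raise HarmonizationError(
            f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    if _is_palindromic(exposure.effect_allele, exposure.other_allele):
        lo, hi = _AMBIGUOUS_EAF
        if (exposure.eaf is not None and outcome.eaf is not None
                and lo < exposure.eaf < hi and lo < outcome.eaf < hi):
            raise StrandAmbiguityError(
                f"{exposure.rsid}: palindromic alleles with EAF near 0.5 on both sides")
    ea, oa = exposure.effect_allele.upper(), (exposure.other_allele or "").upper()
    out_ea = outcome.effect_allele.upper()
    if out_ea == ea:
        aligned = outcome if outcome.effect_allele == exposure.effect_allele else replace(
            outcome, effect_allele=exposure.effect_allele)
        return HarmonizedPair(exposure.rsid, exposure, aligned, flipped=False)
    if oa and out_ea == oa:
        flipped = replace(
            outcome,
            effect_allele=exposure.effect_allele,
            other_allele=outcome.effect_allele,
            beta=-outcome.beta,
            eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
        )
        return HarmonizedPair(exposure.rsid, exposure, flipped, flipped=True)
    raise HarmonizationError(
        f"{exposure.rsid}: allele sets incompatible "
        f"({ea}/{oa or '?'} vs {out_ea}/{outcome.other_allele or '?'})")


def _parse_cell(raw: object, row: int, column: str) -> Optional[float]:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in ("", "NA", "nan", "."):
        return None
    try:
        return float(text)
    except ValueError:
        raise TableParseError(
            f"row {row}: cannot parse {column}={text!r} as a number") from None


def read_summary_table(path, study_id: str, trait: str,
                       scale: Optional[Scale] = None,
                       level: float = 0.95) -> StudyTable:
    """Read a summary-statistics TSV into a :class:`StudyTable`.

    Effect sizes may be supplied as ``beta``/``se``, as ``or`` with
    ``ci_lower``/``ci_upper`` (converted to log-odds), or as ``beta`` with a
    linear-scale CI.  When both ``beta``/``se`` and OR/CI columns are filled,
    ``beta``/``se`` takes precedence and a warning is logged.  ``scale``
    defaults to ``log_odds`` when an ``or`` column is present, else ``linear``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for required in ("rsid", "effect_allele"):
        if required not in frame.columns:
            raise SchemaError(f"{path}: missing required column '{required}'")
    has = lambda c: c in frame.columns
    beta_se = has("beta") and has("se")
    or_ci = has("or") and has("ci_lower") and has("ci_upper")
    beta_ci = has("beta") and has("ci_lower") and has("ci_upper")
    if not (beta_se or or_ci or beta_ci):
        raise SchemaError(
            f"{path}: need columns (beta, se), (or, ci_lower, ci_upper) "
            "or (beta, ci_lower, ci_upper)")
    if scale is None:
        scale = "log_odds" if has("or") else "linear"

    records: list[SnpAssociation] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        cells = dict(zip(frame.columns, row))
        get = lambda c: _parse_cell(cells.get(c), i, c)
        beta, se = (get("beta"), get("se")) if beta_se else (None, None)
        if beta is not None and se is not None:
            if or_ci and get("or") is not None:
                logger.warning(
                    "%s row %d: both beta/se and OR/CI present; using beta/se", path, i)
        elif or_ci and get("or") is not None:
            beta = beta_from_or(get("or"))
            se = se_from_ci(get("ci_lower"), get("ci_upper"), level, "log_odds")
        elif has("beta") and get("beta") is not None and has("ci_lower"):
            beta = get("beta")
            se = se_from_ci(get("ci_lower"), get("ci_upper"), level, scale)
        else:
            raise TableParseError(f"row {i}: no usable effect columns")
        n_val = get("n")
        records.append(SnpAssociation(
            rsid=str(cells["rsid"]).strip(),
            effect_allele=str(cells["effect_allele"]).strip(),
            other_allele=(str(cells["other_allele"]).strip() or None)
            if has("other_allele") else None,
            eaf=get("eaf") if has("eaf") else None,
            beta=beta,
            se=se,
            p=get("p") if has("p") else None,
            n=int(n_val) if n_val is not None else None,
            trait=trait,
            scale=scale,
        ))
    return StudyTable(study_id=study_id, trait=trait, records=records)


def write_summary_table(table: StudyTable, path) -> None:
    """Write a :class:`StudyTable` in the package TSV dialect (beta/se columns)."""
    rows = []
    for r in table.records:
        rows.append({
            "rsid": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele if r.other_allele is not None else "",
            "eaf": r.eaf if r.eaf is not None else "",
            "beta": repr(r.beta),
            "se": repr(r.se),
            "or": "",
            "ci_lower": "",
            "ci_upper": "",
            "p": r.p if r.p is not None else "",
            "n": r.n if r.n is not None else "",
        })
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def substitute_proxy(table: StudyTable, target_rsid: str, proxy_rsid: str,
                     r2: float, min_r2: float = 1.0) -> StudyTable:
    """Relabel a proxy SNP's record with the rsid of an absent target SNP.

    Mirrors the common situation where a variant is missing from a genotyping
    panel and a variant in (near-)perfect LD stands in for it.  ``r2`` must be
    at least ``min_r2`` (default 1.0: perfect proxies only); the substitution
    is appended to the table's provenance log.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if r2 < min_r2:
        raise ProxyError(
            f"proxy {proxy_rsid} for {target_rsid} has r2={r2} < required {min_r2}")
    if proxy_rsid not in table:
        raise KeyError(f"proxy rsid {proxy_rsid} not present in table {table.study_id}")
    if target_rsid in table:
        raise ValidationError(
            f"target rsid {target_rsid} already present in table {table.study_id}")
    records = [replace(r, rsid=target_rsid) if r.rsid == proxy_rsid else r
               for r in table.records]
    return StudyTable(
        study_id=table.study_id,
        trait=table.trait,
        records=records,
        provenance=table.provenance + [
            f"substituted proxy {proxy_rsid} (r2={r2}) for {target_rsid}"],
    )


def harmonize_tables(exposure: Iterable[SnpAssociation],
                     outcome: StudyTable) -> list[HarmonizedPair]:
    """Harmonize every exposure record against the matching outcome record.

    Raises :class:`HarmonizationError` listing rsids absent from the outcome
    table.
    """
    missing = [e.rsid for e in exposure if e.rsid not in outcome]
    if missing:
        raise HarmonizationError(
            f"rsid(s) absent from outcome table {outcome.study_id}: {', '.join(missing)}")
    return [harmonize_pair(e, outcome.get(e.rsid)) for e in exposure]
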