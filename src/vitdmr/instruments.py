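"""Instrument validation: strength metrics, confounder screen, LD independence.

A valid Mendelian randomization instrument must be (i) strongly associated
with the exposure, (ii) unassociated with confounders of the exposure-outcome
relation, and (iii) independent of the other instruments (no linkage
disequilibrium).  This module quantifies each requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .errors import ValidationError

Pathway = Literal["synthesis", "metabolism"]

#: Gene-to-pathway map for the four 25OHD loci: DHCR7 (7-dehydrocholesterol
#: reductase) and CYP2R1 (hepatic 25-hydroxylase) act in vitamin D synthesis;
#: GC (vitamin D binding protein, transport) and CYP24A1 (catabolism) act in
#: metabolism of circulating 25OHD.
PATHWAYS: dict[str, Pathway] = {
    "DHCR7": "synthesis",
    "CYP2R1": "synthesis",
    "GC": "metabolism",
    "CYP24A1": "metabolism",
}


def classify_pathway(locus: str) -> Pathway:
    """Map a locus label to its vitamin D pathway (synthesis or metabolism)."""
    try:
        return PATHWAYS[locus]
    except KeyError:
        raise LookupError(
            f"unknown locus {locus!r}; expected one of {sorted(PATHWAYS)}") from None


def f_statistic(beta_x: float, se_x: float) -> float:
    """Instrument-strength F statistic, ``(beta_x / se_x) ** 2``."""
    if se_x <= 0:
        raise ValueError(f"se_x must be positive, got {se_x}")
    return (beta_x / se_x) ** 2


def r2_from_f(f: float, n: int) -> float:
    """Exposure variance explained implied by an F statistic: ``f / (f + n - 2)``."""
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    if f < 0:
        raise ValueError(f"F statistic must be nonnegative, got {f}")
    return f / (f + n - 2)


def f_from_r2(r2: float, n: int) -> float:
    """Inverse of :func:`r2_from_f`: ``r2 (n - 2) / (1 - r2)``."""
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass(frozen=True)
class ConfounderScreenEntry:
    rsid: str
    confounder: str
    p: float
    significant: bool


@dataclass(frozen=True)
class ConfounderScreenReport:
    """Bonferroni-corrected screen of instrument-confounder associations.

    An entry is flagged when ``p <= 0.05 / m`` (inclusive boundary) for ``m``
    instruments; the screen passes when no entry is flagged.
    """

    m: int
    threshold: float
    entries: tuple[ConfounderScreenEntry, ...]

    @property
    def passed(self) -> bool:
        return not any(e.significant for e in self.entries)


def confounder_screen(assocs: Iterable[tuple[str, str, float]],
                      m: int, alpha: float = 0.05) -> ConfounderScreenReport:
    """Screen (rsid, confounder, p) associations at the Bonferroni threshold alpha/m."""
    if m < 1:
        raise ValueError(f"number of instruments must be >= 1, got {m}")
    threshold = alpha / m
    entries = []
    for rsid, confounder, p in assocs:
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"{rsid}/{confounder}: p must be in (0, 1], got {p}")
        entries.append(ConfounderScreenEntry(rsid, confounder, p, p <= threshold))
    return ConfounderScreenReport(m=m, threshold=threshold, entries=tuple(entries))


@dataclass(frozen=True)
class LdPair:
    rsid_a: str
    rsid_b: str
    r2: float


@dataclass(frozen=True)
class LdReport:
    """Pairwise LD gate: instruments are independent iff all r² <= max_allowed."""

    pairs: tuple[LdPair, ...]
    max_allowed: float
    independent: bool

    @property
    def offending(self) -> tuple[LdPair, ...]:
        return tuple(p for p in self.pairs if p.r2 > self.max_allowed)


def ld_independence(pairs: Iterable[tuple[str, str, float]],
                    max_allowed: float = 0.01) -> LdReport:
    """Gate a set of instruments on user-supplied pairwise r² values.

    r² values come from reference panels; no genotype data is touched here.
    An empty pair list (a single instrument) is vacuously independent.
    """
    checked = []
    for a, b, r2 in pairs:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 for ({a}, {b}) must be in [0, 1], got {r2}")
        checked.append(LdPair(a, b, r2))
    independent = all(p.r2 <= max_allowed for p in checked)
    return LdReport(pairs=tuple(checked), max_allowed=max_allowed,
                    independent=independent)


def screen_from_frame(frame, m: Optional[int] = None) -> ConfounderScreenReport:
    """Run :func:`confounder_screen` on a DataFrame with rsid/confounder/p columns."""
    rows: Sequence = list(frame[["rsid", "confounder", "p"]].itertuples(index=False))
    if m is None:
        m = frame["rsid"].nunique()
    return confounder_screen([(r.rsid, r.confounder, float(r.p)) for r in rows], m=m)
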