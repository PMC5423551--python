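"""Loaders for the packaged summary-statistics tables.

The package ships the published per-SNP associations of the four 25OHD
instruments (rs10741657/CYP2R1, rs12785878/DHCR7, rs2282679/GC,
rs6013897/CYP24A1) with ln-25OHD and with each of the four outcomes, as
TSV files in the :mod:`vitdmr.summary_io` dialect.  Only the effect allele
was published; the stored other alleles are fixed non-palindromic
complements, and all tables are stored in a single consistent orientation
(noted in provenance), so harmonization is exercised without sign flips.

The stored exposure effects are per-allele effects on natural-log 25OHD;
their SEs were not published and, when needed for the second-order Wald SE,
are recovered from the published F statistics (F = (beta/se)²).

``confounders_synthetic.tsv`` and ``ld_pairs_synthetic.tsv`` are synthetic
stand-ins for report tables that were published only as summaries ("all BMI
p >= 0.29", "all pairwise r² <= 0.01"); their values respect those published
floors but are otherwise invented.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mr_core import Instrument
from .summary_io import StudyTable, read_summary_table

OUTCOMES = ("asthma", "childhood_asthma", "atopic_dermatitis", "ige")

_OUTCOME_FILES = {
    "asthma": ("table1_asthma.tsv", "UKB+GABRIEL", "log_odds"),
    "childhood_asthma": ("table1_childhood_asthma.tsv", "GABRIEL", "log_odds"),
    "atopic_dermatitis": ("table1_atopic_dermatitis.tsv", "EAGLE", "log_odds"),
    "ige": ("table1_ige.tsv", "GABRIEL", "linear"),
}

ORIENTATION_NOTE = (
    "other alleles are fixed non-palindromic complements of the published "
    "effect alleles; all tables share one orientation")


def _data_path(name: str):
    return resources.files("vitdmr.data") / name


def load_instruments() -> list[Instrument]:
    """The four 25OHD instruments with per-allele effects and strength metadata."""
    frame = pd.read_csv(_data_path("table1_exposure.tsv"), sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        f_stat = float(row.f_stat)
        out.append(Instrument(
            rsid=row.rsid, locus=row.locus, beta_x=float(row.beta),
            effect_allele=row.effect_allele, other_allele=row.other_allele,
            eaf=float(row.eaf), se_x=abs(float(row.beta)) / f_stat ** 0.5,
            p_x=float(row.p), f_stat=f_stat,
            variance_explained=float(row.variance_explained_pct) / 100.0))
    return out


def load_outcome_table(outcome: str) -> StudyTable:
    """Published per-SNP associations with one of the four outcomes."""
    try:
        filename, study_id, scale = _OUTCOME_FILES[outcome]
    except KeyError:
        raise LookupError(
            f"unknown outcome {outcome!r}; expected one of {OUTCOMES}") from None
    with resources.as_file(_data_path(filename)) as path:
        table = read_summary_table(path, study_id=study_id, trait=outcome,
                                   scale=scale)
    table.provenance.append(ORIENTATION_NOTE)
    return table


def load_outcomes() -> dict[str, StudyTable]:
    return {name: load_outcome_table(name) for name in OUTCOMES}


def load_confounder_screen_table() -> pd.DataFrame:
    """Synthetic stand-in confounder p-value table (rsid, confounder, p)."""
    return pd.read_csv(_data_path("confounders_synthetic.tsv"), sep="\t")


def load_ld_pairs() -> pd.DataFrame:
    """Synthetic stand-in pairwise LD table (rsid_a, rsid_b, r2)."""
    return pd.read_csv(_data_path("ld_pairs_synthetic.tsv"), sep="\t")
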