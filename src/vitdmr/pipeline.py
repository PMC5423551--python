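"""End-to-end orchestration of the MR study from the packaged fixture tables.

``run_study`` harmonizes the four instruments against each outcome table,
runs the estimator chain for the main analysis and the named sensitivity
subsets, and emits a report bundle: per-SNP association table, main MR table,
sensitivity table (with N/A cells where a subset does not apply to an
outcome), per-outcome forest-data tables, and a JSON provenance record.
Machine outputs are written unrounded; rounding is applied only in the
human-readable report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .errors import DesignError
from .mr_core import (
    DEFAULT_SIGMA,
    Instrument,
    MrEstimate,
    WaldMethod,
    WaldRatio,
    subset_analysis,
    wald_ratio,
)
from .summary_io import HarmonizedPair, StudyTable, harmonize_tables

_Z_NOTE = "z quantile 1.959963984540054 (standard normal, 95%)"

#: Sensitivity rows in report order and the outcomes each applies to.
#: A subset is reported as N/A for outcomes where no potential bias was
#: flagged for the excluded loci.
SENSITIVITY_LAYOUT: list[tuple[str, tuple[str, ...]]] = [
    ("exclude_DHCR7", ("asthma", "atopic_dermatitis", "ige")),
    ("synthesis_only", ("asthma", "atopic_dermatitis", "ige")),
    ("metabolism_only", ("asthma", "atopic_dermatitis", "ige")),
    ("exclude_CYP2R1_CYP24A1", ("asthma",)),
    ("exclude_CYP2R1", ("atopic_dermatitis", "ige")),
]


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    sigma: float = DEFAULT_SIGMA
    wald_method: WaldMethod = "first_order"
    level: float = 0.95
    outcomes: Sequence[str] = datasets.OUTCOMES
    out_dir: Optional[Path] = None
    report_decimals: int = 2
    fixture_paths: dict = field(default_factory=dict)  # outcome -> path override
    proxy_substitutions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)


@dataclass
class StudyReport:
    """In-memory result bundle of :func:`run_study`."""

    config: StudyConfig
    instruments: list[Instrument]
    pairs: dict[str, list[HarmonizedPair]]
    main: dict[str, MrEstimate]
    sensitivity: dict[tuple[str, str], Optional[MrEstimate]]
    snp_table: pd.DataFrame
    forest: dict[str, pd.DataFrame]
    provenance: dict


def _load_outcome(config: StudyConfig, outcome: str) -> StudyTable:
    if outcome in config.fixture_paths:
        from .summary_io import read_summary_table
        scale = "linear" if outcome == "ige" else "log_odds"
        return read_summary_table(config.fixture_paths[outcome],
                                  study_id=outcome, trait=outcome, scale=scale)
    return datasets.load_outcome_table(outcome)


def render_forest(ratios: Sequence[WaldRatio], pooled: MrEstimate,
                  instruments: Sequence[Instrument]) -> pd.DataFrame:
    """Forest-plot data: one row per SNP plus a fixed-effects summary row.

    Per-SNP estimates are rescaled to the per-SD-decrease reporting scale of
    the pooled estimate; IVW weights are normalized to percentages (they sum
    to 100 within 0.01).
    """
    if len(ratios) == 0:
        raise DesignError("forest table needs at least one per-SNP estimate")
    loci = {ins.rsid: ins.locus for ins in instruments}
    sigma, z = pooled.sigma, 1.959963984540054
    w = np.array([1.0 / r.se ** 2 for r in ratios])
    weights = 100.0 * w / w.sum()
    rows = []
    for r, pct in zip(ratios, weights):
        est = -sigma * r.estimate
        se = sigma * r.se
        rows.append({"rsid": r.rsid, "locus": loci.get(r.rsid, ""),
                     "estimate_per_sd_decrease": est,
                     "ci_lower": est - z * se, "ci_upper": est + z * se,
                     "or": math.exp(est) if pooled.or_scale else None,
                     "weight_pct": float(pct)})
    rows.append({"rsid": "summary", "locus": "fixed-effects",
                 "estimate_per_sd_decrease": pooled.estimate_per_sd_decrease,
                 "ci_lower": pooled.ci_lower, "ci_upper": pooled.ci_upper,
                 "or": pooled.odds_ratio if pooled.or_scale else None,
                 "weight_pct": 100.0})
    return pd.DataFrame(rows)


def run_study(config: Optional[StudyConfig] = None) -> StudyReport:
    """Run the whole MR study; optionally write the bundle to ``config.out_dir``."""
    config = config or StudyConfig()
    instruments = datasets.load_instruments()
    exposure_records = [ins.as_association() for ins in instruments]

    pairs: dict[str, list[HarmonizedPair]] = {}
    main: dict[str, MrEstimate] = {}
    forest: dict[str, pd.DataFrame] = {}
    snp_rows = []
    for outcome in config.outcomes:
        table = _load_outcome(config, outcome)
        for target, proxy, r2 in config.proxy_substitutions:
            from .summary_io import substitute_proxy
            table = substitute_proxy(table, target, proxy, r2)
        pairs[outcome] = harmonize_tables(exposure_records, table)
        main[outcome] = subset_analysis(
            pairs[outcome], instruments, "all", sigma=config.sigma,
            method=config.wald_method, level=config.level, outcome=outcome)
        by_rsid = {p.rsid: p for p in pairs[outcome]}
        ratios = [wald_ratio(by_rsid[ins.rsid], ins, config.wald_method)
                  for ins in instruments]
        forest[outcome] = render_forest(ratios, main[outcome], instruments)
        for ins in instruments:
            rec = by_rsid[ins.rsid].outcome
            snp_rows.append({
                "outcome": outcome, "rsid": ins.rsid, "locus": ins.locus,
                "effect_allele": rec.effect_allele, "beta": rec.beta,
                "se": rec.se, "p": rec.p, "n": rec.n, "scale": rec.scale})

    sensitivity: dict[tuple[str, str], Optional[MrEstimate]] = {}
    for subset, applicable in SENSITIVITY_LAYOUT:
        for outcome in ("asthma", "atopic_dermatitis", "ige"):
            if outcome not in config.outcomes:
                continue
            if outcome in applicable:
                sensitivity[(subset, outcome)] = subset_analysis(
                    pairs[outcome], instruments, subset, sigma=config.sigma,
                    method=config.wald_method, level=config.level,
                    outcome=outcome)
            else:
                sensitivity[(subset, outcome)] = None

    provenance = {
        "sigma": config.sigma,
        "sigma_note": ("SD of ln-25OHD; not identified from summary "
                       "statistics, calibrated against the pooled asthma "
                       "odds ratio"),
        "wald_method": config.wald_method,
        "z_quantile": _Z_NOTE,
        "orientation": datasets.ORIENTATION_NOTE,
        "proxy_substitutions": [list(p) for p in config.proxy_substitutions],
        "level": config.level,
    }
    report = StudyReport(config=config, instruments=instruments, pairs=pairs,
                         main=main, sensitivity=sensitivity,
                         snp_table=pd.DataFrame(snp_rows), forest=forest,
                         provenance=provenance)
    if config.out_dir is not None:
        write_bundle(report, Path(config.out_dir))
    return report


def main_results_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for outcome, est in report.main.items():
        rows.append({
            "outcome": outcome, "subset": est.subset, "k": est.k,
            "estimate_per_sd_decrease": est.estimate_per_sd_decrease,
            "se": est.se, "ci_lower": est.ci_lower, "ci_upper": est.ci_upper,
            "or": est.odds_ratio if est.or_scale else None,
            "or_ci_lower": est.or_ci[0] if est.or_scale else None,
            "or_ci_upper": est.or_ci[1] if est.or_scale else None,
            "p": est.p, "q": est.q, "i2": est.i2,
            "i2_ci_lower": est.i2_ci[0], "i2_ci_upper": est.i2_ci[1]})
    return pd.DataFrame(rows)


def sensitivity_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for (subset, outcome), est in report.sensitivity.items():
        if est is None:
            rows.append({"subset": subset, "outcome": outcome, "estimate": "N/A",
                         "ci_lower": "N/A", "ci_upper": "N/A", "p": "N/A"})
        else:
            reported = est.odds_ratio if est.or_scale else est.estimate_per_sd_decrease
            lo, hi = est.or_ci if est.or_scale else (est.ci_lower, est.ci_upper)
            rows.append({"subset": subset, "outcome": outcome,
                         "estimate": reported, "ci_lower": lo, "ci_upper": hi,
                         "p": est.p})
    return pd.DataFrame(rows)


def write_bundle(report: StudyReport, out_dir: Path) -> None:
    """Write the full report bundle (TSV + JSON + rounded text report)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    report.snp_table.to_csv(out_dir / "snp_associations.tsv", sep="\t", index=False)
    main_results_frame(report).to_csv(out_dir / "main_results.tsv", sep="\t",
                                      index=False)
    sensitivity_frame(report).to_csv(out_dir / "sensitivity_results.tsv",
                                     sep="\t", index=False)
    for outcome, frame in report.forest.items():
        frame.to_csv(out_dir / f"forest_{outcome}.tsv", sep="\t", index=False)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(human_report(report))


def human_report(report: StudyReport) -> str:
    """Rounded, human-readable study summary (2 decimals, I² in whole percent)."""
    d = report.config.report_decimals
    lines = ["MR estimates per SD decrease of ln-25OHD", ""]
    for outcome, est in report.main.items():
        if est.or_scale:
            val, (lo, hi) = est.odds_ratio, est.or_ci
            label = "OR"
        else:
            val, lo, hi = est.estimate_per_sd_decrease, est.ci_lower, est.ci_upper
            label = "beta"
        lines.append(
            f"{outcome}: {label} {val:.{d}f} (95% CI {lo:.{d}f} to {hi:.{d}f}), "
            f"p = {est.p:.{d}f}, I2 = {est.i2 * 100:.0f}% "
            f"({est.i2_ci[0] * 100:.0f}%-{est.i2_ci[1] * 100:.0f}%)")
    lines.append("")
    lines.append("Sensitivity analyses")
    for (subset, outcome), est in report.sensitivity.items():
        if est is None:
            lines.append(f"{outcome} [{subset}]: N/A")
        elif est.or_scale:
            lines.append(f"{outcome} [{subset}]: OR {est.odds_ratio:.{d}f} "
                         f"(95% CI {est.or_ci[0]:.{d}f} to {est.or_ci[1]:.{d}f}), "
                         f"p = {est.p:.{d}f}")
        else:
            lines.append(f"{outcome} [{subset}]: beta "
                         f"{est.estimate_per_sd_decrease:.{d}f} "
                         f"(95% CI {est.ci_lower:.{d}f} to {est.ci_upper:.{d}f}), "
                         f"p = {est.p:.{d}f}")
    return "\n".join(lines) + "\n"
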