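"""Generative model for the assumed causal structure of the MR design.

Simulates individual-level cohorts under the directed-acyclic-graph that a
two-sample MR study of 25OHD assumes: four independent biallelic loci affect
natural-log 25OHD additively; a latent confounder may affect both the
exposure and the outcome; the standardized exposure affects a binary outcome
through a logistic model (or a continuous outcome linearly); and optional
direct SNP-to-outcome (pleiotropic) effects bypass the exposure.  From a
cohort, non-overlapping sub-samples yield exposure- and outcome-side GWAS
summary statistics in the :mod:`vitdmr.summary_io` schema, so the whole
estimator chain can be exercised and calibrated without external data.

Defaults mirror the four 25OHD loci: allele frequencies (0.62, 0.27, 0.30,
0.19), per-allele effects on ln-25OHD (-0.052, -0.056, -0.047, -0.027) and a
residual SD of 0.47 log-units.  Loci are simulated without LD (the real
instruments have all pairwise r² <= 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import ConvergenceError, DesignError, ValidationError
from .mr_core import Instrument, ivw_pool, two_sided_p, wald_ratio
from .summary_io import HarmonizedPair, SnpAssociation, StudyTable

_DEFAULT_LOCI = ("CYP2R1", "DHCR7", "GC", "CYP24A1")
_DEFAULT_RSIDS = ("rs10741657", "rs12785878", "rs2282679", "rs6013897")
_DEFAULT_EAF = (0.62, 0.27, 0.30, 0.19)
_DEFAULT_BETA_X = (-0.052, -0.056, -0.047, -0.027)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    ``theta`` is the causal effect of the exposure per population SD of
    ln-25OHD (log-odds for a binary outcome, linear units for a continuous
    one).  ``confounder_effects = (gamma, delta)`` are the effects of a
    standard-normal confounder on the exposure and the outcome;
    ``pleiotropy`` holds per-allele direct effects on the outcome.
    """

    n_individuals: int = 20000
    eaf: tuple[float, ...] = _DEFAULT_EAF
    beta_x: tuple[float, ...] = _DEFAULT_BETA_X
    sigma_resid: float = 0.47
    theta: float = 0.0
    confounder_effects: tuple[float, float] = (0.0, 0.0)
    pleiotropy: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    prevalence: float = 0.17
    outcome_type: Literal["binary", "continuous"] = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.eaf) != len(self.beta_x) or len(self.eaf) != len(self.pleiotropy):
            raise ValidationError("eaf, beta_x and pleiotropy must have equal length")
        if not all(0.0 < f < 1.0 for f in self.eaf):
            raise ValidationError("allele frequencies must be in (0, 1)")
        if self.sigma_resid <= 0:
            raise ValidationError("sigma_resid must be positive")
        if self.outcome_type == "binary" and not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must be in (0, 1)")

    @property
    def n_snps(self) -> int:
        return len(self.eaf)

    def exposure_sd(self) -> float:
        """Population SD of the exposure implied by the model."""
        gamma = self.confounder_effects[0]
        genetic = sum(b * b * 2.0 * f * (1.0 - f)
                      for b, f in zip(self.beta_x, self.eaf))
        return math.sqrt(genetic + gamma ** 2 + self.sigma_resid ** 2)

    def exposure_mean(self) -> float:
        return sum(2.0 * f * b for b, f in zip(self.beta_x, self.eaf))


@dataclass
class SimCohort:
    """Individual-level data produced by :func:`simulate_cohort`."""

    config: SimConfig
    genotypes: np.ndarray       # n x m allele counts in {0, 1, 2}
    confounder: np.ndarray      # n
    exposure: np.ndarray        # n, ln-25OHD
    outcome: np.ndarray         # n, {0,1} or real
    rsids: tuple[str, ...] = _DEFAULT_RSIDS

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        if not (len(self.confounder) == len(self.exposure) == len(self.outcome) == n):
            raise ValidationError("cohort arrays have inconsistent lengths")


_HERMITE_NODES, _HERMITE_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_HERMITE_WEIGHTS = _HERMITE_WEIGHTS / math.sqrt(2.0 * math.pi)
_intercept_cache: dict[tuple, float] = {}


def _solve_intercept(config: SimConfig) -> float:
    """Logistic intercept matching the population prevalence to 1e-8.

    Conditional on a genotype configuration the linear predictor (minus the
    intercept) is Gaussian, so the population mean of the logistic response
    is an exact mixture over the 3^m genotype configurations, each integrated
    with Gauss-Hermite quadrature; the intercept is found by bracketed root
    finding.
    """
    key = (config.eaf, config.beta_x, config.sigma_resid, config.theta,
           config.confounder_effects, config.pleiotropy, config.prevalence)
    if key in _intercept_cache:
        return _intercept_cache[key]
    gamma, delta = config.confounder_effects
    mu, sd = config.exposure_mean(), config.exposure_sd()
    scale = config.theta / sd
    # per-genotype-configuration mean of the linear predictor
    counts = np.array(np.meshgrid(*[[0, 1, 2]] * config.n_snps,
                                  indexing="ij")).reshape(config.n_snps, -1).T
    probs = np.ones(len(counts))
    for j, f in enumerate(config.eaf):
        pj = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
        probs *= pj[counts[:, j]]
    m_g = scale * (counts @ np.array(config.beta_x) - mu) \
        + counts @ np.array(config.pleiotropy)
    # Gaussian part: (theta/sd) * (gamma C + eps) + delta C
    s = math.hypot(scale * gamma + delta, scale * config.sigma_resid)

    def mean_response(alpha: float) -> float:
        lp = alpha + m_g[:, None] + s * _HERMITE_NODES[None, :]
        return float(probs @ (expit(lp) @ _HERMITE_WEIGHTS))

    base = logit(config.prevalence)
    lo, hi = base - 1.0, base + 1.0
    for _ in range(60):
        if mean_response(lo) < config.prevalence < mean_response(hi):
            break
        lo -= 2.0
        hi += 2.0
    else:
        raise ConvergenceError("could not bracket the prevalence intercept")
    alpha = brentq(lambda a: mean_response(a) - config.prevalence, lo, hi,
                   xtol=1e-10)
    if abs(mean_response(alpha) - config.prevalence) > 1e-8:
        raise ConvergenceError("prevalence intercept solve did not converge")
    _intercept_cache[key] = alpha
    return alpha


def simulate_cohort(config: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> SimCohort:
    """Draw one cohort from the generative model.

    Genotypes are independent Binomial(2, EAF) counts; the confounder is
    standard normal; exposure = sum(beta_x * g) + gamma*C + eps with
    eps ~ N(0, sigma_resid²).  Binary outcomes follow a logistic model on the
    population-standardized exposure with the intercept solved so that the
    population prevalence matches the configuration; continuous outcomes add
    unit-variance Gaussian noise.  Fully reproducible from ``config.seed``
    (or an explicitly passed generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    genotypes = rng.binomial(2, np.array(config.eaf), size=(n, m)).astype(np.int8)
    confounder = rng.standard_normal(n)
    gamma, delta = config.confounder_effects
    exposure = (genotypes @ np.array(config.beta_x) + gamma * confounder
                + config.sigma_resid * rng.standard_normal(n))
    x_std = (exposure - config.exposure_mean()) / config.exposure_sd()
    direct = genotypes @ np.array(config.pleiotropy)
    if config.outcome_type == "binary":
        alpha = _solve_intercept(config)
        p = expit(alpha + config.theta * x_std + delta * confounder + direct)
        outcome = (rng.random(n) < p).astype(np.int8)
    else:
        outcome = (config.theta * x_std + delta * confounder + direct
                   + rng.standard_normal(n))
    return SimCohort(config=config, genotypes=genotypes, confounder=confounder,
                     exposure=exposure, outcome=outcome)


def _ols_per_snp(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope, SE and p of y on one genotype column."""
    n = len(g)
    gc = g - g.mean()
    ss = float(gc @ gc)
    slope = float(gc @ y) / ss
    resid = y - y.mean() - slope * gc
    se = math.sqrt(float(resid @ resid) / (n - 2) / ss)
    return slope, se, two_sided_p(slope, se)


def _logistic_per_snp(g: np.ndarray, y: np.ndarray,
                      max_iter: int = 40, tol: float = 1e-10
                      ) -> tuple[float, float, float]:
    """Newton-Raphson logistic regression of y on [1, g]; slope, SE, p.

    Two-parameter fit written out explicitly for speed inside replicated
    experiments; cross-checked against statsmodels in the test suite.
    """
    ybar = min(max(float(y.mean()), 1e-12), 1 - 1e-12)
    b0, b1 = logit(ybar), 0.0
    for _ in range(max_iter):
        p = expit(b0 + b1 * g)
        w = p * (1.0 - p)
        r = y - p
        s0, s1 = float(r.sum()), float(r @ g)
        i00, i01 = float(w.sum()), float(w @ g)
        i11 = float(w @ (g * g))
        det = i00 * i11 - i01 * i01
        if det <= 0:
            raise ConvergenceError("singular information matrix in logistic fit")
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        b0 += d0
        b1 += d1
        if abs(d0) + abs(d1) < tol:
            break
    else:
        raise ConvergenceError("logistic regression did not converge")
    p = expit(b0 + b1 * g)
    w = p * (1.0 - p)
    i00, i01 = float(w.sum()), float(w @ g)
    i11 = float(w @ (g * g))
    se = math.sqrt(i00 / (i00 * i11 - i01 * i01))
    return b1, se, two_sided_p(b1, se)


def summarize_gwas(cohort: SimCohort,
                   split_a: np.ndarray,
                   split_b: np.ndarray) -> tuple[StudyTable, StudyTable]:
    """Two-sample GWAS summaries: exposure associations from sample A, outcome
    associations from sample B.

    The index sets must be disjoint, emulating non-overlapping discovery
    cohorts.  Monomorphic SNPs within a split are dropped with a warning.
    """
    a = np.asarray(split_a)
    b = np.asarray(split_b)
    if a.size == 0 or b.size == 0:
        raise DesignError("both splits must be non-empty")
    if np.intersect1d(a, b).size > 0:
        raise DesignError("two-sample splits overlap")
    cfg = cohort.config
    binary = cfg.outcome_type == "binary"
    exp_records, out_records = [], []
    log = logging.getLogger(__name__)
    for j, rsid in enumerate(cohort.rsids):
        ga, gb = cohort.genotypes[a, j].astype(float), cohort.genotypes[b, j].astype(float)
        if ga.std() == 0 or gb.std() == 0:
            log.warning("SNP %s monomorphic in a split; dropped", rsid)
            continue
        bx, sx, px = _ols_per_snp(ga, cohort.exposure[a])
        exp_records.append(SnpAssociation(
            rsid=rsid, effect_allele="A1", other_allele="A2",
            eaf=float(ga.mean() / 2.0), beta=bx, se=sx, p=max(px, 5e-324),
            n=len(a), trait="ln_25OHD", scale="linear"))
        y = cohort.outcome[b].astype(float)
        if binary:
            by, sy, py = _logistic_per_snp(gb, y)
        else:
            by, sy, py = _ols_per_snp(gb, y)
        out_records.append(SnpAssociation(
            rsid=rsid, effect_allele="A1", other_allele="A2",
            eaf=float(gb.mean() / 2.0), beta=by, se=sy, p=max(py, 5e-324),
            n=len(b), trait="outcome",
            scale="log_odds" if binary else "linear"))
    return (StudyTable("sim_exposure", "ln_25OHD", exp_records),
            StudyTable("sim_outcome", "outcome", out_records))


def halves(n: int) -> tuple[np.ndarray, np.ndarray]:
    """First-half / second-half two-sample split of a cohort of size n."""
    idx = np.arange(n)
    return idx[: n // 2], idx[n // 2:]


def mr_from_summaries(exposure: StudyTable, outcome: StudyTable,
                      sigma: float) -> tuple[float, float]:
    """Pooled per-SD MR estimate (per SD *increase* of exposure) and SE.

    Convenience for experiments: builds Wald ratios from simulated summary
    tables and pools them; the per-unit estimate is scaled by ``sigma``.
    """
    ratios = []
    for pos, rec in enumerate(exposure.records):
        if rec.rsid not in outcome:
            continue
        locus = (_DEFAULT_LOCI[_DEFAULT_RSIDS.index(rec.rsid)]
                 if rec.rsid in _DEFAULT_RSIDS
                 else _DEFAULT_LOCI[pos % len(_DEFAULT_LOCI)])
        ins = Instrument(rsid=rec.rsid, locus=locus, beta_x=rec.beta,
                         se_x=rec.se, effect_allele=rec.effect_allele,
                         other_allele=rec.other_allele, eaf=rec.eaf)
        pair = HarmonizedPair(rec.rsid, rec, outcome.get(rec.rsid), flipped=False)
        ratios.append(wald_ratio(pair, ins))
    est, se = ivw_pool(ratios)
    return est * sigma, se * sigma


def observational_estimate(cohort: SimCohort) -> tuple[float, float]:
    """Naive regression of the outcome on the standardized exposure.

    Deliberately unadjusted for the confounder: the contrast between this
    estimate and the MR estimate demonstrates confounding bias.  Logistic for
    binary outcomes, OLS for continuous ones; returns (beta per SD, SE).
    """
    cfg = cohort.config
    x = (cohort.exposure - cohort.exposure.mean()) / cohort.exposure.std()
    y = cohort.outcome.astype(float)
    if cfg.outcome_type == "binary":
        b, se, _ = _logistic_per_snp(x, y)
    else:
        b, se, _ = _ols_per_snp(x, y)
    return b, se


def run_experiment(grid: Sequence[SimConfig], replicates: int, seed: int,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Replicated simulation experiment over a grid of configurations.

    For each configuration cell: simulate a cohort, form the two-sample
    split, compute the MR estimate per SD of exposure, and record the
    empirical rejection rate of the null (two-sided, level ``alpha``), mean
    and SD of the estimates, and coverage of the 95% CI for the true theta.
    Deterministic given ``seed``: per-replicate generators are spawned from a
    single ``numpy.random.SeedSequence``.
    """
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    root = np.random.SeedSequence(seed)
    z95 = float(norm.ppf(0.975))
    rows = []
    for cell, cfg in enumerate(grid):
        streams = root.spawn(replicates)
        ests, ses = np.empty(replicates), np.empty(replicates)
        for r in range(replicates):
            rng = np.random.default_rng(streams[r])
            cohort = simulate_cohort(cfg, rng=rng)
            a, b = halves(cfg.n_individuals)
            exp_tab, out_tab = summarize_gwas(cohort, a, b)
            sigma_hat = float(cohort.exposure[a].std(ddof=1))
            ests[r], ses[r] = mr_from_summaries(exp_tab, out_tab, sigma_hat)
        reject = np.mean(np.abs(ests / ses) > float(norm.ppf(1 - alpha / 2)))
        cover = np.mean((ests - z95 * ses <= cfg.theta)
                        & (cfg.theta <= ests + z95 * ses))
        rows.append({
            "cell": cell, "theta": cfg.theta, "n": cfg.n_individuals,
            "replicates": replicates, "reject_rate": float(reject),
            "mean_est": float(ests.mean()),
            "sd_est": float(ests.std(ddof=1)) if replicates > 1 else 0.0,
            "coverage": float(cover),
        })
    return pd.DataFrame(rows)


def monte_carlo_power(n: int, r2: float, effect: float, alpha: float = 0.05,
                      replicates: int = 10000, seed: int = 0,
                      chunk: int = 500) -> float:
    """Simulation oracle for the analytic power formula (continuous outcome).

    Per replicate: draw a standardized instrument score ``s``, the exposure
    ``x = sqrt(r2) s + sqrt(1-r2) e``, the outcome ``y = effect*x + noise``,
    regress ``y`` on ``s`` and apply the two-sided Wald test; returns the
    empirical rejection rate.  The noise is scaled so that the residual SD of
    the outcome *given the instrument* is one — the unit in which the
    analytic formula's effect parameter is expressed.
    """
    rng = np.random.default_rng(seed)
    zcrit = float(norm.ppf(1 - alpha / 2))
    noise_sd = math.sqrt(max(1.0 - effect ** 2 * (1.0 - r2), 1e-12))
    rejected = 0
    done = 0
    while done < replicates:
        reps = min(chunk, replicates - done)
        s = rng.standard_normal((reps, n))
        x = math.sqrt(r2) * s + math.sqrt(1 - r2) * rng.standard_normal((reps, n))
        y = effect * x + noise_sd * rng.standard_normal((reps, n))
        sc = s - s.mean(axis=1, keepdims=True)
        ss = np.einsum("ij,ij->i", sc, sc)
        slope = np.einsum("ij,ij->i", sc, y) / ss
        resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * sc
        se = np.sqrt(np.einsum("ij,ij->i", resid, resid) / (n - 2) / ss)
        rejected += int(np.sum(np.abs(slope / se) > zcrit))
        done += reps
    return rejected / replicates


def decreasing_allele_score_slope(cohort: SimCohort) -> tuple[float, float, float]:
    """Regression of the exposure on the count of exposure-decreasing alleles.

    Mirrors the classical allele-score check that carrying more
    25OHD-decreasing alleles lowers measured 25OHD; returns (slope, se, p).
    """
    signs = np.sign(cohort.config.beta_x)
    score = cohort.genotypes @ np.where(np.array(signs) < 0, 1.0, -1.0)
    return _ols_per_snp(score.astype(float), cohort.exposure)
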