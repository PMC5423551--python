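"""Analytic power and minimal-detectable-effect calculations for MR studies.

Uses the standard normal approximation for the two-sided Wald test of the IVW
estimate: with outcome sample size ``n``, instrument R² on the exposure, and a
true effect ``b`` per SD of exposure, the non-centrality parameter is

    NCP = n · R² · b²                      (variant='plain')
    NCP = n · R² · b² · K · (1 - K)        (variant='case_control_scaled')

where ``K`` is the case fraction, and

    power = Φ(√NCP - z_{1-α/2}) + Φ(-√NCP - z_{1-α/2}).

The case-control scaling reflects that for a binary outcome analysed by
logistic regression the effective information per subject is proportional to
``K(1-K)``.  Both variants are exposed because published power statements for
binary outcomes rarely pin down which scaling was used; ``plain`` is the
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConvergenceError

OutcomeType = Literal["binary", "continuous"]
NcpVariant = Literal["plain", "case_control_scaled"]


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of one MR power calculation.

    ``effect`` is the true causal effect per SD of the exposure: a log-odds
    ratio for binary outcomes, a linear beta for continuous ones.  ``r2`` is
    the fraction of exposure variance explained by the instrument set.
    """

    n: int
    r2: float
    effect: float
    alpha: float = 0.05
    outcome_type: OutcomeType = "binary"
    case_fraction: Optional[float] = None
    variant: NcpVariant = "plain"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be positive, got {self.n}")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError(f"r2 must be in (0, 1), got {self.r2}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.outcome_type == "binary" and self.case_fraction is not None:
            if not 0.0 < self.case_fraction < 1.0:
                raise ValueError(
                    f"case_fraction must be in (0, 1), got {self.case_fraction}")
        if self.variant == "case_control_scaled" and self.case_fraction is None:
            raise ValueError("case_control_scaled variant requires case_fraction")


def _ncp(spec: PowerSpec) -> float:
    ncp = spec.n * spec.r2 * spec.effect ** 2
    if spec.variant == "case_control_scaled":
        ncp *= spec.case_fraction * (1.0 - spec.case_fraction)
    return ncp


def mr_power(spec: PowerSpec) -> float:
    """Two-sided power of the MR Wald test under ``spec``.

    Symmetric in the sign of the effect; equals ``alpha`` at effect 0 and
    tends to 1 as the non-centrality parameter grows.
    """
    ncp = _ncp(spec)
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    root = math.sqrt(ncp)
    return float(norm.cdf(root - z) + norm.cdf(-root - z))


def minimal_detectable_effect(n: int, r2: float, alpha: float = 0.05,
                              target_power: float = 0.8,
                              outcome_type: OutcomeType = "binary",
                              case_fraction: Optional[float] = None,
                              variant: NcpVariant = "plain") -> float:
    """Smallest |effect| per SD of exposure reaching ``target_power``.

    Solved by root bisection on :func:`mr_power` to 1e-10.  For binary
    outcomes the result is a log-odds ratio; ``exp`` of it gives the
    minimal detectable OR.
    """
    spec = PowerSpec(n=n, r2=r2, effect=0.0, alpha=alpha,
                     outcome_type=outcome_type, case_fraction=case_fraction,
                     variant=variant)
    if not alpha < target_power < 1.0:
        raise ValueError(
            f"target power must be in (alpha, 1), got {target_power}")
    f = lambda e: mr_power(replace(spec, effect=e)) - target_power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ConvergenceError("target power unattainable at any effect size")
    return float(brentq(f, 0.0, hi, xtol=1e-10))


#: The four outcome configurations of the study: outcome label -> (n, case fraction).
STUDY_POWER_CONFIGS: dict[str, tuple[int, Optional[float]]] = {
    "asthma": (144243, 25471 / 146761),
    "childhood_asthma": (15008, 7047 / 15008),
    "atopic_dermatitis": (40835, 10788 / 40835),
    "ige": (12853, None),
}

#: Default instrument R²: sum of the per-SNP variance explained in ln-25OHD
#: (0.13% + 0.12% + 0.09% + 0.02%).
DEFAULT_INSTRUMENT_R2 = 0.0036


def study_power_table(r2: float = DEFAULT_INSTRUMENT_R2, alpha: float = 0.05,
                      target_power: float = 0.8,
                      variant: NcpVariant = "plain") -> list[dict]:
    """Power summary for the four study configurations.

    For each outcome: power to detect a reference effect (OR 1.6 for asthma
    outcomes, OR 1.5 for atopic dermatitis, beta -0.43 for log-IgE) and the
    minimal detectable effect at ``target_power``.
    """
    reference = {"asthma": math.log(1.6), "childhood_asthma": math.log(1.6),
                 "atopic_dermatitis": math.log(1.5), "ige": -0.43}
    rows = []
    for outcome, (n, case_fraction) in STUDY_POWER_CONFIGS.items():
        binary = outcome != "ige"
        spec = PowerSpec(n=n, r2=r2, effect=reference[outcome], alpha=alpha,
                         outcome_type="binary" if binary else "continuous",
                         case_fraction=case_fraction if binary else None,
                         variant=variant)
        mde = minimal_detectable_effect(
            n, r2, alpha, target_power,
            "binary" if binary else "continuous",
            case_fraction if binary else None, variant)
        rows.append({
            "outcome": outcome, "n": n, "r2": r2,
            "reference_effect": reference[outcome],
            "power_at_reference": mr_power(spec),
            "minimal_detectable_effect": mde,
            "minimal_detectable_or": math.exp(mde) if binary else None,
        })
    return rows
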