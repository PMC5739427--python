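"""Expected accuracy and power of genomic prediction for a single reference.

Quantitative traits use the classic SNP-BLUP reliability

    r^2(g, ghat) = b h^2 / (b h^2 + Me / N)

where ``h^2`` is the heritability, ``N`` the number of phenotyped reference
records, ``Me`` the effective number of chromosome segments and
``b = M / (Me + M)`` the fraction of QTL variance captured by the marker
panel.  The accuracy of predicting a future phenotype is ``h * r(g, ghat)``.

Binary (disease) traits are handled on the liability threshold model: with
population prevalence ``K``, case fraction ``P`` in the reference, and ``z``
the standard-normal density at the liability threshold,

    r^2(u, uhat) = h^2 z^2 / ( h^2 z^2 + [K(1-K)]^2 Me / [P(1-P) N] ).

Power of detecting association between the genomic predictor and the outcome
in a target set of size ``N_T`` uses the non-centrality parameter
``NCP = N_T r^2 / (1 - r^2)`` (or an odds-ratio form for case-control risk
stratification) plugged into a normal-approximation two-sided test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .theory import b_captured

__all__ = [
    "TraitModel",
    "PredictionSetting",
    "PowerSetting",
    "reliability_gbv",
    "accuracy_gbv",
    "accuracy_phenotype",
    "reliability_binary",
    "ncp_quantitative",
    "ncp_case_control_or",
    "power",
]


class ConfigurationError(ValueError):
    """A parameter set is incomplete or internally inconsistent."""


@dataclass(frozen=True)
class TraitModel:
    """Trait genetic architecture: heritability plus, for binary traits,
    population prevalence K and reference case fraction P.

    For binary traits the heritability is on the liability scale.  The
    threshold density z is always recomputed from K (never user-supplied).
    """

    heritability: float
    prevalence: Optional[float] = None
    case_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError(f"heritability must be in [0, 1], got {self.heritability}")
        for name, val in (("prevalence", self.prevalence), ("case_fraction", self.case_fraction)):
            if val is not None and not (0.0 < val < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {val}")

    @property
    def is_binary(self) -> bool:
        return self.prevalence is not None or self.case_fraction is not None

    @property
    def threshold_density(self) -> float:
        """Standard-normal density z at the liability threshold Phi^-1(1-K)."""
        if self.prevalence is None:
            raise ConfigurationError("threshold_density requires a prevalence (binary trait)")
        return float(stats.norm.pdf(stats.norm.isf(self.prevalence)))


@dataclass(frozen=True)
class PredictionSetting:
    """One reference cohort's prediction design: Me, record count, marker
    count (None = saturating panel, b = 1) and the trait."""

    me: float
    n_records: int
    trait: TraitModel
    n_markers: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.me > 0:
            raise ValueError(f"me must be positive, got {self.me}")
        if self.n_records < 1:
            raise ValueError(f"n_records must be >= 1, got {self.n_records}")

    @property
    def b(self) -> float:
        if self.n_markers is None:
            return 1.0
        return b_captured(self.n_markers, self.me)


def reliability_gbv(setting: PredictionSetting) -> float:
    """Reliability r^2(g, ghat) = b h^2 / (b h^2 + Me / N) of the GBV."""
    h2 = setting.trait.heritability
    if h2 == 0.0:
        warnings.warn("heritability is 0: genomic prediction has zero reliability", stacklevel=2)
        return 0.0
    bh2 = setting.b * h2
    return bh2 / (bh2 + setting.me / setting.n_records)


def accuracy_gbv(setting: PredictionSetting) -> float:
    """Accuracy r(g, ghat), the square root of the GBV reliability."""
    return math.sqrt(reliability_gbv(setting))


def accuracy_phenotype(setting: PredictionSetting) -> float:
    """Correlation between future phenotypes and the GBV: h * r(g, ghat)."""
    h = math.sqrt(setting.trait.heritability)
    return h * accuracy_gbv(setting)


def reliability_binary(me: float, n_records: int, trait: TraitModel) -> float:
    """Reliability of a genomic profile score on the 0/1 disease scale.

    r^2(u, uhat) = h^2 z^2 / ( h^2 z^2 + [K(1-K)]^2 Me / [P(1-P) N] ) with
    K the population prevalence, P the case fraction among the N reference
    records, and z the normal density at the liability threshold.
    """
    if trait.prevalence is None or trait.case_fraction is None:
        raise ConfigurationError("binary reliability requires both prevalence (K) and case_fraction (P)")
    if not me > 0:
        raise ValueError(f"me must be positive, got {me}")
    if n_records < 1:
        raise ValueError(f"n_records must be >= 1, got {n_records}")
    h2 = trait.heritability
    if h2 == 0.0:
        warnings.warn("heritability is 0: genomic prediction has zero reliability", stacklevel=2)
        return 0.0
    k = trait.prevalence
    p = trait.case_fraction
    z = trait.threshold_density
    num = h2 * z * z
    denom = num + (k * (1.0 - k)) ** 2 * me / (p * (1.0 - p) * n_records)
    return num / denom


def ncp_quantitative(r2_y: float, target_n: int) -> float:
    """Non-centrality parameter NCP = N_T r^2 / (1 - r^2) of the
    predictor-outcome association test in a target set of size N_T."""
    if not (0.0 <= r2_y < 1.0):
        raise ValueError(f"r2_y must be in [0, 1), got {r2_y}")
    if target_n < 1:
        raise ValueError(f"target_n must be >= 1, got {target_n}")
    return target_n * r2_y / (1.0 - r2_y)


@dataclass(frozen=True)
class PowerSetting:
    """Power-analysis inputs.  Exactly one parameterization is active:
    reliability-based (``r2_y`` with ``target_n``) or odds-ratio risk
    stratification (``odds_ratio`` with group sizes and case fractions for
    the top and bottom strata of the predictor)."""

    alpha: float = 0.05
    r2_y: Optional[float] = None
    target_n: Optional[int] = None
    odds_ratio: Optional[float] = None
    n_top: Optional[int] = None
    n_bottom: Optional[int] = None
    p_top: Optional[float] = None
    p_bottom: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        rel = self.r2_y is not None or self.target_n is not None
        orb = any(v is not None for v in (self.odds_ratio, self.n_top, self.n_bottom, self.p_top, self.p_bottom))
        if rel and orb:
            raise ConfigurationError("specify either the reliability-based or the odds-ratio parameter set, not both")
        if not rel and not orb:
            raise ConfigurationError("no power parameterization supplied")

    def ncp(self) -> float:
        if self.r2_y is not None:
            if self.target_n is None:
                raise ConfigurationError("reliability-based power needs target_n")
            return ncp_quantitative(self.r2_y, self.target_n)
        return ncp_case_control_or(self)


def ncp_case_control_or(setting: PowerSetting) -> float:
    """NCP from the odds ratio contrasting top vs bottom risk groups.

    NCP = ln(OR)^2 [N_top P_t(1-P_t) P_b(1-P_b)] /
          [P_b(1-P_b) + (N_top/N_bottom) P_t(1-P_t)].

    Zero at OR = 1 and symmetric under OR -> 1/OR.
    """
    orr, nt, nb, pt, pb = (
        setting.odds_ratio,
        setting.n_top,
        setting.n_bottom,
        setting.p_top,
        setting.p_bottom,
    )
    if any(v is None for v in (orr, nt, nb, pt, pb)):
        raise ConfigurationError("odds-ratio power needs odds_ratio, n_top, n_bottom, p_top, p_bottom")
    if not orr > 0:
        raise ValueError(f"odds_ratio must be positive, got {orr}")
    for name, p in (("p_top", pt), ("p_bottom", pb)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must be strictly inside (0, 1), got {p} (degenerate group)")
    if nt < 1 or nb < 1:
        raise ValueError("group sizes must be >= 1")
    vt = pt * (1.0 - pt)
    vb = pb * (1.0 - pb)
    return math.log(orr) ** 2 * (nt * vt * vb) / (vb + (nt / nb) * vt)


def power(ncp: float, alpha: float, *, literal_ncp: bool = False, two_sided: bool = True) -> float:
    """Power of the predictor-outcome association test.

    power = 1 - Phi[Phi^-1(1 - alpha/2) - delta] + Phi[Phi^-1(alpha/2) - delta]

    By default ``delta = sqrt(NCP)``, the z-scale shift that makes the test
    agree with a 1-df non-central chi-square and gives power exactly alpha at
    NCP = 0.  ``literal_ncp=True`` uses ``delta = NCP`` directly.  One-sided
    power replaces alpha/2 by alpha and drops the lower tail.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if ncp < 0:
        raise ValueError(f"ncp must be non-negative, got {ncp}")
    delta = ncp if literal_ncp else math.sqrt(ncp)
    if two_sided:
        upper = stats.norm.isf(alpha / 2.0)
        return float(stats.norm.sf(upper - delta) + stats.norm.cdf(-upper - delta))
    return float(stats.norm.sf(stats.norm.isf(alpha) - delta))
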