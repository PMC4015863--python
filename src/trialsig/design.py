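"""Sample-size and power calculations defining the design alternative.

Normal-approximation (unpooled-variance, no continuity correction) formulas
for two proportions and for a mean difference; the inverse power
calculation; the information fraction of an under- or over-recruited trial;
and the confirmatory/exploratory classification of secondary outcomes
(power below 80% at the planned sample size demotes an outcome to
exploratory).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from scipy.stats import norm

from .bayes import AlternativeHypothesis, AlternativeSource
from .effects import rr_to_or

__all__ = [
    "OutcomeType",
    "EffectAssumption",
    "TrialDesign",
    "OutcomeStatus",
    "PowerAssessment",
    "SampleSize",
    "sample_size_two_proportions",
    "sample_size_mean_difference",
    "power_two_proportions",
    "power_mean_difference",
    "information_fraction",
    "assess_outcome_power",
    "CONFIRMATORY_POWER",
]

#: minimum power for an outcome analysed at full threshold (inclusive)
CONFIRMATORY_POWER = 0.80


class OutcomeType(str, Enum):
    BINARY = "binary"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class EffectAssumption:
    """The anticipated effect of a sample-size calculation."""

    type: str  # "rr", "or", "hr" or "md"
    value: float
    systematic_review_based: bool = False

    def __post_init__(self) -> None:
        if self.type not in ("rr", "or", "hr", "md"):
            raise ValueError(f"unknown effect type {self.type!r}")
        if self.type != "md" and self.value <= 0:
            raise ValueError(f"non-positive ratio effect {self.value}")
        if self.value == (1.0 if self.type != "md" else 0.0):
            raise ValueError("anticipated effect equals the null value")


@dataclass
class TrialDesign:
    """Ingredients of the a-priori sample-size calculation."""

    outcome_type: OutcomeType
    effect: EffectAssumption
    alpha: float = 0.05
    power: float = 0.80
    planned_n_total: int = 0
    control_risk: Optional[float] = None
    sd: Optional[float] = None
    allocation_ratio: float = 1.0
    looks: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.outcome_type = OutcomeType(self.outcome_type)
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.alpha + (1 - self.power) >= 1:
            raise ValueError("alpha + beta must be below 1")
        if self.planned_n_total <= 0:
            raise ValueError("planned_n_total must be positive")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation_ratio must be positive")
        if self.outcome_type is OutcomeType.BINARY:
            if self.effect.type == "rr" and self.control_risk is None:
                raise ValueError("a risk-ratio design needs control_risk")
            if self.control_risk is not None and not 0 < self.control_risk < 1:
                raise ValueError(f"control risk {self.control_risk} outside (0, 1)")
        else:
            if self.sd is None or self.sd <= 0:
                raise ValueError("a continuous design needs sd > 0")
        looks = tuple(self.looks or ())
        if looks and (any(not 0 < t <= 1 for t in looks) or list(looks) != sorted(set(looks))):
            raise ValueError("looks must be strictly increasing fractions in (0, 1]")
        self.looks = looks

    def alternative(self) -> AlternativeHypothesis:
        """The design alternative on the analysis scale.

        A risk-ratio assumption is converted to the odds-ratio implied at
        the control-group risk before taking logs; OR/HR are logged
        directly; a mean difference is used as-is.
        """
        e = self.effect
        if e.type == "md":
            return AlternativeHypothesis(theta_alt=e.value)
        if e.type == "rr":
            theta = math.log(rr_to_or(e.value, self.control_risk))
        else:
            theta = math.log(e.value)
        return AlternativeHypothesis(
            theta_alt=theta,
            source=AlternativeSource.SAMPLE_SIZE_CALCULATION,
            original_ratio=e.value,
            ratio_measure=e.type,
            control_risk=self.control_risk,
        )


class OutcomeStatus(str, Enum):
    CONFIRMATORY = "confirmatory"
    EXPLORATORY = "exploratory"


@dataclass(frozen=True)
class PowerAssessment:
    outcome_id: str
    power: float
    status: OutcomeStatus


@dataclass(frozen=True)
class SampleSize:
    n_per_group: int
    n_total: int


def _zq(p: float) -> float:
    return float(norm.ppf(p))


def sample_size_two_proportions(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    power: float = 0.80,
    allocation_ratio: float = 1.0,
) -> SampleSize:
    """Participants per group to detect risk ``p1`` vs control risk ``p0``.

    Unpooled normal approximation: with allocation ratio r (experimental
    per control participant), the control group needs

        n0 = (z_{1-a/2} + z_{pow})^2 (p0 q0 + p1 q1 / r) / (p1 - p0)^2

    and the experimental group r * n0; each is rounded up.
    """
    for name, p in (("p0", p0), ("p1", p1)):
        if not 0 < p < 1:
            raise ValueError(f"{name}={p} outside (0, 1)")
    if p0 == p1:
        raise ValueError("p0 = p1: infinite sample size")
    z = _zq(1 - alpha / 2) + _zq(power)
    n0 = z**2 * (p0 * (1 - p0) + p1 * (1 - p1) / allocation_ratio) / (p1 - p0) ** 2
    n_control = math.ceil(n0)
    n_exp = math.ceil(allocation_ratio * n0)
    if allocation_ratio == 1.0:
        n = max(n_control, n_exp)
        return SampleSize(n_per_group=n, n_total=2 * n)
    return SampleSize(n_per_group=n_control, n_total=n_control + n_exp)


def sample_size_mean_difference(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.80
) -> SampleSize:
    """Per-group n for a mean difference: ``2 (z_{1-a/2}+z_pow)^2 sd^2 / delta^2``."""
    if delta == 0:
        raise ValueError("delta = 0: infinite sample size")
    if sd <= 0:
        raise ValueError(f"non-positive sd {sd}")
    z = _zq(1 - alpha / 2) + _zq(power)
    n = math.ceil(2.0 * z**2 * sd**2 / delta**2)
    return SampleSize(n_per_group=n, n_total=2 * n)


def power_two_proportions(
    p0: float, p1: float, n_per_group: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided level-``alpha`` Wald test at ``n_per_group``.

    Inverse of :func:`sample_size_two_proportions` (equal allocation);
    equals ``alpha`` when ``p0 == p1``. Both rejection tails are counted.
    """
    for name, p in (("p0", p0), ("p1", p1)):
        if not 0 < p < 1:
            raise ValueError(f"{name}={p} outside (0, 1)")
    if n_per_group < 2:
        raise ValueError(f"n_per_group {n_per_group} too small")
    se = math.sqrt((p0 * (1 - p0) + p1 * (1 - p1)) / n_per_group)
    za = _zq(1 - alpha / 2)
    shift = (p1 - p0) / se
    return float(norm.sf(za - shift) + norm.cdf(-za - shift))


def power_mean_difference(
    delta: float, sd: float, n_per_group: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided Wald test for a mean difference."""
    if sd <= 0:
        raise ValueError(f"non-positive sd {sd}")
    if n_per_group < 2:
        raise ValueError(f"n_per_group {n_per_group} too small")
    se = sd * math.sqrt(2.0 / n_per_group)
    za = _zq(1 - alpha / 2)
    shift = delta / se
    return float(norm.sf(za - shift) + norm.cdf(-za - shift))


def information_fraction(n_randomised: int, planned_n_total: int) -> float:
    """Randomised over planned participants, clamped to 1 when exceeded."""
    if planned_n_total <= 0:
        raise ValueError("planned_n_total must be positive")
    if n_randomised <= 0:
        raise ValueError("n_randomised must be positive")
    frac = n_randomised / planned_n_total
    if frac > 1:
        warnings.warn(
            f"{n_randomised} randomised exceeds planned {planned_n_total}; "
            "information fraction clamped to 1",
            stacklevel=2,
        )
        return 1.0
    return frac


def assess_outcome_power(
    outcome_id: str,
    design: TrialDesign,
    effect: EffectAssumption,
    control_risk: Optional[float] = None,
    sd: Optional[float] = None,
) -> PowerAssessment:
    """Classify an outcome as confirmatory or exploratory at the planned N.

    Power is computed from the outcome's own anticipated effect and
    variability at the design's planned total sample size; an outcome with
    power below 80% is exploratory and should not be judged at the full
    significance threshold.
    """
    n_per_group = design.planned_n_total / 2.0
    if effect.type == "md":
        if sd is None or sd <= 0:
            raise ValueError(f"outcome {outcome_id!r}: mean-difference power needs sd > 0")
        pw = power_mean_difference(effect.value, sd, n_per_group, design.alpha)
    else:
        p0 = control_risk if control_risk is not None else design.control_risk
        if p0 is None:
            raise ValueError(f"outcome {outcome_id!r}: binary power needs a control risk")
        if effect.type == "rr":
            p1 = effect.value * p0
        else:  # or / hr treated via the odds transform
            odds = effect.value * p0 / (1 - p0)
            p1 = odds / (1 + odds)
        if not 0 < p1 < 1:
            raise ValueError(f"outcome {outcome_id!r}: implied experimental risk {p1} invalid")
        pw = power_two_proportions(p0, p1, n_per_group, design.alpha)
    status = (
        OutcomeStatus.CONFIRMATORY if pw >= CONFIRMATORY_POWER else OutcomeStatus.EXPLORATORY
    )
    return PowerAssessment(outcome_id=outcome_id, power=pw, status=status)
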