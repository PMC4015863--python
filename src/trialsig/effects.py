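"""Effect-measure algebra for two-arm trial summaries.

Conversions among a point estimate, its confidence interval, its standard
error and its two-sided P-value, on the correct analysis scale (natural log
for ratio measures OR/RR/HR, identity for a mean difference), plus the
standard Wald estimators from a 2x2 table of event counts.

All ratio-measure arithmetic is carried on the log scale; published hazard
and risk ratios are log-transformed and treated like log odds ratios
downstream, with the original measure retained for provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from scipy.stats import norm

__all__ = [
    "Measure",
    "Scale",
    "Direction",
    "EffectEstimate",
    "TwoByTwoTable",
    "AnalysisScaleValue",
    "TableEffects",
    "to_analysis_scale",
    "from_analysis_scale",
    "se_from_ci",
    "ci_from_se",
    "p_from_estimate",
    "se_from_p",
    "effects_from_table",
    "rr_to_or",
]

#: relative disagreement between CI-derived and P-derived SE above which a
#: warning is raised (published inputs are rounded, so some slack is needed)
SE_AGREEMENT_RTOL = 0.10


class Measure(str, Enum):
    OR = "or"
    RR = "rr"
    HR = "hr"
    MD = "md"

    @property
    def is_ratio(self) -> bool:
        return self is not Measure.MD

    @property
    def null_value(self) -> float:
        return 1.0 if self.is_ratio else 0.0


class Scale(str, Enum):
    LOG = "log"
    IDENTITY = "identity"


class Direction(str, Enum):
    """Which side of the null value counts as benefit."""

    LESS_THAN_NULL = "less_than_null"
    GREATER_THAN_NULL = "greater_than_null"

    @property
    def sign(self) -> int:
        return -1 if self is Direction.LESS_THAN_NULL else 1


@dataclass(frozen=True)
class AnalysisScaleValue:
    """An effect carried on its analysis scale (log for ratios)."""

    value: float
    scale: Scale
    measure: Measure


@dataclass(frozen=True)
class TwoByTwoTable:
    """Event / non-event counts of a two-arm trial."""

    events_experimental: int
    nonevents_experimental: int
    events_control: int
    nonevents_control: int

    def __post_init__(self) -> None:
        for name, v in self.cells().items():
            if v < 0:
                raise ValueError(f"negative cell count {name}={v}")
        if self.n_experimental == 0 or self.n_control == 0:
            raise ValueError("an arm with zero randomised participants")

    def cells(self) -> dict[str, float]:
        return {
            "events_experimental": self.events_experimental,
            "nonevents_experimental": self.nonevents_experimental,
            "events_control": self.events_control,
            "nonevents_control": self.nonevents_control,
        }

    @property
    def n_experimental(self) -> float:
        return self.events_experimental + self.nonevents_experimental

    @property
    def n_control(self) -> float:
        return self.events_control + self.nonevents_control

    @classmethod
    def from_margins(
        cls, events_experimental: int, n_experimental: int, events_control: int, n_control: int
    ) -> "TwoByTwoTable":
        return cls(
            events_experimental,
            n_experimental - events_experimental,
            events_control,
            n_control - events_control,
        )


@dataclass
class EffectEstimate:
    """A published intervention-effect estimate.

    At least one of the confidence interval, the standard error (on the
    analysis scale) or the two-sided P-value must be supplied; the others
    are derived on demand.
    """

    measure: Measure
    point: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_level: float = 0.95
    se: Optional[float] = None
    p_two_sided: Optional[float] = None
    direction_of_benefit: Direction = Direction.LESS_THAN_NULL
    #: which source the resolved SE came from ("se", "ci" or "p")
    se_source: str = field(default="", init=False)

    def __post_init__(self) -> None:
        self.measure = Measure(self.measure)
        self.direction_of_benefit = Direction(self.direction_of_benefit)
        if self.measure.is_ratio and self.point <= 0:
            raise ValueError(f"non-positive {self.measure.value} estimate {self.point}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level {self.ci_level} outside (0, 1)")
        has_ci = self.ci_lower is not None and self.ci_upper is not None
        if has_ci and not self.ci_lower < self.point < self.ci_upper:
            raise ValueError("confidence interval does not bracket the point estimate")
        if self.p_two_sided is not None and not 0 < self.p_two_sided <= 1:
            raise ValueError(f"two-sided P {self.p_two_sided} outside (0, 1]")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"non-positive standard error {self.se}")
        if not (has_ci or self.se is not None or self.p_two_sided is not None):
            raise ValueError("need at least one of CI, SE or P")

    @property
    def scale(self) -> Scale:
        return Scale.LOG if self.measure.is_ratio else Scale.IDENTITY

    def resolve(self) -> tuple[AnalysisScaleValue, float, float]:
        """Resolve to ``(theta_hat, se, p_two_sided)`` on the analysis scale.

        SE precedence: explicit SE, then the CI, then the P-value; when
        several sources exist the CI-derived and P-derived SEs are compared
        and a warning emitted if they disagree beyond ``SE_AGREEMENT_RTOL``.
        """
        theta = to_analysis_scale(self)
        se_ci = None
        if self.ci_lower is not None and self.ci_upper is not None:
            se_ci = se_from_ci(self.ci_lower, self.ci_upper, self.ci_level, self.scale)
        se_p = None
        if self.p_two_sided is not None and self.p_two_sided < 1 and theta.value != 0:
            se_p = se_from_p(theta, self.p_two_sided)
        if self.se is not None:
            se, self.se_source = self.se, "se"
        elif se_ci is not None:
            se, self.se_source = se_ci, "ci"
        elif se_p is not None:
            se, self.se_source = se_p, "p"
        else:
            raise ValueError("cannot resolve a standard error (P=1 or null estimate with no CI/SE)")
        if se_ci is not None and se_p is not None:
            if abs(se_ci - se_p) > SE_AGREEMENT_RTOL * se_ci:
                warnings.warn(
                    f"SE from CI ({se_ci:.4g}) and from P ({se_p:.4g}) disagree by more than "
                    f"{SE_AGREEMENT_RTOL:.0%}; using the {self.se_source!r}-derived value",
                    stacklevel=2,
                )
        p = self.p_two_sided if self.p_two_sided is not None else p_from_estimate(theta, se)
        return theta, se, p


@dataclass(frozen=True)
class TableEffects:
    """Closed-form Wald summaries of a 2x2 table."""

    odds_ratio: float
    log_or: float
    se_log_or: float
    risk_ratio: float
    risk_experimental: float
    risk_control: float
    risk_difference: float
    continuity_corrected: bool


def to_analysis_scale(est: EffectEstimate) -> AnalysisScaleValue:
    """Natural log of the point estimate for OR/RR/HR; identity for MD."""
    if est.measure.is_ratio:
        return AnalysisScaleValue(math.log(est.point), Scale.LOG, est.measure)
    return AnalysisScaleValue(est.point, Scale.IDENTITY, est.measure)


def from_analysis_scale(theta: AnalysisScaleValue) -> float:
    """Inverse of :func:`to_analysis_scale`: back to the reporting scale."""
    return math.exp(theta.value) if theta.scale is Scale.LOG else theta.value


def _transform(x: float, scale: Scale) -> float:
    if scale is Scale.LOG:
        if x <= 0:
            raise ValueError(f"non-positive bound {x} on the log scale")
        return math.log(x)
    return x


def se_from_ci(
    ci_lower: float, ci_upper: float, ci_level: float = 0.95, scale: Scale = Scale.LOG
) -> float:
    """Wald SE recovered from a symmetric CI on the analysis scale."""
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level {ci_level} outside (0, 1)")
    if not ci_lower < ci_upper:
        raise ValueError(f"crossed confidence bounds ({ci_lower}, {ci_upper})")
    scale = Scale(scale)
    z = norm.ppf(0.5 + ci_level / 2.0)
    return (_transform(ci_upper, scale) - _transform(ci_lower, scale)) / (2.0 * z)


def ci_from_se(
    theta: AnalysisScaleValue, se: float, ci_level: float = 0.95
) -> tuple[float, float]:
    """Symmetric Wald CI on the reporting scale (exponentiated for ratios)."""
    if se <= 0:
        raise ValueError(f"non-positive standard error {se}")
    z = norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = theta.value - z * se, theta.value + z * se
    if theta.scale is Scale.LOG:
        return math.exp(lo), math.exp(hi)
    return lo, hi


def p_from_estimate(theta: AnalysisScaleValue, se: float) -> float:
    """Two-sided Wald P-value, ``2(1 - Phi(|theta|/se))``."""
    if se <= 0:
        raise ValueError(f"non-positive standard error {se}")
    return float(2.0 * norm.sf(abs(theta.value) / se))


def se_from_p(theta: AnalysisScaleValue, p_two_sided: float) -> float:
    """SE implied by a two-sided Wald P for a non-null estimate."""
    if not 0 < p_two_sided < 1:
        raise ValueError(f"two-sided P {p_two_sided} outside (0, 1)")
    if theta.value == 0:
        raise ValueError("SE undefined from P for a null estimate")
    z = norm.isf(p_two_sided / 2.0)  # isf keeps precision for very small P
    return abs(theta.value) / z


def effects_from_table(
    table: TwoByTwoTable, continuity_correction: float = 0.5
) -> TableEffects:
    """Odds ratio, risk ratio and risk difference with Wald log-OR SE.

    Any zero cell triggers the Haldane–Anscombe correction: the correction
    (default 0.5) is added to all four cells before the OR and its SE are
    computed. Risks are reported from the uncorrected margins.
    """
    a, b = table.events_experimental, table.nonevents_experimental
    c, d = table.events_control, table.nonevents_control
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + continuity_correction for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    se_log_or = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    risk_e = table.events_experimental / table.n_experimental
    risk_c = table.events_control / table.n_control
    if corrected:
        rr = (a / (a + b)) / (c / (c + d))
    else:
        rr = risk_e / risk_c if risk_c > 0 else float("inf")
    return TableEffects(
        odds_ratio=odds_ratio,
        log_or=math.log(odds_ratio),
        se_log_or=se_log_or,
        risk_ratio=rr,
        risk_experimental=risk_e,
        risk_control=risk_c,
        risk_difference=risk_e - risk_c,
        continuity_corrected=corrected,
    )


def rr_to_or(rr: float, control_risk: float) -> float:
    """Odds ratio implied by a risk ratio at a given control-group risk.

    ``OR = odds(rr * p0) / odds(p0)`` with ``odds(p) = p / (1 - p)``.
    """
    if rr <= 0:
        raise ValueError(f"non-positive risk ratio {rr}")
    if not 0 < control_risk < 1:
        raise ValueError(f"control risk {control_risk} outside (0, 1)")
    p1 = rr * control_risk
    if p1 >= 1:
        raise ValueError(f"experimental risk {p1} >= 1")
    return (p1 / (1 - p1)) / (control_risk / (1 - control_risk))
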