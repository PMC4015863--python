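"""Gaussian likelihood-ratio Bayes factor against the design alternative.

The Bayes factor used here is the ratio of the likelihood of the observed
effect under the point null (no effect) to its likelihood under the point
alternative hypothesised in the trial's sample-size calculation, both
evaluated with the same Gaussian kernel on the analysis (log-ratio or
mean-difference) scale:

    BF = exp(-theta_hat^2 / (2 SE^2)) / exp(-(theta_hat - theta_alt)^2 / (2 SE^2))

so log BF = (theta_alt^2 - 2 theta_hat theta_alt) / (2 SE^2), exactly linear
in the observed effect. BF < 1 favours the alternative; BF = 1 when the
observed effect sits exactly half way between the null and the alternative;
a BF below 0.1 (ten-fold support) is the conventional significance
threshold in this procedure. No priors are placed on the effect and no
integration is performed: both hypotheses are point hypotheses, which keeps
the quantity a pure likelihood ratio.

Directionality is preserved: an observed effect on the opposite side of the
null from the alternative produces a very large BF (strong support for the
null over the anticipated benefit), with no two-sided folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .effects import rr_to_or

__all__ = [
    "AlternativeSource",
    "AlternativeHypothesis",
    "BFClassification",
    "BayesFactorResult",
    "bayes_factor",
    "sceptical_alternative",
    "bf_curve",
    "curve_to_csv",
    "DEFAULT_BF_THRESHOLD",
]

DEFAULT_BF_THRESHOLD = 0.1


class AlternativeSource(str, Enum):
    SAMPLE_SIZE_CALCULATION = "sample_size_calculation"
    SCEPTICAL = "sceptical"
    USER = "user"


@dataclass(frozen=True)
class AlternativeHypothesis:
    """A point alternative on the analysis scale.

    ``original_ratio`` keeps the RR/OR/HR before the log transform (needed
    to form the sceptical alternative half way to 1.0 on the ratio scale);
    ``control_risk`` is needed when the ratio is a risk ratio that must be
    re-expressed as an odds ratio.
    """

    theta_alt: float
    source: AlternativeSource = AlternativeSource.SAMPLE_SIZE_CALCULATION
    original_ratio: Optional[float] = None
    ratio_measure: Optional[str] = None  # "rr", "or" or "hr"
    control_risk: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta_alt == 0:
            raise ValueError("degenerate alternative: theta_alt = 0")


class BFClassification(str, Enum):
    SUPPORTS_ALTERNATIVE = "supports_alternative"
    EQUIVOCAL = "equivocal"
    SUPPORTS_NULL = "supports_null"


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    log_bf: float
    theta_obs: float
    se: float
    theta_alt: float
    classification: BFClassification
    threshold: float = DEFAULT_BF_THRESHOLD


def bayes_factor(
    theta_obs: float,
    se: float,
    theta_alt: float,
    threshold: float = DEFAULT_BF_THRESHOLD,
) -> BayesFactorResult:
    """Likelihood ratio of the point null to the point alternative.

    Parameters are all on the analysis scale (log ratio, or outcome units
    for a mean difference). ``threshold`` classifies the result:
    BF < threshold supports the alternative, BF > 1/threshold supports the
    null, anything between is equivocal.
    """
    if se <= 0:
        raise ValueError(f"non-positive standard error {se}")
    if theta_alt == 0:
        raise ValueError("degenerate alternative: theta_alt = 0")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    log_bf = (theta_alt**2 - 2.0 * theta_obs * theta_alt) / (2.0 * se**2)
    bf = math.exp(log_bf) if log_bf < 709.0 else math.inf
    if bf < threshold:
        cls = BFClassification.SUPPORTS_ALTERNATIVE
    elif bf > 1.0 / threshold:
        cls = BFClassification.SUPPORTS_NULL
    else:
        cls = BFClassification.EQUIVOCAL
    return BayesFactorResult(bf, log_bf, theta_obs, se, theta_alt, cls, threshold)


def sceptical_alternative(
    alt: AlternativeHypothesis, log_scale_midpoint: bool = False
) -> AlternativeHypothesis:
    """Alternative with a ratio half way between 1.0 and the design ratio.

    The midpoint is taken on the ratio scale, ``(1 + ratio) / 2`` (the
    geometric midpoint on the log scale is available behind
    ``log_scale_midpoint=True``). A risk-ratio alternative is halved on the
    RR scale and then re-expressed as an odds ratio using the design's
    control-group risk, mirroring how the design alternative itself is
    formed.
    """
    if alt.original_ratio is None:
        raise ValueError("sceptical alternative needs the original ratio")
    if alt.original_ratio == 1:
        raise ValueError("no effect to halve: original ratio is 1.0")
    if log_scale_midpoint:
        ratio = math.exp(math.log(alt.original_ratio) / 2.0)
    else:
        ratio = (1.0 + alt.original_ratio) / 2.0
    if alt.ratio_measure == "rr":
        if alt.control_risk is None:
            raise ValueError("risk-ratio alternative needs control_risk")
        theta = math.log(rr_to_or(ratio, alt.control_risk))
    else:
        theta = math.log(ratio)
    return AlternativeHypothesis(
        theta_alt=theta,
        source=AlternativeSource.SCEPTICAL,
        original_ratio=ratio,
        ratio_measure=alt.ratio_measure,
        control_risk=alt.control_risk,
    )


def bf_curve(
    theta_alt: float, se: float, grid: Iterable[float]
) -> list[tuple[float, float]]:
    """Bayes factor as a function of the observed effect over ``grid``.

    Strictly monotone in the observed effect: decreasing towards the
    alternative (equal to 1 at theta_alt / 2, below 1 beyond it).
    """
    return [(float(t), bayes_factor(float(t), se, theta_alt).bf) for t in grid]


def curve_to_csv(curve: Sequence[tuple[float, float]]) -> str:
    """Two-column CSV rendering (theta, bf) of a Bayes-factor curve."""
    lines = ["theta,bf"]
    lines += [f"{t!r},{b!r}" for t, b in curve]
    return "\n".join(lines) + "\n"
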