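"""Clinical-significance assessment (step 5 of the procedure).

Clinical significance is only assessed when statistical significance has
survived all four earlier steps AND the Bayes factor supports the
alternative (BF strictly below its threshold, 0.1 by default). The
assessment itself is descriptive: the absolute risk difference and its
reciprocal, the number-needed-to-treat (benefit) or number-needed-to-harm
(harm), rounded up; and a comparison of the estimate and its CI against
the minimal relevant clinical difference (MCID) used to size the trial.
The balance between beneficial and harmful effects has no quantitative
model here and is emitted as a narrative flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from .effects import Direction

__all__ = [
    "NNTKind",
    "NumberNeeded",
    "MCIDComparison",
    "ClinicalAssessment",
    "nnt_nnh",
    "clinical_gate",
    "compare_to_mcid",
]


class NNTKind(str, Enum):
    NNT = "NNT"
    NNH = "NNH"


@dataclass(frozen=True)
class NumberNeeded:
    value: int
    kind: NNTKind
    risk_difference: float


@dataclass(frozen=True)
class MCIDComparison:
    mcid_met: bool
    ci_excludes_mcid_shortfall: bool


@dataclass(frozen=True)
class ClinicalAssessment:
    assessable: bool
    nnt_or_nnh: Optional[NumberNeeded] = None
    risk_difference: Optional[float] = None
    mcid: Optional[MCIDComparison] = None
    narrative_flags: tuple[str, ...] = field(default_factory=tuple)


def nnt_nnh(
    risk_control: float,
    risk_experimental: float,
    direction_of_benefit: Direction = Direction.LESS_THAN_NULL,
) -> NumberNeeded:
    """Number needed to treat (or harm): ``ceil(1 / |risk difference|)``.

    The kind is NNT when the experimental arm's risk moved in the benefit
    direction (lower risk when benefit means fewer events), NNH otherwise.
    """
    for name, r in (("risk_control", risk_control), ("risk_experimental", risk_experimental)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name}={r} outside [0, 1]")
    diff = risk_experimental - risk_control
    if diff == 0:
        raise ValueError("zero risk difference: NNT undefined")
    benefit = diff < 0 if direction_of_benefit is Direction.LESS_THAN_NULL else diff > 0
    return NumberNeeded(
        value=math.ceil(1.0 / abs(diff)),
        kind=NNTKind.NNT if benefit else NNTKind.NNH,
        risk_difference=diff,
    )


def clinical_gate(
    step_results: Mapping[int, bool], bf: float, threshold: float = 0.1
) -> bool:
    """True iff steps 1-4 all passed and the Bayes factor is below threshold."""
    missing = [k for k in (1, 2, 3, 4) if k not in step_results]
    if missing:
        raise ValueError(f"missing step verdicts: {missing}")
    return all(step_results[k] for k in (1, 2, 3, 4)) and bf < threshold


def compare_to_mcid(
    theta: float,
    ci_lower: float,
    ci_upper: float,
    mcid: float,
    direction_of_benefit: Direction = Direction.LESS_THAN_NULL,
) -> MCIDComparison:
    """Compare an estimate (analysis scale) against the minimal relevant difference.

    ``mcid_met`` is inclusive: the point estimate at least as extreme as
    the MCID in the benefit direction. The second flag demands the whole
    CI be at least as extreme, i.e. the data exclude effects smaller than
    the MCID.
    """
    if mcid == 0:
        raise ValueError("MCID of zero is not a clinical difference")
    s = Direction(direction_of_benefit).sign
    met = s * theta >= s * mcid
    inner_bound = ci_upper if s < 0 else ci_lower
    ci_beyond = s * inner_bound >= s * mcid
    return MCIDComparison(mcid_met=met, ci_excludes_mcid_shortfall=ci_beyond)
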