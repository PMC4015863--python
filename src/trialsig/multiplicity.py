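"""Strong-control multiplicity adjustment across outcome comparisons.

Four procedures, all controlling the familywise error rate in the strong
sense (under every configuration of true and false nulls):

- Bonferroni: each raw P multiplied by the family size (capped at 1).
- Hommel: closed testing with Simes local tests; uniformly no more
  conservative than Bonferroni. Adjusted P-values are delegated to
  statsmodels; no standard simultaneous CI exists for this procedure.
- Fixed sequence: hypotheses tested in a pre-specified order, each at the
  full family alpha, stopping at the first non-rejection.
- Fallback: fixed order with importance weights; a hypothesis is tested at
  its own alpha share plus the shares accumulated from previously rejected
  hypotheses, and testing never stops.

Comparisons pre-specified as exploratory are excluded from the family by
default and flagged for conservative interpretation. A closed-testing
enumeration oracle (Simes or Bonferroni local tests) is included for
cross-validation of the shortcut procedures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Role",
    "Procedure",
    "Comparison",
    "ComparisonFamily",
    "AdjustedComparison",
    "bonferroni",
    "hommel",
    "fixed_sequence",
    "fallback",
    "adjust",
    "closed_testing_simes_oracle",
    "closed_testing_bonferroni_oracle",
]


class Role(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    EXPLORATORY = "exploratory"


class Procedure(str, Enum):
    BONFERRONI = "bonferroni"
    HOMMEL = "hommel"
    FIXED_SEQUENCE = "fixed_sequence"
    FALLBACK = "fallback"
    NONE = "none"


@dataclass(frozen=True)
class Comparison:
    id: str
    p_raw: float
    role: Role = Role.PRIMARY
    order_index: int = 0
    weight: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.p_raw <= 1:
            raise ValueError(f"comparison {self.id!r}: P {self.p_raw} outside (0, 1]")
        if self.weight < 0:
            raise ValueError(f"comparison {self.id!r}: negative weight")


@dataclass
class ComparisonFamily:
    comparisons: Sequence[Comparison]
    alpha_family: float = 0.05
    procedure: Procedure = Procedure.HOMMEL
    include_exploratory: bool = False

    def __post_init__(self) -> None:
        self.procedure = Procedure(self.procedure)
        if not 0 < self.alpha_family < 1:
            raise ValueError(f"alpha_family {self.alpha_family} outside (0, 1)")
        if not self.comparisons:
            raise ValueError("empty comparison family")

    def members(self) -> list[Comparison]:
        """Comparisons actually in the family (exploratory excluded by default)."""
        if self.include_exploratory:
            return list(self.comparisons)
        return [c for c in self.comparisons if c.role is not Role.EXPLORATORY]


@dataclass(frozen=True)
class AdjustedComparison:
    id: str
    p_raw: float
    rejected: bool
    tested: bool = True
    p_adjusted: Optional[float] = None
    local_alpha: Optional[float] = None
    notes: tuple[str, ...] = field(default_factory=tuple)


def _require_members(family: ComparisonFamily) -> list[Comparison]:
    members = family.members()
    if not members:
        raise ValueError("no non-exploratory comparisons in the family")
    return members


def bonferroni(family: ComparisonFamily) -> list[AdjustedComparison]:
    """``p_adj = min(1, m p)`` with per-comparison local alpha ``alpha/m``."""
    members = _require_members(family)
    m = len(members)
    out = []
    for c in members:
        p_adj = min(1.0, m * c.p_raw)
        out.append(
            AdjustedComparison(
                id=c.id,
                p_raw=c.p_raw,
                p_adjusted=p_adj,
                local_alpha=family.alpha_family / m,
                rejected=p_adj < family.alpha_family,
            )
        )
    return out


def hommel(family: ComparisonFamily) -> list[AdjustedComparison]:
    """Hommel adjusted P-values (closed testing with Simes local tests)."""
    members = _require_members(family)
    pvals = np.array([c.p_raw for c in members])
    if len(members) == 1:
        adjusted = pvals
    else:
        _, adjusted, _, _ = multipletests(pvals, alpha=family.alpha_family, method="hommel")
    return [
        AdjustedComparison(
            id=c.id,
            p_raw=c.p_raw,
            p_adjusted=float(p_adj),
            local_alpha=None,
            rejected=bool(p_adj < family.alpha_family),
            notes=("no standard simultaneous CI for the Hommel procedure",),
        )
        for c, p_adj in zip(members, adjusted)
    ]


def _ordered(members: list[Comparison]) -> list[Comparison]:
    idx = [c.order_index for c in members]
    if len(set(idx)) != len(idx):
        raise ValueError("sequence-based procedures need unique order_index values")
    return sorted(members, key=lambda c: c.order_index)


def fixed_sequence(family: ComparisonFamily) -> list[AdjustedComparison]:
    """Test in pre-specified order at full alpha; stop at the first failure."""
    ordered = _ordered(_require_members(family))
    out, testing = [], True
    for c in ordered:
        if testing:
            rejected = c.p_raw < family.alpha_family
            out.append(
                AdjustedComparison(
                    id=c.id,
                    p_raw=c.p_raw,
                    local_alpha=family.alpha_family,
                    rejected=rejected,
                    tested=True,
                )
            )
            testing = rejected
        else:
            out.append(
                AdjustedComparison(
                    id=c.id,
                    p_raw=c.p_raw,
                    local_alpha=None,
                    rejected=False,
                    tested=False,
                    notes=("not tested: an earlier hypothesis in the sequence failed",),
                )
            )
    return out


def fallback(family: ComparisonFamily) -> list[AdjustedComparison]:
    """Weighted sequential testing that never stops.

    Hypothesis i is tested at ``w_i alpha`` plus the alpha accumulated from
    previously rejected hypotheses; a failure forfeits only the local
    share, and testing continues down the sequence.
    """
    ordered = _ordered(_require_members(family))
    weights = [c.weight for c in ordered]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"fallback weights sum to {sum(weights)}, expected 1")
    out, carried = [], 0.0
    for c, w in zip(ordered, weights):
        local = w * family.alpha_family + carried
        rejected = local > 0 and c.p_raw < local
        carried = local if rejected else 0.0
        out.append(
            AdjustedComparison(
                id=c.id, p_raw=c.p_raw, local_alpha=local, rejected=rejected, tested=True
            )
        )
    return out


_DISPATCH = {
    Procedure.BONFERRONI: bonferroni,
    Procedure.HOMMEL: hommel,
    Procedure.FIXED_SEQUENCE: fixed_sequence,
    Procedure.FALLBACK: fallback,
}


def adjust(family: ComparisonFamily) -> list[AdjustedComparison]:
    """Apply the family's chosen procedure (``none`` leaves P-values raw)."""
    if family.procedure is Procedure.NONE:
        return [
            AdjustedComparison(
                id=c.id,
                p_raw=c.p_raw,
                p_adjusted=c.p_raw,
                local_alpha=family.alpha_family,
                rejected=c.p_raw < family.alpha_family,
                notes=("no multiplicity adjustment applied",),
            )
            for c in _require_members(family)
        ]
    return _DISPATCH[family.procedure](family)


def _closed_testing(pvals: Sequence[float], local_test) -> list[float]:
    m = len(pvals)
    if m > 12:
        raise ValueError("enumeration oracle limited to m <= 12")
    p = np.asarray(pvals, dtype=float)
    adjusted = np.zeros(m)
    indices = range(m)
    for size in range(1, m + 1):
        for subset in itertools.combinations(indices, size):
            local_p = local_test(p[list(subset)])
            for i in subset:
                adjusted[i] = max(adjusted[i], local_p)
    return [float(min(1.0, a)) for a in adjusted]


def closed_testing_simes_oracle(pvals: Sequence[float]) -> list[float]:
    """Exact closed-testing adjusted P-values with Simes local tests.

    Enumerates all 2^m - 1 intersection hypotheses (m <= 12); the adjusted
    P of hypothesis i is the largest Simes P over intersections containing
    i. Equals the Hommel adjustment; intended as an independent
    cross-check.
    """

    def simes(ps: np.ndarray) -> float:
        k = len(ps)
        order = np.sort(ps)
        return float(np.min(k * order / np.arange(1, k + 1)))

    return _closed_testing(pvals, simes)


def closed_testing_bonferroni_oracle(pvals: Sequence[float]) -> list[float]:
    """Closed testing with Bonferroni local tests (Holm's procedure)."""

    def bonf(ps: np.ndarray) -> float:
        return float(min(1.0, len(ps) * np.min(ps)))

    return _closed_testing(pvals, bonf)
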