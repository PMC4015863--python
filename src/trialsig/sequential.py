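"""Group-sequential threshold adjustment (O'Brien-Fleming-type).

When a trial stops before its planned sample size, or analyses accumulating
data at interim looks, the significance threshold at each analysis must be
tightened so that the familywise type-I error over all looks stays at the
design alpha. Two O'Brien-Fleming-style constructions are provided:

``obf_classic``
    The classical boundary for K equally spaced looks: the critical value
    on the score (Brownian) scale is constant, so z_k = C * sqrt(t_K / t_k)
    with C calibrated so the overall two-sided crossing probability is
    alpha.

``obf_spending``
    The Lan-DeMets O'Brien-Fleming-type alpha-spending function

        alpha*(t) = 2 * (1 - Phi(z_{1-alpha/2} / sqrt(t)))

    which spends almost no alpha early and all of it at full information,
    and supports arbitrary (not pre-planned) stopping fractions.

Crossing probabilities over the correlated sequence of test statistics
(corr(Z_i, Z_j) = sqrt(t_i / t_j)) are computed by the standard recursive
numerical integration of the sub-density of the score statistic over the
continuation region, using Gauss-Legendre quadrature; boundary values are
solved by root bracketing. Reported per-look nominal P-values are two-sided.

The widened confidence level accompanying an adjusted threshold follows the
repeated-confidence-interval convention: a look with two-sided nominal
threshold p reports a (1 - p) interval, so the interval and the threshold
always agree on significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "BoundaryMethod",
    "LookSchedule",
    "LookBoundary",
    "BoundarySet",
    "obf_spending_function",
    "boundaries",
    "adjusted_ci_level",
    "apply_step3",
    "Step3Adjustment",
]

_QUAD_NODES = 241  # Gauss-Legendre nodes per continuation region
_ZMAX = 40.0


class BoundaryMethod(str, Enum):
    OBF_CLASSIC = "obf_classic"
    OBF_SPENDING = "obf_spending"


@dataclass(frozen=True)
class LookSchedule:
    fractions: tuple[float, ...]
    alpha_total: float = 0.05

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("at least one look is required")
        if any(not 0 < t <= 1 for t in self.fractions):
            raise ValueError("look fractions must lie in (0, 1]")
        if list(self.fractions) != sorted(set(self.fractions)):
            raise ValueError("look fractions must be strictly increasing")
        if not 0 < self.alpha_total < 1:
            raise ValueError(f"alpha_total {self.alpha_total} outside (0, 1)")


@dataclass(frozen=True)
class LookBoundary:
    fraction: float
    z_boundary: float
    nominal_p: float  # two-sided
    cumulative_alpha_spent: float


@dataclass(frozen=True)
class BoundarySet:
    method: BoundaryMethod
    alpha_total: float
    looks: tuple[LookBoundary, ...]

    @property
    def z_boundaries(self) -> tuple[float, ...]:
        return tuple(lk.z_boundary for lk in self.looks)

    @property
    def nominal_p_values(self) -> tuple[float, ...]:
        return tuple(lk.nominal_p for lk in self.looks)


def obf_spending_function(t: float, alpha_total: float = 0.05) -> float:
    """Cumulative two-sided alpha spent by information fraction ``t``."""
    if t <= 0:
        raise ValueError(f"information fraction {t} must be positive")
    if not 0 < alpha_total < 1:
        raise ValueError(f"alpha_total {alpha_total} outside (0, 1)")
    t = min(t, 1.0)
    z = norm.ppf(1.0 - alpha_total / 2.0)
    return float(2.0 * norm.sf(z / math.sqrt(t)))


def _gl(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(_QUAD_NODES)
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    return mid + half * x, half * w


class _Recursion:
    """Sub-density of the score statistic over successive continuation regions."""

    def __init__(self, t1: float) -> None:
        self.t_prev = t1
        self.nodes: Optional[np.ndarray] = None
        self.weights: Optional[np.ndarray] = None
        self.dens: Optional[np.ndarray] = None
        self._first = True

    def cross_prob(self, t: float, b: float) -> float:
        """P(cross +-b at this look, no crossing at earlier looks)."""
        if self._first:
            return float(2.0 * norm.sf(b / math.sqrt(t)))
        s = math.sqrt(t - self.t_prev)
        tail = norm.sf((b - self.nodes) / s) + norm.cdf((-b - self.nodes) / s)
        return float(np.sum(self.weights * self.dens * tail))

    def advance(self, t: float, b: float) -> None:
        """Condition on not crossing at this look and move the density on."""
        x, w = _gl(-b, b)
        if self._first:
            dens = norm.pdf(x / math.sqrt(t)) / math.sqrt(t)
            self._first = False
        else:
            s = math.sqrt(t - self.t_prev)
            kernel = norm.pdf((x[:, None] - self.nodes[None, :]) / s) / s
            dens = kernel @ (self.weights * self.dens)
        self.nodes, self.weights, self.dens = x, w, dens
        self.t_prev = t


def _solve_boundary(rec: _Recursion, t: float, target: float) -> float:
    """S-scale boundary b with incremental crossing probability ``target``."""
    hi = _ZMAX * math.sqrt(t)
    if target <= rec.cross_prob(t, hi):
        return hi
    lo = 1e-9
    if target >= rec.cross_prob(t, lo):
        return lo
    return brentq(lambda b: rec.cross_prob(t, b) - target, lo, hi, xtol=1e-12)


def _spending_boundaries(schedule: LookSchedule) -> tuple[tuple[float, ...], tuple[float, ...]]:
    spends = [obf_spending_function(t, schedule.alpha_total) for t in schedule.fractions]
    rec = _Recursion(schedule.fractions[0])
    bs, cumulative = [], []
    spent_prev = 0.0
    for t, spent in zip(schedule.fractions, spends):
        b = _solve_boundary(rec, t, spent - spent_prev)
        rec.advance(t, b)
        bs.append(b)
        cumulative.append(spent)
        spent_prev = spent
    return tuple(bs), tuple(cumulative)


def _classic_total_alpha(schedule: LookSchedule, c: float) -> float:
    """Total two-sided crossing probability of the constant-score boundary c*sqrt(t_K)."""
    t_last = schedule.fractions[-1]
    rec = _Recursion(schedule.fractions[0])
    total = 0.0
    for t in schedule.fractions:
        b = c * math.sqrt(t_last)
        total += rec.cross_prob(t, b)
        rec.advance(t, b)
    return total


def boundaries(
    schedule: LookSchedule, method: BoundaryMethod = BoundaryMethod.OBF_SPENDING
) -> BoundarySet:
    """Two-sided symmetric stopping boundaries for a look schedule."""
    method = BoundaryMethod(method)
    if method is BoundaryMethod.OBF_SPENDING:
        bs, cumulative = _spending_boundaries(schedule)
    else:
        c = brentq(
            lambda c: _classic_total_alpha(schedule, c) - schedule.alpha_total,
            0.5,
            10.0,
            xtol=1e-10,
        )
        t_last = schedule.fractions[-1]
        bs = tuple(c * math.sqrt(t_last) for _ in schedule.fractions)
        rec = _Recursion(schedule.fractions[0])
        cumulative, total = [], 0.0
        for t, b in zip(schedule.fractions, bs):
            total += rec.cross_prob(t, b)
            rec.advance(t, b)
            cumulative.append(total)
    looks = []
    for t, b, spent in zip(schedule.fractions, bs, cumulative):
        z = b / math.sqrt(t)
        looks.append(
            LookBoundary(
                fraction=t,
                z_boundary=z,
                nominal_p=float(2.0 * norm.sf(z)),
                cumulative_alpha_spent=float(spent),
            )
        )
    return BoundarySet(method=method, alpha_total=schedule.alpha_total, looks=tuple(looks))


def adjusted_ci_level(nominal_p_at_look: float) -> float:
    """Confidence level matching a look's adjusted two-sided threshold."""
    if not 0 < nominal_p_at_look < 1:
        raise ValueError(f"nominal p {nominal_p_at_look} outside (0, 1)")
    return 1.0 - nominal_p_at_look


@dataclass(frozen=True)
class Step3Adjustment:
    required_threshold: float
    met: bool
    adjusted_ci_level: float
    information_fraction: float
    adjusted: bool
    boundary_set: Optional[BoundarySet] = None


def apply_step3(
    p_observed: float,
    fraction: float,
    alpha: float = 0.05,
    planned_fractions: Sequence[float] = (),
    method: BoundaryMethod = BoundaryMethod.OBF_SPENDING,
) -> Step3Adjustment:
    """Threshold adjustment for early stopping and/or interim analyses.

    With full information and no interim looks the threshold is the design
    alpha, unchanged. Otherwise the analysis looks are the planned interim
    fractions at or below the achieved fraction, followed by the achieved
    fraction itself, and the required threshold is the final look's nominal
    two-sided P boundary.
    """
    if not 0 < p_observed <= 1:
        raise ValueError(f"observed P {p_observed} outside (0, 1]")
    if fraction <= 0:
        raise ValueError(f"information fraction {fraction} must be positive")
    fraction = min(fraction, 1.0)
    interim = tuple(t for t in planned_fractions if t < min(fraction, 1.0) - 1e-12)
    if fraction >= 1.0 and not interim:
        return Step3Adjustment(
            required_threshold=alpha,
            met=p_observed < alpha,
            adjusted_ci_level=1.0 - alpha,
            information_fraction=fraction,
            adjusted=False,
        )
    schedule = LookSchedule(fractions=interim + (fraction,), alpha_total=alpha)
    bset = boundaries(schedule, method)
    threshold = bset.looks[-1].nominal_p
    return Step3Adjustment(
        required_threshold=threshold,
        met=p_observed < threshold,
        adjusted_ci_level=adjusted_ci_level(threshold),
        information_fraction=fraction,
        adjusted=True,
        boundary_set=bset,
    )
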