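"""Synthetic two-arm trials and Monte-Carlo oracles.

Everything the calibration tests need is generated here: binomial two-arm
trials (simulated at the count level, no normal approximation, so small-n
behaviour is honest), accumulating-data trials analysed at interim looks,
families of independent test statistics for familywise-error studies, and
the sequential-statistic paths used as an independent oracle for
group-sequential boundary crossing probabilities.

Reproducibility: one documented generator family (NumPy ``default_rng``)
with an explicit seed everywhere. Replicate ``k`` of a configuration is
drawn from the substream ``default_rng([seed, k])``, so any single
replicate can be regenerated in isolation; batch estimates are plain
averages over those substreams. Every stochastic summary carries its
Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .effects import TwoByTwoTable
from .bayes import bayes_factor

__all__ = [
    "SimulationConfig",
    "MonteCarloRate",
    "simulate_binary_trial",
    "simulate_binary_trials",
    "wald_log_or",
    "look_z_paths",
    "estimate_type1_and_power",
    "bf_operating_characteristics",
    "simulate_pvalue_families",
    "mc_crossing_probability",
    "naive_repeated_analysis",
    "boundary_monitored_analysis",
    "final_only_analysis",
    "replicates_to_csv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """A synthetic two-arm binary trial configuration."""

    control_risk: float
    true_rr: float
    n_per_arm: int
    replicates: int
    seed: int
    looks: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.control_risk < 1:
            raise ValueError(f"control risk {self.control_risk} outside (0, 1)")
        p1 = self.true_rr * self.control_risk
        if not 0 <= p1 <= 1:
            raise ValueError(f"experimental risk {p1} outside [0, 1]")
        if self.n_per_arm < 1 or self.replicates < 1:
            raise ValueError("n_per_arm and replicates must be positive")
        if self.looks and (
            any(not 0 < t <= 1 for t in self.looks)
            or list(self.looks) != sorted(set(self.looks))
        ):
            raise ValueError("looks must be strictly increasing fractions in (0, 1]")

    @property
    def experimental_risk(self) -> float:
        return self.true_rr * self.control_risk


@dataclass(frozen=True)
class MonteCarloRate:
    rate: float
    mc_se: float
    replicates: int


def _rate(hits: np.ndarray) -> MonteCarloRate:
    r = float(np.mean(hits))
    n = int(hits.size)
    return MonteCarloRate(rate=r, mc_se=math.sqrt(r * (1.0 - r) / n), replicates=n)


def _rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([seed, replicate])


def simulate_binary_trial(config: SimulationConfig, replicate: int = 0) -> TwoByTwoTable:
    """One synthetic trial: binomial event counts in each arm."""
    rng = _rng(config.seed, replicate)
    n = config.n_per_arm
    ee = int(rng.binomial(n, config.experimental_risk))
    ec = int(rng.binomial(n, config.control_risk))
    return TwoByTwoTable(ee, n - ee, ec, n - ec)


def simulate_binary_trials(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Event counts ``(events_experimental, events_control)`` per replicate."""
    ee = np.empty(config.replicates, dtype=np.int64)
    ec = np.empty(config.replicates, dtype=np.int64)
    for k in range(config.replicates):
        rng = _rng(config.seed, k)
        ee[k] = rng.binomial(config.n_per_arm, config.experimental_risk)
        ec[k] = rng.binomial(config.n_per_arm, config.control_risk)
    return ee, ec


def wald_log_or(
    events_exp: np.ndarray, events_ctrl: np.ndarray, n_per_arm: np.ndarray | int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised log odds ratio and SE with Haldane correction for zero cells."""
    a = np.asarray(events_exp, dtype=float)
    c = np.asarray(events_ctrl, dtype=float)
    n = np.asarray(n_per_arm, dtype=float)
    b, d = n - a, n - c
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def look_z_paths(config: SimulationConfig) -> np.ndarray:
    """Wald log-OR z-statistics at each look, shape ``(replicates, n_looks)``.

    Per replicate, arm counts accumulate across looks (the increment
    between looks is an independent binomial on the additional patients),
    so the statistics have the canonical group-sequential correlation.
    A configuration without looks is treated as a single look at full
    information.
    """
    looks = config.looks or (1.0,)
    n_at = [max(1, round(t * config.n_per_arm)) for t in looks]
    z = np.empty((config.replicates, len(looks)))
    p1, p0 = config.experimental_risk, config.control_risk
    for k in range(config.replicates):
        rng = _rng(config.seed, k)
        ae = ac = 0
        prev = 0
        for j, n_j in enumerate(n_at):
            extra = n_j - prev
            ae += rng.binomial(extra, p1) if extra > 0 else 0
            ac += rng.binomial(extra, p0) if extra > 0 else 0
            prev = n_j
            log_or, se = wald_log_or(ae, ac, n_j)
            z[k, j] = log_or / se
    return z


def naive_repeated_analysis(alpha: float = 0.05) -> Callable[[np.ndarray], np.ndarray]:
    """Reject if any look's |z| exceeds the unadjusted two-sided critical value."""
    zcrit = float(norm.ppf(1 - alpha / 2))
    return lambda z: np.any(np.abs(z) >= zcrit, axis=1)


def boundary_monitored_analysis(
    z_boundaries: Sequence[float],
) -> Callable[[np.ndarray], np.ndarray]:
    """Reject if any look's |z| crosses its group-sequential boundary."""
    zb = np.asarray(z_boundaries, dtype=float)
    return lambda z: np.any(np.abs(z) >= zb[None, :], axis=1)


def final_only_analysis(alpha: float = 0.05) -> Callable[[np.ndarray], np.ndarray]:
    """Reject on the final look only, at the unadjusted threshold."""
    zcrit = float(norm.ppf(1 - alpha / 2))
    return lambda z: np.abs(z[:, -1]) >= zcrit


def estimate_type1_and_power(
    config: SimulationConfig, analysis: Callable[[np.ndarray], np.ndarray]
) -> MonteCarloRate:
    """Rejection rate of an analysis rule over simulated trials.

    ``analysis`` maps the ``(replicates, n_looks)`` matrix of z-statistics
    to a boolean rejection vector. Under the null (``true_rr = 1``) the
    rate estimates type-I error; under an effect it estimates power.
    """
    if config.replicates < 100:
        raise ValueError("need at least 100 replicates for a rate estimate")
    rejected = np.asarray(analysis(look_z_paths(config)), dtype=bool)
    if rejected.shape != (config.replicates,):
        raise ValueError("analysis handle returned a malformed rejection vector")
    return _rate(rejected)


@dataclass(frozen=True)
class BFOperatingCharacteristics:
    prop_bf_below_threshold: MonteCarloRate
    threshold: float
    theta_alt: float


def bf_operating_characteristics(
    config: SimulationConfig, theta_alt: float, threshold: float = 0.1
) -> BFOperatingCharacteristics:
    """Proportion of replicates whose Bayes factor falls below the threshold."""
    ee, ec = simulate_binary_trials(config)
    log_or, se = wald_log_or(ee, ec, config.n_per_arm)
    bf = np.exp((theta_alt**2 - 2.0 * log_or * theta_alt) / (2.0 * se**2))
    return BFOperatingCharacteristics(
        prop_bf_below_threshold=_rate(bf < threshold),
        threshold=threshold,
        theta_alt=theta_alt,
    )


def simulate_pvalue_families(
    n_families: int,
    means: Sequence[float],
    seed: int,
) -> np.ndarray:
    """Two-sided P-values from independent normal statistics, one row per family.

    ``means`` gives the per-comparison mean of the z statistic (0 for a
    true null); used to study familywise error under arbitrary
    configurations of true and false nulls.
    """
    mu = np.asarray(means, dtype=float)
    rng = np.random.default_rng([seed, 777])
    z = rng.standard_normal((n_families, mu.size)) + mu[None, :]
    return 2.0 * norm.sf(np.abs(z))


def mc_crossing_probability(
    fractions: Sequence[float],
    z_boundaries: Sequence[float],
    replicates: int,
    seed: int,
) -> MonteCarloRate:
    """Monte-Carlo oracle for group-sequential boundary crossing.

    Simulates the exact joint law of the sequential z statistics under the
    null (Brownian increments on the information scale, fully vectorised)
    and reports the probability of crossing any boundary.
    """
    t = np.asarray(fractions, dtype=float)
    zb = np.asarray(z_boundaries, dtype=float)
    if t.shape != zb.shape:
        raise ValueError("fractions and boundaries must align")
    rng = np.random.default_rng([seed, 424242])
    increments = rng.standard_normal((replicates, t.size)) * np.sqrt(np.diff(t, prepend=0.0))
    score = np.cumsum(increments, axis=1)
    z = score / np.sqrt(t)[None, :]
    return _rate(np.any(np.abs(z) >= zb[None, :], axis=1))


def replicates_to_csv(config: SimulationConfig) -> str:
    """Replicate-level results as CSV (counts, log OR, SE, Wald P, z)."""
    ee, ec = simulate_binary_trials(config)
    log_or, se = wald_log_or(ee, ec, config.n_per_arm)
    z = log_or / se
    p = 2.0 * norm.sf(np.abs(z))
    lines = ["replicate,events_experimental,events_control,n_per_arm,log_or,se_log_or,z,p"]
    for k in range(config.replicates):
        lines.append(
            f"{k},{ee[k]},{ec[k]},{config.n_per_arm},"
            f"{log_or[k]:.6g},{se[k]:.6g},{z[k]:.6g},{p[k]:.6g}"
        )
    return "\n".join(lines) + "\n"
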