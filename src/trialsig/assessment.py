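"""Five-step assessment of a randomised superiority trial.

Runs the whole procedure over a validated trial-specification document:

1. report the confidence interval and the exact P-value per outcome;
2. the Bayes factor of the primary outcome(s) against the alternative
   hypothesised in the sample-size calculation (plus a sceptical variant
   when that alternative is not based on a systematic review);
3. threshold adjustment for early stopping / interim analyses;
4. multiplicity adjustment across outcome comparisons;
5. clinical significance, gated on all four earlier steps passing and a
   Bayes factor below its threshold.

The report is deterministic: identical documents give byte-identical JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import clinical as clin
from . import design as dsg
from . import multiplicity as mult
from . import sequential as seq
from .bayes import (
    AlternativeHypothesis,
    BayesFactorResult,
    bayes_factor,
    sceptical_alternative,
)
from .effects import (
    Direction,
    EffectEstimate,
    Measure,
    TwoByTwoTable,
    ci_from_se,
    effects_from_table,
    p_from_estimate,
    AnalysisScaleValue,
    Scale,
)

__all__ = [
    "ResultSpec",
    "OutcomeSpec",
    "DesignSpec",
    "LooksSpec",
    "MultiplicitySpec",
    "ClinicalSpec",
    "TrialSpecification",
    "Verdict",
    "StepResult",
    "AssessmentReport",
    "read_specification",
    "load_specification",
    "run_assessment",
    "render_report",
    "example_path",
]

SCHEMA_VERSION = "1"


# --------------------------------------------------------------------------
# document schema
# --------------------------------------------------------------------------


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ResultSpec(_Model):
    """One outcome's observed result: estimate+CI, estimate+P, or a 2x2 table."""

    measure: Literal["or", "rr", "hr", "md"] = "or"
    estimate: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    se: Optional[float] = Field(default=None, gt=0)
    p: Optional[float] = Field(default=None, gt=0, le=1)
    events_experimental: Optional[int] = Field(default=None, ge=0)
    n_experimental: Optional[int] = Field(default=None, gt=0)
    events_control: Optional[int] = Field(default=None, ge=0)
    n_control: Optional[int] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _one_shape(self) -> "ResultSpec":
        counts = [self.events_experimental, self.n_experimental, self.events_control, self.n_control]
        has_counts = all(v is not None for v in counts)
        if any(v is not None for v in counts) and not has_counts:
            raise ValueError("a 2x2 result needs all four of events/n per arm")
        has_ci = self.ci_lower is not None and self.ci_upper is not None
        if self.estimate is not None and not (has_ci or self.p is not None or self.se is not None):
            raise ValueError("an estimate needs a CI, an SE or a P-value alongside it")
        if self.estimate is None and not has_counts:
            raise ValueError("result needs either an estimate or a 2x2 table of counts")
        return self


class OutcomeSpec(_Model):
    id: str
    role: Literal["primary", "secondary", "exploratory"] = "secondary"
    result: Optional[ResultSpec] = None
    direction_of_benefit: Literal["less_than_null", "greater_than_null"] = "less_than_null"
    timepoints_assessed: int = Field(default=1, ge=1)
    weight: float = Field(default=0.0, ge=0)


class EffectSpecModel(_Model):
    type: Literal["rr", "or", "hr", "md"]
    value: float
    systematic_review_based: bool = False


class DesignSpec(_Model):
    outcome_type: Literal["binary", "continuous"] = "binary"
    effect: EffectSpecModel
    control_risk: Optional[float] = Field(default=None, gt=0, lt=1)
    sd: Optional[float] = Field(default=None, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    power: float = Field(default=0.80, gt=0, lt=1)
    planned_n_total: int = Field(gt=0)
    allocation_ratio: float = Field(default=1.0, gt=0)

    def to_design(self) -> dsg.TrialDesign:
        return dsg.TrialDesign(
            outcome_type=dsg.OutcomeType(self.outcome_type),
            effect=dsg.EffectAssumption(
                self.effect.type, self.effect.value, self.effect.systematic_review_based
            ),
            alpha=self.alpha,
            power=self.power,
            planned_n_total=self.planned_n_total,
            control_risk=self.control_risk,
            sd=self.sd,
            allocation_ratio=self.allocation_ratio,
        )


class LooksSpec(_Model):
    planned_fractions: list[float] = Field(default_factory=list)
    performed_looks: int = Field(default=0, ge=0)
    stopped_at_fraction: Optional[float] = Field(default=None, gt=0, le=1)


class MultiplicitySpec(_Model):
    procedure: Literal["bonferroni", "hommel", "fixed_sequence", "fallback", "none"] = "none"
    alpha_family: Optional[float] = Field(default=None, gt=0, lt=1)
    include_exploratory: bool = False


class ClinicalSpec(_Model):
    mcid: Optional[float] = None
    mcid_scale: Literal["ratio", "log", "identity"] = "ratio"


class TrialSpecification(_Model):
    """The validated trial specification + results document."""

    schema_version: str = SCHEMA_VERSION
    title: str = ""
    design: DesignSpec
    n_randomised: int = Field(gt=0)
    outcomes: list[OutcomeSpec] = Field(min_length=1)
    looks: Optional[LooksSpec] = None
    multiplicity: MultiplicitySpec = Field(default_factory=MultiplicitySpec)
    clinical: Optional[ClinicalSpec] = None
    extra_alternatives: list[EffectSpecModel] = Field(default_factory=list)
    bf_threshold: float = Field(default=0.1, gt=0, lt=1)
    p_threshold: float = Field(default=0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _checks(self) -> "TrialSpecification":
        ids = [o.id for o in self.outcomes]
        if len(set(ids)) != len(ids):
            raise ValueError("outcome ids must be unique")
        return self

    def primary_outcomes(self) -> list[OutcomeSpec]:
        return [o for o in self.outcomes if o.role == "primary"]


def read_specification(text: str) -> TrialSpecification:
    """Parse and validate a JSON (or YAML) trial-specification document."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("specification document must be a mapping")
    return TrialSpecification.model_validate(data)


def load_specification(path: str | Path) -> TrialSpecification:
    return read_specification(Path(path).read_text())


def example_path(name: str) -> Path:
    """Path to a packaged worked-example specification (example1/2/3)."""
    p = Path(__file__).parent / "examples" / f"{name}.json"
    if not p.exists():
        raise FileNotFoundError(f"no packaged example {name!r}")
    return p


# --------------------------------------------------------------------------
# report model
# --------------------------------------------------------------------------


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    WARNING = "warning"
    NOT_ASSESSED = "not_assessed"


_STEP_NAMES = {
    1: "Confidence intervals and exact P-values",
    2: "Bayes factor for the primary outcome",
    3: "Adjustment for early stopping / interim analyses",
    4: "Adjustment for multiplicity",
    5: "Clinical significance",
}


@dataclass
class StepResult:
    step: int
    verdict: Verdict
    values: dict[str, Any] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return _STEP_NAMES[self.step]

    def passed(self) -> bool:
        return self.verdict is Verdict.PASS


@dataclass
class AssessmentReport:
    title: str
    steps: list[StepResult]
    overall_interpretation: str
    bf_results: list[dict[str, Any]]

    def step(self, k: int) -> StepResult:
        return self.steps[k - 1]

    def verdict_pattern(self) -> tuple[str, ...]:
        return tuple(s.verdict.value for s in self.steps)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "title": self.title,
            "steps": [
                {
                    "step": s.step,
                    "name": s.name,
                    "verdict": s.verdict.value,
                    "values": s.values,
                    "notes": s.notes,
                }
                for s in self.steps
            ],
            "overall_interpretation": self.overall_interpretation,
            "bf_results": self.bf_results,
        }


# --------------------------------------------------------------------------
# resolution helpers
# --------------------------------------------------------------------------


@dataclass
class _Resolved:
    outcome: OutcomeSpec
    theta: float
    se: float
    p: float
    ci_reporting: tuple[float, float]
    measure: Measure
    risk_experimental: Optional[float] = None
    risk_control: Optional[float] = None


def _resolve_outcome(o: OutcomeSpec) -> _Resolved:
    r = o.result
    direction = Direction(o.direction_of_benefit)
    if r.events_experimental is not None:
        table = TwoByTwoTable.from_margins(
            r.events_experimental, r.n_experimental, r.events_control, r.n_control
        )
        eff = effects_from_table(table)
        theta, se = eff.log_or, eff.se_log_or
        p = p_from_estimate(AnalysisScaleValue(theta, Scale.LOG, Measure.OR), se)
        ci = ci_from_se(AnalysisScaleValue(theta, Scale.LOG, Measure.OR), se, r.ci_level)
        return _Resolved(
            o, theta, se, p, ci, Measure.OR, eff.risk_experimental, eff.risk_control
        )
    est = EffectEstimate(
        measure=Measure(r.measure),
        point=r.estimate,
        ci_lower=r.ci_lower,
        ci_upper=r.ci_upper,
        ci_level=r.ci_level,
        se=r.se,
        p_two_sided=r.p,
        direction_of_benefit=direction,
    )
    theta_v, se, p = est.resolve()
    if r.ci_lower is not None:
        ci = (r.ci_lower, r.ci_upper)
    else:
        ci = ci_from_se(theta_v, se, r.ci_level)
    return _Resolved(o, theta_v.value, se, p, ci, est.measure)


def _bf_entry(label: str, outcome_id: str, res: BayesFactorResult) -> dict[str, Any]:
    return {
        "outcome": outcome_id,
        "alternative": label,
        "theta_obs": res.theta_obs,
        "se": res.se,
        "theta_alt": res.theta_alt,
        "bf": res.bf,
        "log_bf": res.log_bf,
        "classification": res.classification.value,
        "threshold": res.threshold,
    }


# --------------------------------------------------------------------------
# the five steps
# --------------------------------------------------------------------------


def run_assessment(spec: TrialSpecification) -> AssessmentReport:
    """Run the five-step procedure and assemble the report."""
    resolved: list[_Resolved] = []
    failures: list[str] = []
    for o in spec.outcomes:
        if o.result is None:
            continue
        try:
            resolved.append(_resolve_outcome(o))
        except ValueError as exc:  # collect every offending outcome id
            failures.append(f"{o.id}: {exc}")
    if failures:
        raise ValueError("unresolvable outcome results: " + "; ".join(failures))

    primaries = spec.primary_outcomes()
    focus = [r for r in resolved if r.outcome.role == "primary"]
    no_primary = not primaries
    if no_primary:
        focus = resolved  # fall back to every reported outcome, with a warning

    steps: list[StepResult] = []

    # step 1 -- report CI and exact P; significance at the stated threshold
    s1_values = {
        r.outcome.id: {
            "measure": r.measure.value,
            "theta": r.theta,
            "se": r.se,
            "ci": list(r.ci_reporting),
            "p": r.p,
        }
        for r in resolved
    }
    s1 = StepResult(1, Verdict.PASS, values=s1_values)
    for o in spec.outcomes:
        if o.result is None:
            s1.notes.append(f"outcome {o.id!r}: no result supplied")
    if not resolved:
        s1.verdict = Verdict.FAIL
        s1.notes.append("no outcome results to report")
    elif not all(r.p < spec.p_threshold for r in focus):
        s1.verdict = Verdict.FAIL
        s1.notes.append(
            f"observed P above the {spec.p_threshold:g} threshold for a focus outcome"
        )
    steps.append(s1)

    # step 2 -- Bayes factor(s) against the design alternative
    design = spec.design.to_design()
    design_alt = design.alternative()
    bf_results: list[dict[str, Any]] = []
    principal_bfs: list[float] = []
    for r in focus:
        res = bayes_factor(r.theta, r.se, design_alt.theta_alt, spec.bf_threshold)
        principal_bfs.append(res.bf)
        bf_results.append(_bf_entry("sample_size_calculation", r.outcome.id, res))
        for extra in spec.extra_alternatives:
            alt = dsg.TrialDesign(
                outcome_type=design.outcome_type,
                effect=dsg.EffectAssumption(extra.type, extra.value, extra.systematic_review_based),
                alpha=design.alpha,
                power=design.power,
                planned_n_total=design.planned_n_total,
                control_risk=design.control_risk,
                sd=design.sd,
            ).alternative()
            res_x = bayes_factor(r.theta, r.se, alt.theta_alt, spec.bf_threshold)
            bf_results.append(_bf_entry(f"user:{extra.type}={extra.value:g}", r.outcome.id, res_x))
        if not spec.design.effect.systematic_review_based and design_alt.original_ratio:
            sc = sceptical_alternative(design_alt)
            res_s = bayes_factor(r.theta, r.se, sc.theta_alt, spec.bf_threshold)
            bf_results.append(_bf_entry("sceptical", r.outcome.id, res_s))
    s2 = StepResult(2, Verdict.PASS, values={"bf_threshold": spec.bf_threshold})
    if no_primary:
        s2.notes.append(
            "no primary outcome declared; Bayes factors computed for all reported outcomes"
        )
    if not focus:
        s2.verdict = Verdict.FAIL
        s2.notes.append("no resolvable outcome to compute a Bayes factor for")
    elif any(bf >= spec.bf_threshold for bf in principal_bfs):
        s2.verdict = Verdict.FAIL
        s2.notes.append(
            f"Bayes factor at or above the {spec.bf_threshold:g} threshold: the data do not "
            "support the intervention effect hypothesised in the sample size calculation"
        )
    s2.values["bf"] = {
        e["outcome"]: e["bf"] for e in bf_results if e["alternative"] == "sample_size_calculation"
    }
    steps.append(s2)

    # step 3 -- sequential adjustment
    fraction = dsg.information_fraction(spec.n_randomised, spec.design.planned_n_total)
    planned = tuple(spec.looks.planned_fractions) if spec.looks else ()
    s3 = StepResult(3, Verdict.PASS, values={"information_fraction": fraction})
    if focus:
        adjustments = [
            seq.apply_step3(r.p, fraction, spec.design.alpha, planned) for r in focus
        ]
        adj = adjustments[0]
        s3.values["required_threshold"] = adj.required_threshold
        s3.values["adjusted_ci_level"] = adj.adjusted_ci_level
        s3.values["adjusted"] = adj.adjusted
        if not adj.adjusted:
            s3.notes.append("planned sample size reached and no interim analyses: no adjustment")
        else:
            s3.notes.append(
                "threshold tightened by O'Brien-Fleming-type alpha spending at the achieved "
                "information fraction; the matching repeated-confidence-interval level is "
                f"{adj.adjusted_ci_level:.4f}"
            )
        if not all(a.met for a in adjustments):
            s3.verdict = Verdict.FAIL
            s3.notes.append("observed P does not meet the sequentially adjusted threshold")
    else:
        s3.verdict = Verdict.FAIL
        s3.notes.append("no resolvable outcome")
    steps.append(s3)

    # step 4 -- multiplicity
    family_alpha = spec.multiplicity.alpha_family or spec.p_threshold
    members = [
        mult.Comparison(
            id=r.outcome.id,
            p_raw=r.p,
            role=mult.Role(r.outcome.role),
            order_index=i,
            weight=r.outcome.weight,
        )
        for i, r in enumerate(resolved)
    ]
    non_exploratory = [c for c in members if c.role is not mult.Role.EXPLORATORY]
    s4 = StepResult(4, Verdict.PASS, values={"procedure": spec.multiplicity.procedure})
    n_comparisons = sum(
        o.timepoints_assessed for o in spec.outcomes if o.role != "exploratory"
    )
    s4.values["n_outcome_comparisons"] = n_comparisons
    if no_primary:
        s4.verdict = Verdict.FAIL
        s4.notes.append(
            "no clear definition of a primary outcome: the P-value should have been "
            "adjusted for multiplicity over the outcome hierarchy"
        )
    elif spec.multiplicity.procedure == "none" and n_comparisons > 1:
        s4.verdict = Verdict.WARNING
        s4.notes.append(
            "more than one non-exploratory outcome comparison but no multiplicity "
            "procedure specified"
        )
    if non_exploratory:
        family = mult.ComparisonFamily(
            comparisons=members,
            alpha_family=family_alpha,
            procedure=mult.Procedure(spec.multiplicity.procedure),
            include_exploratory=spec.multiplicity.include_exploratory,
        )
        adjusted = mult.adjust(family)
        s4.values["adjusted"] = [
            {
                "id": a.id,
                "p_raw": a.p_raw,
                "p_adjusted": a.p_adjusted,
                "local_alpha": a.local_alpha,
                "tested": a.tested,
                "rejected": a.rejected,
            }
            for a in adjusted
        ]
        if s4.verdict is Verdict.PASS:
            primary_ids = {o.id for o in primaries}
            primary_adj = [a for a in adjusted if a.id in primary_ids]
            if primary_adj and not all(a.rejected for a in primary_adj):
                s4.verdict = Verdict.FAIL
                s4.notes.append("a primary outcome loses significance after adjustment")
            elif spec.multiplicity.procedure == "none" and n_comparisons == 1:
                s4.notes.append("single pre-specified comparison: no adjustment needed")
    exploratory_ids = [c.id for c in members if c.role is mult.Role.EXPLORATORY]
    if exploratory_ids and not spec.multiplicity.include_exploratory:
        s4.notes.append(
            "exploratory outcomes excluded from the family; interpret conservatively: "
            + ", ".join(exploratory_ids)
        )
    steps.append(s4)

    # step 5 -- clinical significance, gated
    gate_bf = min(principal_bfs) if principal_bfs else math.inf
    gate = clin.clinical_gate(
        {k: steps[k - 1].passed() for k in (1, 2, 3, 4)}, gate_bf, spec.bf_threshold
    )
    s5 = StepResult(5, Verdict.PASS if gate else Verdict.NOT_ASSESSED)
    s5.values["gate"] = gate
    if not gate:
        s5.notes.append(
            "clinical significance is only assessed when statistical significance has been "
            "obtained in all four preceding steps and the Bayes factor is below "
            f"{spec.bf_threshold:g}"
        )
    descriptive = None
    for r in focus:
        if r.risk_control is not None and r.risk_control != r.risk_experimental:
            nn = clin.nnt_nnh(
                r.risk_control,
                r.risk_experimental,
                Direction(r.outcome.direction_of_benefit),
            )
            descriptive = {
                "outcome": r.outcome.id,
                "kind": nn.kind.value,
                "value": nn.value,
                "risk_difference": nn.risk_difference,
            }
            s5.values["number_needed"] = descriptive
            label = "number-needed-to-treat" if nn.kind is clin.NNTKind.NNT else "number-needed-to-harm"
            s5.notes.append(
                f"{label} for {r.outcome.id!r}: {nn.value} "
                f"(risk difference {nn.risk_difference:+.3f})"
            )
            break
    if gate and spec.clinical and spec.clinical.mcid is not None:
        mcid = spec.clinical.mcid
        if spec.clinical.mcid_scale == "ratio":
            mcid = math.log(mcid)
        ref = focus[0]
        lo, hi = ref.ci_reporting
        if ref.measure.is_ratio:
            lo, hi = math.log(lo), math.log(hi)
        cmp_res = clin.compare_to_mcid(
            ref.theta, lo, hi, mcid, Direction(ref.outcome.direction_of_benefit)
        )
        s5.values["mcid"] = {
            "mcid_analysis_scale": mcid,
            "mcid_met": cmp_res.mcid_met,
            "ci_excludes_mcid_shortfall": cmp_res.ci_excludes_mcid_shortfall,
        }
    if gate:
        s5.notes.append(
            "a further assessment of the balance between beneficial and harmful effects "
            "should also be performed"
        )
    steps.append(s5)

    overall = _overall(steps, gate, principal_bfs, spec)
    return AssessmentReport(
        title=spec.title, steps=steps, overall_interpretation=overall, bf_results=bf_results
    )


def _overall(
    steps: list[StepResult],
    gate: bool,
    principal_bfs: list[float],
    spec: TrialSpecification,
) -> str:
    if gate:
        return (
            "Statistical significance was reached according to all of the first four steps "
            "and the Bayes factor supports the hypothesised intervention effect; clinical "
            "significance has been assessed."
        )
    if principal_bfs and max(principal_bfs) >= 1.0 / spec.bf_threshold:
        return (
            "The trial result is far more compatible with a null (or opposite-direction) "
            "effect than with the intervention effect hypothesised in the sample size "
            "calculation; clinical significance was not assessed."
        )
    failed = [s.step for s in steps[:4] if not s.passed()]
    if failed:
        return (
            "Statistical significance was not adequately demonstrated (step"
            + ("s " if len(failed) > 1 else " ")
            + ", ".join(str(k) for k in failed)
            + "); the results should be interpreted with caution and clinical significance "
            "was not assessed."
        )
    return (
        "Statistical significance thresholds were met but the Bayes factor does not "
        "clearly support the hypothesised effect; clinical significance was not assessed."
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _fmt_bf(bf: float) -> str:
    if bf >= 1000:
        return f"{bf:,.0f}"
    if bf >= 10:
        return f"{bf:.1f}"
    return f"{bf:.2f}"


def _fmt_p(p: float) -> str:
    return f"{p:.2g}" if p < 0.001 else f"{p:.4g}"


def render_report(report: AssessmentReport, format: str = "json") -> str:
    """Render a report as machine-diffable JSON or the five-point markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=False, allow_nan=False) + "\n"
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    lines = [f"# Five-step assessment: {report.title}" if report.title else "# Five-step assessment", ""]
    for s in report.steps:
        lines.append(f"## Step {s.step}: {s.name}")
        lines.append(f"Verdict: **{s.verdict.value}**")
        if s.step == 1:
            for oid, v in s.values.items():
                if not isinstance(v, dict):
                    continue
                lo, hi = v["ci"]
                lines.append(
                    f"- {oid}: {v['measure'].upper()} scale, log effect {v['theta']:.2f} "
                    f"(SE {v['se']:.3f}), CI {lo:.3g} to {hi:.3g}, P = {_fmt_p(v['p'])}"
                )
        if s.step == 2:
            for e in report.bf_results:
                lines.append(
                    f"- {e['outcome']} vs {e['alternative']}: Bayes factor = "
                    f"{_fmt_bf(e['bf'])} ({e['classification']})"
                )
        if s.step == 3 and "required_threshold" in s.values:
            lines.append(
                f"- information fraction {s.values['information_fraction']:.3f}, required "
                f"threshold {_fmt_p(s.values['required_threshold'])}"
            )
        if s.step == 4 and "adjusted" in s.values:
            for a in s.values["adjusted"]:
                padj = "-" if a["p_adjusted"] is None else _fmt_p(a["p_adjusted"])
                lines.append(
                    f"- {a['id']}: raw P {_fmt_p(a['p_raw'])}, adjusted P {padj}, "
                    f"{'rejected' if a['rejected'] else 'not rejected'}"
                )
        if s.step == 5 and "number_needed" in s.values:
            nn = s.values["number_needed"]
            lines.append(f"- {nn['kind']} = {nn['value']} for {nn['outcome']}")
        for note in s.notes:
            lines.append(f"- note: {note}")
        lines.append("")
    lines.append("## Interpretation")
    lines.append(report.overall_interpretation)
    lines.append("")
    return "\n".join(lines)
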