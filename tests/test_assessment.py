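"""End-to-end five-step assessment: schema validation, verdicts, rendering, CLI."""

import json
import warnings

import pytest
from click.testing import CliRunner
from pydantic import ValidationError

from trialsig import assessment
from trialsig.assessment import (
    TrialSpecification,
    read_specification,
    render_report,
    run_assessment,
)
from trialsig.cli import main as cli_main


def minimal_spec(**overrides) -> dict:
    doc = {
        "design": {
            "effect": {"type": "rr", "value": 0.8},
            "control_risk": 0.5,
            "planned_n_total": 800,
        },
        "n_randomised": 800,
        "outcomes": [
            {
                "id": "mortality",
                "role": "primary",
                "result": {"measure": "or", "estimate": 0.6, "p": 0.001},
            }
        ],
    }
    doc.update(overrides)
    return doc


class TestSchema:
    def test_unknown_fields_rejected_with_path(self):
        doc = minimal_spec()
        doc["design"]["typo_field"] = 1
        with pytest.raises(ValidationError) as exc:
            TrialSpecification.model_validate(doc)
        assert "typo_field" in str(exc.value)

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValidationError):
            TrialSpecification.model_validate(minimal_spec(outcomes=[]))

    def test_all_errors_enumerated(self):
        doc = minimal_spec()
        doc["bf_threshold"] = 2.0
        doc["p_threshold"] = -1.0
        with pytest.raises(ValidationError) as exc:
            TrialSpecification.model_validate(doc)
        assert exc.value.error_count() >= 2

    def test_result_needs_a_complete_shape(self):
        doc = minimal_spec()
        doc["outcomes"][0]["result"] = {"events_experimental": 10, "n_experimental": 100}
        with pytest.raises(ValidationError):
            TrialSpecification.model_validate(doc)

    def test_yaml_dialect_accepted(self):
        text = (
            "design:\n"
            "  effect: {type: rr, value: 0.8}\n"
            "  control_risk: 0.5\n"
            "  planned_n_total: 800\n"
            "n_randomised: 800\n"
            "outcomes:\n"
            "  - id: mortality\n"
            "    role: primary\n"
            "    result: {measure: or, estimate: 0.6, p: 0.001}\n"
        )
        spec = read_specification(text)
        assert spec.outcomes[0].id == "mortality"

    def test_round_trip_is_identity(self):
        spec = TrialSpecification.model_validate(minimal_spec())
        again = read_specification(spec.model_dump_json())
        assert again == spec


class TestWorkedExamples:
    def test_verdict_patterns(self, example_reports):
        assert example_reports["example1"].verdict_pattern() == (
            "pass", "fail", "pass", "fail", "not_assessed",
        )
        assert example_reports["example2"].verdict_pattern() == (
            "pass", "pass", "pass", "pass", "pass",
        )
        assert example_reports["example3"].verdict_pattern() == (
            "pass", "fail", "pass", "pass", "not_assessed",
        )

    def test_multivitamin_bayes_factors_far_above_threshold(self, example_reports):
        entries = {
            e["alternative"]: e["bf"] for e in example_reports["example1"].bf_results
        }
        assert entries["sample_size_calculation"] >= 10
        assert entries["user:or=0.7"] >= 1e6

    def test_tranexamic_bf_and_gate(self, example_reports):
        rep = example_reports["example2"]
        bf = rep.bf_results[0]["bf"]
        assert round(bf, 2) == 0.01
        assert rep.step(5).values["gate"] is True

    def test_starch_reports_descriptive_nnh(self, example_reports):
        rep = example_reports["example3"]
        nn = rep.step(5).values["number_needed"]
        assert nn["kind"] == "NNH"
        assert nn["value"] == 13
        assert rep.step(5).verdict.value == "not_assessed"
        assert rep.bf_results[0]["classification"] == "supports_null"

    def test_no_primary_outcome_triggers_multiplicity_failure(self, example_reports):
        s4 = example_reports["example1"].step(4)
        assert s4.verdict.value == "fail"
        assert any("primary outcome" in note for note in s4.notes)

    def test_sceptical_bf_reported_when_not_review_based(self, example_reports):
        for name in ("example1", "example2", "example3"):
            alts = [e["alternative"] for e in example_reports[name].bf_results]
            assert "sceptical" in alts


class TestDeterminismAndRendering:
    def test_reports_are_byte_identical(self, example_specs):
        for spec in example_specs.values():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = render_report(run_assessment(spec), "json")
                b = render_report(run_assessment(spec), "json")
            assert a == b

    def test_json_render_is_idempotent(self, example_reports):
        text = render_report(example_reports["example2"], "json")
        parsed = json.loads(text)
        assert json.dumps(parsed, indent=2, sort_keys=False, allow_nan=False) + "\n" == text

    def test_markdown_shows_rounded_bf(self, example_reports):
        md = render_report(example_reports["example2"], "markdown")
        assert "Bayes factor = 0.01" in md

    def test_markdown_explains_closed_gate(self, example_reports):
        md = render_report(example_reports["example3"], "markdown")
        assert "not_assessed" in md
        assert "only assessed when" in md

    def test_unknown_format_rejected(self, example_reports):
        with pytest.raises(ValueError):
            render_report(example_reports["example1"], "pdf")


class TestVerdictMonotonicity:
    def test_worsening_p_never_flips_fail_to_pass(self):
        base = run_assessment(TrialSpecification.model_validate(minimal_spec()))
        doc = minimal_spec()
        doc["outcomes"][0]["result"]["p"] = 0.2
        worse = run_assessment(TrialSpecification.model_validate(doc))
        order = {"pass": 0, "warning": 1, "fail": 2, "not_assessed": 2}
        for sb, sw in zip(base.steps, worse.steps):
            assert order[sw.verdict.value] >= order[sb.verdict.value]

    def test_unresolvable_outcome_lists_offender(self):
        doc = minimal_spec()
        doc["outcomes"][0]["result"] = {"measure": "or", "estimate": 0.6, "p": 1.0}
        spec = TrialSpecification.model_validate(doc)
        with pytest.raises(ValueError, match="mortality"):
            run_assessment(spec)


class TestCLI:
    def test_assess_json_output(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["assess", "--spec", str(assessment.example_path("example2"))]
        )
        assert result.exit_code == 0
        payload = json.loads(result.output)
        assert [s["verdict"] for s in payload["steps"]] == ["pass"] * 5

    def test_assess_validation_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"n_randomised": 10}')
        result = CliRunner().invoke(cli_main, ["assess", "--spec", str(bad)])
        assert result.exit_code == 2

    def test_bf_subcommand(self):
        result = CliRunner().invoke(
            cli_main, ["bf", "--theta-obs", "-0.12", "--se", "0.04", "--theta-alt", "-0.11"]
        )
        assert result.exit_code == 0
        assert "supports_alternative" in result.output

    def test_boundaries_subcommand(self):
        result = CliRunner().invoke(
            cli_main, ["boundaries", "--alpha", "0.05", "--fractions", "0.5,1.0"]
        )
        assert result.exit_code == 0
        assert len(result.output.strip().split("\n")) == 3

    def test_samplesize_subcommand(self):
        result = CliRunner().invoke(
            cli_main, ["samplesize", "--p0", "0.5", "--p1", "0.4"]
        )
        assert result.exit_code == 0
        assert "n_per_group=385" in result.output

    def test_simulate_subcommand(self):
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--control-risk", "0.2", "--rr", "0.9", "--n-per-arm", "100",
             "--replicates", "10", "--seed", "4"],
        )
        assert result.exit_code == 0
        assert len(result.output.strip().split("\n")) == 11
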