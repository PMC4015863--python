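import warnings

import pytest

from trialsig import assessment


def run_example(name: str) -> assessment.AssessmentReport:
    spec = assessment.load_specification(assessment.example_path(name))
    with warnings.catch_warnings():
        # over-recruited trials clamp the information fraction with a warning
        warnings.simplefilter("ignore")
        return assessment.run_assessment(spec)


@pytest.fixture(scope="session")
def example_reports() -> dict[str, assessment.AssessmentReport]:
    return {name: run_example(name) for name in ("example1", "example2", "example3")}


@pytest.fixture(scope="session")
def example_specs() -> dict[str, assessment.TrialSpecification]:
    return {
        name: assessment.load_specification(assessment.example_path(name))
        for name in ("example1", "example2", "example3")
    }
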