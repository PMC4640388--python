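"""Shared fixtures: packaged models and medium-sized simulated cohorts.

Expensive cohorts are session-scoped and reused across test modules; every
simulation is fully determined by its spec, so sharing does not couple
tests.
"""

import pytest

import ydrisk


@pytest.fixture(scope="session")
def model_us():
    """Packaged parameters with U.S. prevalences (the tool's denominator)."""
    return ydrisk.read_params(prevalence_source="us")


@pytest.fixture(scope="session")
def model_nhs():
    """Packaged parameters with the validation cohort's observed prevalences."""
    return ydrisk.read_params(prevalence_source="nhs")


@pytest.fixture(scope="session")
def overall_counts():
    """Published overall per-category subject/case counts."""
    return (
        ydrisk.read_published_category_counts("overall")
        .set_index("category")[["n", "cases"]]
    )


@pytest.fixture(scope="session")
def consensus_scored(model_us, model_nhs):
    """50k-subject cohort drawn at cohort prevalences with consensus effect
    RRs, scored with the tool's own parameters."""
    spec = ydrisk.CohortSpec(n_subjects=50_000, random_seed=20260926)
    cohort = ydrisk.simulate_cohort(spec, model_nhs)
    return ydrisk.score_cohort(model_us, cohort)


def make_binary_model(p_exposed=0.5, rr=2.0, factor_id="x"):
    """A one-factor model with a binary exposure."""
    factor = ydrisk.FactorDefinition(
        factor_id=factor_id,
        levels=(
            ydrisk.FactorLevel("ref", 1.0, 1.0 - p_exposed),
            ydrisk.FactorLevel("exp", rr, p_exposed),
        ),
        reference_level="ref",
    )
    return ydrisk.RiskModel(factors=(factor,))
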