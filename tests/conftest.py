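import pytest

from vaultshape import synthetic
from vaultshape.pipeline import StudyConfig, run_study
from vaultshape.synthetic import CohortConfig


@pytest.fixture(scope="session")
def template():
    """Small symmetric vault template (290 vertices)."""
    return synthetic.build_symmetric_template(3)


@pytest.fixture(scope="session")
def template_fine():
    """Working-resolution template (2050 vertices)."""
    return synthetic.build_symmetric_template(8)


@pytest.fixture(scope="session")
def deformed_subject(template_fine):
    """Noise-free right-sided case of severity 0.8."""
    spec = synthetic.SubjectSpec(
        subject_id="case", group="UCS", laterality="right",
        severity=0.8, noise_scale=0.0, seed=11,
    )
    return synthetic.synthesize_subject(template_fine, spec)


@pytest.fixture(scope="session")
def small_cohort():
    """12 UCS + 6 controls at low resolution, for structural tests."""
    config = CohortConfig(
        n_ucs=12, n_controls=6, template_subdivisions=4, master_seed=42
    )
    return synthetic.synthesize_cohort(config)


@pytest.fixture(scope="session")
def small_study():
    """Complete desk-scale study run shared by pipeline tests."""
    config = StudyConfig(
        cohort=CohortConfig(
            n_ucs=14, n_controls=8, template_subdivisions=4, master_seed=3
        ),
        ranking_n_ucs=8,
        ranking_n_controls=2,
        mcmc_steps=500,
        mcmc_burn_in=200,
        master_seed=3,
    )
    config.index.dice_resolution = 3.0
    return run_study(config)
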