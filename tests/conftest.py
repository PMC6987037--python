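import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def small_config():
    """A two-strain, few-batch study for fast pipeline tests."""
    from probenum import NoiseModel, PipelineConfig, StudyDesign

    design = StudyDesign(
        n_batches_per_strain={"NCFM": 3, "Bl-04": 2},
        plate_replicates=5,
        well_replicates=3,
        flow_replicates=3,
        seed=7,
    )
    return PipelineConfig(design=design, noise=NoiseModel())
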