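import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_annotations():
    from mitoasym.refdata import reference_annotation

    return reference_annotation()


@pytest.fixture(scope="session")
def toy_genome():
    """Non-overlapping synthetic genome: every CDS contract holds exactly."""
    from mitoasym.simulate import generate_genome, toy_genome_spec

    genome, _ = generate_genome(toy_genome_spec(seed=3))
    return genome


@pytest.fixture(scope="session")
def table2_genome(ref_annotations):
    """Synthetic genome laid out with the real reference coordinates."""
    from mitoasym.simulate import GenomeSpec, generate_genome, table2_layout

    spec = GenomeSpec(layout=table2_layout(ref_annotations), seed=42)
    genome, _ = generate_genome(spec)
    return genome
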