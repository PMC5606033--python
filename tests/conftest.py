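import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from omicsfed.synth import SynthSpec, generate_federation, reference_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """The curated two-source worked-example federation."""
    return reference_fixture()


@pytest.fixture(scope="session")
def fixture_fed(fixture_bundle):
    """Worked-example federation with discovered sameAs links loaded."""
    return fixture_bundle.linked_federation()


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic federation at default study conditions."""
    return generate_federation(SynthSpec(seed=11))


#: Reduced problem size used when many federations are generated in a loop.
SMALL_SPEC = dict(
    n_genes=8, n_samples=6, n_cnv_segments=10, n_methyl_sites=12,
    n_mutations=20, go_per_gene=1,
)
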