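import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from acmgrules import AnnotatedVariant, EngineConfig, FixtureSpec, ReferenceBundle
from acmgrules.fixtures_validation import generate_fixtures


@pytest.fixture(scope="session")
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture()
def empty_bundle() -> ReferenceBundle:
    return ReferenceBundle()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The default scenario suite generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(FixtureSpec(seed=1), out)


@pytest.fixture(scope="session")
def make_variant():
    """Factory for minimal annotated variants with overridable fields."""

    def _make(chrom="1", pos=1000, ref="A", alt="T", **kw) -> AnnotatedVariant:
        return AnnotatedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)

    return _make
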