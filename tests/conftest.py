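import pytest
from hypothesis import settings

from matloci import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return synthetic.build_default_panel()


@pytest.fixture(scope="session")
def mono_strain():
    """One monokaryon (Type2, with P/R locus) plus its truth table."""
    spec = synthetic.StrainSpec("mono1", "mono", ("Type2",), ("a1",), ("b1",))
    return synthetic.generate_strain(spec, seed=101)


@pytest.fixture(scope="session")
def dik_strain():
    """One dikaryon (Type1 x Type3) plus its truth table."""
    spec = synthetic.StrainSpec("dik1", "di", ("Type1", "Type3"), ("a1", "a2"), ("b1", "b2"))
    return synthetic.generate_strain(spec, seed=202)


@pytest.fixture(scope="session")
def dik_report(dik_strain, panel):
    from matloci import pipeline

    contigs, models, _ = dik_strain
    return pipeline.annotate_strain("dik1", contigs, models, panel)
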