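import pytest

from lncnet.simulate import SyntheticSpec, generate_dataset

#: Fixed seed for the shared default fixture used by planted-truth tests.
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic cohort: 9 tumor/normal pairs, 100 up + 50 down planted
    genes at log2_effect=2, 10 tumor-only co-expression pairs, 3 ceRNA triplets."""
    return generate_dataset(SyntheticSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def default_de(default_dataset):
    """DE table plus filtered up/down lists on the default cohort."""
    from lncnet.de import de_table, filter_differential

    table = de_table(default_dataset.expression, default_dataset.annotation)
    up, down = filter_differential(table)
    return table, up, down
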