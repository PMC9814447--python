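import pytest

from iridaprev import (
    filter_for_estimation,
    packaged_missense_table,
    synthetic_ptv_complement,
)


@pytest.fixture(scope="session")
def missense_records():
    """The 40 packaged P/LP missense variants with global MAFs."""
    return packaged_missense_table()


@pytest.fixture(scope="session")
def curated_records(missense_records):
    """86-variant curated table: packaged missense + synthetic PTV complement."""
    return missense_records + synthetic_ptv_complement(seed=11)


@pytest.fixture(scope="session")
def included_records(curated_records):
    return filter_for_estimation(curated_records)
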