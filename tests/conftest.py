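import pytest

from vitdmr import datasets
from vitdmr.summary_io import harmonize_tables


@pytest.fixture(scope="session")
def instruments():
    return datasets.load_instruments()


@pytest.fixture(scope="session")
def outcome_tables():
    return datasets.load_outcomes()


@pytest.fixture(scope="session")
def harmonized(instruments, outcome_tables):
    exposure = [i.as_association() for i in instruments]
    return {name: harmonize_tables(exposure, table)
            for name, table in outcome_tables.items()}
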