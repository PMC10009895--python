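from importlib import resources

import pytest

from allovax.hla import load_typing_table
from allovax.matching import load_expression_table


def _data(name: str):
    return resources.files("allovax.data").joinpath(name)


@pytest.fixture(scope="session")
def table1_typings():
    """All typings from the packaged cell-line + cohort table."""
    return load_typing_table(_data("table1_typings.csv"))


@pytest.fixture(scope="session")
def line_typing(table1_typings):
    return next(t for t in table1_typings if t.subject_id == "SV-BR-1-GM")


@pytest.fixture(scope="session")
def cohort_typings(table1_typings):
    return [t for t in table1_typings if t.subject_id != "SV-BR-1-GM"]


@pytest.fixture(scope="session")
def expression_gate():
    """OR of vehicle and IFN-gamma expression calls for the line's alleles."""
    return load_expression_table(_data("line_expression.tsv"))
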