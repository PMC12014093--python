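import pytest

from heddc import CostParams, UnitSet, build_cost_tables


@pytest.fixture(scope="session")
def aaag_ag() -> UnitSet:
    return UnitSet(["AAAG", "AG"])


@pytest.fixture(scope="session")
def aaag_ag_table(aaag_ag):
    return build_cost_tables(aaag_ag, CostParams())


@pytest.fixture(scope="session")
def aaag_ag_aag() -> UnitSet:
    return UnitSet(["AAAG", "AG", "AAG"])


@pytest.fixture(scope="session")
def aaag_ag_aag_table(aaag_ag_aag):
    return build_cost_tables(aaag_ag_aag, CostParams())
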