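import pytest

from canalmorph import CalibrationTable, fixture


@pytest.fixture(scope="session")
def diameter_records():
    return fixture("table1")


@pytest.fixture(scope="session")
def lumen_records():
    return fixture("table2")


@pytest.fixture(scope="session")
def angle_records():
    return fixture("table3")


@pytest.fixture(scope="session")
def endothiodon(diameter_records):
    return {r.specimen_id: r for r in diameter_records if r.taxon == "Endothiodon"}


@pytest.fixture(scope="session")
def calibration(diameter_records):
    return CalibrationTable.from_records(diameter_records)
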