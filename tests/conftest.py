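from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from barcodeid.refdata import load_table1_fixture, load_table2_annotations

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case_fixture():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def case_annotations():
    return load_table2_annotations()


def make_record(record_id, sequence, species=None, **kw):
    from barcodeid.refdata import BarcodeRecord

    return BarcodeRecord(record_id, species, sequence, **kw)
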