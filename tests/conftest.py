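from datetime import datetime

import pytest
from hypothesis import settings

from rxaudit.records import PrescriptionRecord

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def make_record():
    """Factory for a valid oral-tablet oxycodone record with overridable fields."""

    def _make(**overrides) -> PrescriptionRecord:
        base = dict(
            rx_id="RX1",
            patient_id="P1",
            drug_name="oxycodone 5 mg tablet",
            route="oral",
            formulation="tablet",
            strength_mg=5.0,
            discrete_dose="5 mg",
            frequency_label="twice a day",
            quantity=6.0,
            written_duration_value=3.0,
            written_duration_unit="days",
            ordered_at=datetime(2018, 1, 15, 9, 30),
            is_refill=False,
        )
        base.update(overrides)
        return PrescriptionRecord(**base)

    return _make
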