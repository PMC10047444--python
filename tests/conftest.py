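import datetime as dt

import pytest

from periotrack.diagnosis_model import (
    DiseaseType,
    Extent,
    Onset,
    PDDiagnosis,
    Severity,
)

SEVERITIES = list(Severity)
EXTENTS = list(Extent)
TYPES = list(DiseaseType)


def make_diag(
    disease_type=None,
    severity=None,
    extent=None,
    onset=None,
    location=(),
    patient_id="p1",
    date=dt.date(2010, 1, 1),
    source_text="",
):
    """Shorthand diagnosis-record factory for tests."""
    return PDDiagnosis(
        patient_id=patient_id,
        diagnosis_date=date,
        disease_type=DiseaseType(disease_type) if disease_type else None,
        severity=Severity(severity) if severity else None,
        extent=Extent(extent) if extent else None,
        onset=Onset(onset) if onset else None,
        location=tuple(location),
        source_text=source_text,
    )


@pytest.fixture
def enumerated_full_order():
    """Independent brute-force oracle: the 20 full states as explicit rank
    tuples, sorted; position in this list defines the ordering."""
    tuples = [
        (t, s, e)
        for t in (1, 2)
        for s in (1, 2, 3, 4, 5)
        for e in (1, 2)
    ]
    return sorted(tuples)
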