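import pandas as pd
import pytest

from shareduse.claims import ClaimsTable

BASE = pd.Timestamp("2016-04-01")


def day(n: int) -> pd.Timestamp:
    """Calendar date n days after the start of FY2016."""
    return BASE + pd.Timedelta(days=n)


def make_claims(visit_rows, enrollments=None, facilities=None) -> ClaimsTable:
    """Build a validated ClaimsTable from (patient, facility, day, exam?, modality?)
    tuples; enrollment spans and facility rows are filled in automatically."""
    rows = []
    for r in visit_rows:
        patient, facility, d = r[0], r[1], r[2]
        is_exam = r[3] if len(r) > 3 else False
        modality = r[4] if len(r) > 4 else ("CT" if is_exam else "NONE")
        rows.append((patient, facility, day(d) if isinstance(d, int) else d, is_exam, modality))
    visits = pd.DataFrame(
        rows, columns=["patient_id", "facility_id", "service_date", "is_imaging_exam", "modality"]
    )
    if enrollments is None:
        patients = sorted(visits["patient_id"].unique())
        enrollments = pd.DataFrame(
            [(p, day(-365), day(5 * 365)) for p in patients],
            columns=["patient_id", "start_date", "end_date"],
        )
    if facilities is None:
        facs = sorted(visits["facility_id"].unique())
        facilities = pd.DataFrame(
            [(f, 10) for f in facs], columns=["facility_id", "bed_count"]
        )
    return ClaimsTable(visits=visits, enrollments=enrollments, facilities=facilities)


@pytest.fixture
def toy_episode() -> ClaimsTable:
    """Source visits at days 70 and 130 bracketing an isolated exam at day 100."""
    return make_claims([
        ("P1", "S", 70),
        ("P1", "S", 130),
        ("P1", "T", 100, True, "CT"),
    ])
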