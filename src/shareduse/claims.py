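"""Claims data model, CSV I/O, fiscal-year assignment and population filtering.

The unit of analysis is a visit: one patient contacting one medical facility
on one calendar date, optionally receiving a diagnostic imaging examination
(CT or MRI).  Visits, enrollment spans and facility attributes are held as
pandas DataFrames inside a :class:`ClaimsTable`, validated on construction.

Fiscal years follow the Japanese convention: April 1 through March 31,
labelled by the starting calendar year (2016-04-01 .. 2017-03-31 is FY2016).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("CT", "MRI")
#: modality value for non-imaging visits
NO_MODALITY = "NONE"

VISIT_COLUMNS = ["patient_id", "facility_id", "service_date", "is_imaging_exam", "modality"]
ENROLLMENT_COLUMNS = ["patient_id", "start_date", "end_date"]
FACILITY_COLUMNS = ["facility_id", "bed_count"]

DateLike = Union[date, pd.Timestamp, str, np.datetime64]


class ClaimsSchemaError(ValueError):
    """A CSV/table is missing required columns or has unparseable values."""


class ClaimsValidationError(ValueError):
    """Row-level contract violation: bad enum, bad date, referential failure."""


@dataclass(frozen=True)
class VisitRecord:
    """One patient–facility–date service contact."""

    patient_id: str
    facility_id: str
    service_date: date
    is_imaging_exam: bool = False
    modality: str = NO_MODALITY

    def __post_init__(self) -> None:
        if self.is_imaging_exam and self.modality not in MODALITIES:
            raise ClaimsValidationError(
                f"imaging exam requires modality in {MODALITIES}, got {self.modality!r}"
            )
        if not self.is_imaging_exam and self.modality != NO_MODALITY:
            raise ClaimsValidationError(
                f"non-imaging visit must have modality {NO_MODALITY!r}, got {self.modality!r}"
            )


@dataclass(frozen=True)
class EnrollmentSpan:
    """Continuous insurance-coverage interval for one patient."""

    patient_id: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ClaimsValidationError(
                f"enrollment start {self.start_date} after end {self.end_date} "
                f"for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class FacilityRecord:
    """Facility attributes; bed_count 0 encodes a clinic without beds."""

    facility_id: str
    bed_count: int = 0

    def __post_init__(self) -> None:
        if self.bed_count < 0:
            raise ClaimsValidationError(
                f"negative bed_count {self.bed_count} for facility {self.facility_id}"
            )


def fiscal_year(service_date: DateLike) -> int:
    """Japanese fiscal year of a date: FY(Y) runs Y-04-01 .. (Y+1)-03-31."""
    ts = pd.Timestamp(service_date)
    return ts.year if ts.month >= 4 else ts.year - 1


def fiscal_year_span(fy: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar date of a Japanese fiscal year."""
    return pd.Timestamp(fy, 4, 1), pd.Timestamp(fy + 1, 3, 31)


@dataclass
class ClaimsTable:
    """Validated container for visits, enrollment spans and facilities.

    Invariants enforced by :meth:`validate`:

    * every ``patient_id`` in ``visits`` appears in ``enrollments``;
    * every ``facility_id`` in ``visits`` appears in ``facilities``;
    * ``modality == "NONE"`` exactly when ``is_imaging_exam`` is false;
    * duplicate identical visit rows are collapsed (logged).
    """

    visits: pd.DataFrame
    enrollments: pd.DataFrame
    facilities: pd.DataFrame
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        visits: Iterable[VisitRecord],
        enrollments: Iterable[EnrollmentSpan],
        facilities: Iterable[FacilityRecord],
    ) -> "ClaimsTable":
        vrows = [
            (v.patient_id, v.facility_id, pd.Timestamp(v.service_date), bool(v.is_imaging_exam), v.modality)
            for v in visits
        ]
        erows = [(e.patient_id, pd.Timestamp(e.start_date), pd.Timestamp(e.end_date)) for e in enrollments]
        frows = [(f.facility_id, int(f.bed_count)) for f in facilities]
        return cls(
            visits=pd.DataFrame(vrows, columns=VISIT_COLUMNS),
            enrollments=pd.DataFrame(erows, columns=ENROLLMENT_COLUMNS),
            facilities=pd.DataFrame(frows, columns=FACILITY_COLUMNS),
        )

    def validate(self) -> None:
        for df, cols, name in (
            (self.visits, VISIT_COLUMNS, "visits"),
            (self.enrollments, ENROLLMENT_COLUMNS, "enrollments"),
            (self.facilities, FACILITY_COLUMNS, "facilities"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ClaimsSchemaError(f"{name} table missing column(s): {', '.join(missing)}")

        v = self.visits.copy()
        v["patient_id"] = v["patient_id"].astype(str)
        v["facility_id"] = v["facility_id"].astype(str)
        v["service_date"] = _parse_dates(v["service_date"], "visits.service_date")
        v["is_imaging_exam"] = _parse_bool(v["is_imaging_exam"])
        v["modality"] = v["modality"].astype(str).str.upper()

        bad_mod = v.loc[~v["modality"].isin(MODALITIES + (NO_MODALITY,)), "modality"].unique()
        if len(bad_mod):
            raise ClaimsValidationError(f"unknown modality value(s): {sorted(bad_mod)}")
        mismatch = v["is_imaging_exam"] != (v["modality"] != NO_MODALITY)
        if mismatch.any():
            raise ClaimsValidationError(
                f"{int(mismatch.sum())} visit row(s) violate modality/is_imaging_exam "
                "consistency (modality NONE iff not an exam)"
            )

        n_before = len(v)
        v = v.drop_duplicates(subset=VISIT_COLUMNS, ignore_index=True)
        if len(v) < n_before:
            logger.info("collapsed %d duplicate visit rows", n_before - len(v))
        v = v.sort_values(VISIT_COLUMNS[:3] + ["modality"], kind="mergesort", ignore_index=True)

        e = self.enrollments.copy()
        e["patient_id"] = e["patient_id"].astype(str)
        e["start_date"] = _parse_dates(e["start_date"], "enrollments.start_date")
        e["end_date"] = _parse_dates(e["end_date"], "enrollments.end_date")
        inverted = e["start_date"] > e["end_date"]
        if inverted.any():
            raise ClaimsValidationError(
                f"enrollment start after end for patient(s): "
                f"{sorted(e.loc[inverted, 'patient_id'].unique())}"
            )
        e = e.sort_values(ENROLLMENT_COLUMNS, kind="mergesort", ignore_index=True)

        f = self.facilities.copy()
        f["facility_id"] = f["facility_id"].astype(str)
        f["bed_count"] = pd.to_numeric(f["bed_count"], errors="raise").astype(int)
        if (f["bed_count"] < 0).any():
            bad = sorted(f.loc[f["bed_count"] < 0, "facility_id"])
            raise ClaimsValidationError(f"negative bed_count for facility(ies): {bad}")
        f = f.drop_duplicates(subset=["facility_id"], ignore_index=True)
        f = f.sort_values("facility_id", kind="mergesort", ignore_index=True)

        orphan_p = sorted(set(v["patient_id"]) - set(e["patient_id"]))
        if orphan_p:
            raise ClaimsValidationError(f"visit patient_id(s) missing from enrollments: {orphan_p}")
        orphan_f = sorted(set(v["facility_id"]) - set(f["facility_id"]))
        if orphan_f:
            raise ClaimsValidationError(f"visit facility_id(s) missing from facilities: {orphan_f}")

        self.visits, self.enrollments, self.facilities = v, e, f

    # -- derived views --------------------------------------------------------

    @property
    def imaging_exams(self) -> pd.DataFrame:
        return self.visits[self.visits["is_imaging_exam"]]

    def patient_ids(self) -> list[str]:
        return sorted(self.enrollments["patient_id"].unique())


def _parse_dates(col: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(col, format="mixed", errors="coerce")
    if parsed.isna().any():
        bad = col[parsed.isna()].astype(str).unique()[:5]
        raise ClaimsValidationError(f"unparseable date(s) in {what}: {list(bad)}")
    return parsed.dt.normalize()


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapped = col.astype(str).str.strip().str.lower().map(
        {"0": False, "1": True, "false": False, "true": True}
    )
    if mapped.isna().any():
        bad = col[mapped.isna()].astype(str).unique()[:5]
        raise ClaimsValidationError(f"unparseable is_imaging_exam flag(s): {list(bad)}")
    return mapped.astype(bool)


# -- CSV I/O -----------------------------------------------------------------


def read_claims(
    visits_path: Union[str, Path],
    enrollments_path: Union[str, Path],
    facilities_path: Union[str, Path],
) -> ClaimsTable:
    """Read the three claims CSVs (UTF-8, header row) into a validated table.

    Rows with unparseable dates or unknown modality strings raise
    :class:`ClaimsValidationError`; a missing column raises
    :class:`ClaimsSchemaError` naming the column.
    """
    visits = pd.read_csv(visits_path, dtype=str, encoding="utf-8")
    enrollments = pd.read_csv(enrollments_path, dtype=str, encoding="utf-8")
    facilities = pd.read_csv(facilities_path, dtype=str, encoding="utf-8")
    return ClaimsTable(visits=visits, enrollments=enrollments, facilities=facilities)


def write_claims(claims: ClaimsTable, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write visits/enrollments/facilities CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "enrollments": out / "enrollments.csv",
        "facilities": out / "facilities.csv",
    }
    v = claims.visits.copy()
    v["service_date"] = v["service_date"].dt.strftime("%Y-%m-%d")
    v["is_imaging_exam"] = v["is_imaging_exam"].astype(int)
    v.to_csv(paths["visits"], index=False, encoding="utf-8")

    e = claims.enrollments.copy()
    for c in ("start_date", "end_date"):
        e[c] = e[c].dt.strftime("%Y-%m-%d")
    e.to_csv(paths["enrollments"], index=False, encoding="utf-8")
    claims.facilities.to_csv(paths["facilities"], index=False, encoding="utf-8")
    return paths


# -- study population filter --------------------------------------------------


def filter_population(
    claims: ClaimsTable,
    study_start: DateLike,
    study_end: DateLike,
) -> ClaimsTable:
    """Apply the study inclusion criteria over ``[study_start, study_end]``.

    A patient is retained iff (a) a single enrollment span covers the whole
    study window (continuous insurance coverage; any gap excludes), and
    (b) the patient has at least one CT or MRI exam dated inside the window.
    All visits of retained patients are kept.  Exclusion tallies are stored in
    ``result.exclusion_counts`` under ``"coverage gap"`` and ``"no exam"``
    (a patient failing both is counted under ``"coverage gap"``).
    """
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    if start > end:
        raise ValueError(f"study_start {start.date()} after study_end {end.date()}")

    e = claims.enrollments
    covered = e[(e["start_date"] <= start) & (e["end_date"] >= end)]
    covered_ids = set(covered["patient_id"])
    all_ids = set(e["patient_id"])

    exams = claims.imaging_exams
    in_window = exams[(exams["service_date"] >= start) & (exams["service_date"] <= end)]
    with_exam = set(in_window["patient_id"])

    keep = covered_ids & with_exam
    exclusion_counts = {
        "coverage gap": len(all_ids - covered_ids),
        "no exam": len(covered_ids - with_exam),
    }

    v = claims.visits[claims.visits["patient_id"].isin(keep)].reset_index(drop=True)
    e_keep = e[e["patient_id"].isin(keep)].reset_index(drop=True)
    result = ClaimsTable(visits=v, enrollments=e_keep, facilities=claims.facilities.copy())
    result.exclusion_counts = exclusion_counts
    logger.info(
        "population filter: kept %d of %d patients (excluded: %s)",
        len(keep), len(all_ids), exclusion_counts,
    )
    return result
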