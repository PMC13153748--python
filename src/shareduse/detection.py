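"""Rule-based detection of shared-use imaging events.

A *shared-use event* is an episode in which one facility (the *target*)
performs a single, temporally isolated CT or MRI examination for a patient
who is simultaneously under an ongoing course of visits at another facility
(the *source*), which is inferred to have requested the exam.  Three
conditions operationalize this:

1. **Isolation** — the target facility performs no other diagnostic imaging
   exam (CT or MRI, either modality) for the patient within
   ``isolation_window_days`` (default 91, a fixed-length 3-month window) of
   the exam date.  Equivalently, every 91-day window containing the exam
   holds only that one imaging visit at the target.
2. **Continuity** — some other facility has at least two visits by the
   patient whose dates span at most ``continuity_window_days`` (default 182,
   a 6-month window).
3. **Containment** — the exam date falls inside that visit bracket, and the
   source facility performs no imaging exam for the patient inside it (the
   source requests but does not conduct the exam).

When several facilities qualify, the default ``nearest`` policy keeps the one
whose visit is closest in time to the exam (ties: larger visit count, then
lexicographically smallest facility id); policy ``all`` emits one event per
qualifying source.

:func:`brute_force_oracle` re-derives the same semantics by exhaustive
enumeration with no indexing or shared helpers; it exists as an independent
reference for testing and for the synthetic generator's verification pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .claims import ClaimsTable, fiscal_year

EVENT_COLUMNS = [
    "patient_id",
    "source_facility_id",
    "target_facility_id",
    "exam_date",
    "modality",
    "fiscal_year",
]


@dataclass(frozen=True)
class DetectionParams:
    """Window lengths (days) and multi-source resolution policy."""

    isolation_window_days: int = 91
    continuity_window_days: int = 182
    multi_source_policy: str = "nearest"

    def __post_init__(self) -> None:
        if self.isolation_window_days <= 0 or self.continuity_window_days <= 0:
            raise ValueError("window lengths must be positive")
        if self.isolation_window_days > self.continuity_window_days:
            raise ValueError(
                "isolation window must not exceed continuity window "
                f"({self.isolation_window_days} > {self.continuity_window_days})"
            )
        if self.multi_source_policy not in ("nearest", "all"):
            raise ValueError(f"unknown multi_source_policy {self.multi_source_policy!r}")


@dataclass(frozen=True)
class SharedUseEvent:
    """One detected collaboration: source facility -> target facility."""

    patient_id: str
    source_facility_id: str
    target_facility_id: str
    exam_date: pd.Timestamp
    modality: str
    fiscal_year: int

    def __post_init__(self) -> None:
        if self.source_facility_id == self.target_facility_id:
            raise ValueError("source and target facility must differ")

    def key(self) -> tuple:
        return (
            self.patient_id,
            self.source_facility_id,
            self.target_facility_id,
            pd.Timestamp(self.exam_date),
            self.modality,
            int(self.fiscal_year),
        )


@dataclass(frozen=True)
class SourceCandidate:
    facility_id: str
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    visit_count: int
    nearest_gap_days: int


def events_to_frame(events: Iterable[SharedUseEvent]) -> pd.DataFrame:
    rows = [e.key() for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# per-patient index used by the fast path


class _PatientIndex:
    """Sorted per-facility visit-day and exam-day arrays for one patient."""

    def __init__(self, patient_visits: pd.DataFrame):
        epoch = pd.Timestamp("1970-01-01")
        days = (patient_visits["service_date"] - epoch).dt.days.to_numpy()
        fac = patient_visits["facility_id"].to_numpy()
        exam = patient_visits["is_imaging_exam"].to_numpy()
        self.visit_days: dict[str, np.ndarray] = {}
        self.exam_days: dict[str, np.ndarray] = {}
        for f in np.unique(fac):
            sel = fac == f
            self.visit_days[f] = np.sort(days[sel])
            self.exam_days[f] = np.sort(days[sel & exam])


def _condition1(index: _PatientIndex, facility: str, exam_day: int, iso: int) -> bool:
    arr = index.exam_days.get(facility)
    if arr is None:
        return False
    lo = np.searchsorted(arr, exam_day - iso, side="left")
    hi = np.searchsorted(arr, exam_day + iso, side="right")
    return hi - lo == 1


def _tightest_bracket(
    vdays: np.ndarray, edays: np.ndarray, exam_day: int, cont: int
) -> Optional[tuple[int, int, int]]:
    """Tightest visit pair [a, b] with a <= exam <= b, a < b, b-a <= cont and
    no imaging exam day in [a, b].  Returns (a, b, visit_count) or None.

    Ties on width are broken toward the later-starting window.
    """
    below = vdays[vdays <= exam_day]
    above = vdays[vdays >= exam_day]
    if below.size == 0 or above.size == 0:
        return None
    best = None
    # candidate starts: visits <= exam, scanned from the latest backwards
    for a in below[::-1]:
        ends = above[above > a]
        if ends.size == 0:
            continue
        b = int(ends[0])  # smallest admissible end for this start
        if b - int(a) > cont:
            continue
        a = int(a)
        if edays.size and np.any((edays >= a) & (edays <= b)):
            continue  # source performed an exam inside the bracket
        width = b - a
        if best is None or width < best[1] - best[0]:
            count = int(np.searchsorted(vdays, b, "right") - np.searchsorted(vdays, a, "left"))
            best = (a, b, count)
    return best


def _qualifying_sources_idx(
    index: _PatientIndex, target: str, exam_day: int, params: DetectionParams
) -> list[SourceCandidate]:
    epoch = pd.Timestamp("1970-01-01")
    out = []
    for fac, vdays in index.visit_days.items():
        if fac == target or vdays.size < 2:
            continue
        bracket = _tightest_bracket(
            vdays, index.exam_days.get(fac, np.empty(0, int)), exam_day, params.continuity_window_days
        )
        if bracket is None:
            continue
        a, b, count = bracket
        inside = vdays[(vdays >= a) & (vdays <= b)]
        gap = int(np.min(np.abs(inside - exam_day)))
        out.append(
            SourceCandidate(
                facility_id=fac,
                window_start=epoch + pd.Timedelta(days=a),
                window_end=epoch + pd.Timedelta(days=b),
                visit_count=count,
                nearest_gap_days=gap,
            )
        )
    return sorted(out, key=lambda c: c.facility_id)


# ---------------------------------------------------------------------------
# public per-exam predicates (operate on a ClaimsTable)


def _exam_row(exam) -> tuple[str, str, pd.Timestamp]:
    if not bool(exam["is_imaging_exam"]):
        raise ValueError("condition predicates require an imaging exam row")
    return str(exam["patient_id"]), str(exam["facility_id"]), pd.Timestamp(exam["service_date"])


def condition1_isolated(exam, claims: ClaimsTable, params: DetectionParams = DetectionParams()) -> bool:
    """True iff no other imaging exam (any modality) at the exam's facility
    falls within ``isolation_window_days`` of the exam date for this patient."""
    patient, facility, when = _exam_row(exam)
    idx = _PatientIndex(claims.visits[claims.visits["patient_id"] == patient])
    day = (when - pd.Timestamp("1970-01-01")).days
    return _condition1(idx, facility, day, params.isolation_window_days)


def qualifying_sources(
    exam, claims: ClaimsTable, params: DetectionParams = DetectionParams()
) -> list[SourceCandidate]:
    """All facilities satisfying the continuity and containment conditions
    for this exam, each with its tightest qualifying visit bracket."""
    patient, facility, when = _exam_row(exam)
    idx = _PatientIndex(claims.visits[claims.visits["patient_id"] == patient])
    day = (when - pd.Timestamp("1970-01-01")).days
    return _qualifying_sources_idx(idx, facility, day, params)


def select_source(candidates: list[SourceCandidate], exam=None) -> Optional[str]:
    """Nearest-visit policy: smallest gap to the exam date, ties broken by
    larger visit count, then lexicographically smallest facility id."""
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (c.nearest_gap_days, -c.visit_count, c.facility_id))
    return best.facility_id


# ---------------------------------------------------------------------------
# full detection


def detect_shared_use(
    claims: ClaimsTable,
    modality: str,
    fiscal_year_: Optional[int] = None,
    params: DetectionParams = DetectionParams(),
) -> list[SharedUseEvent]:
    """Detect shared-use events for one modality (optionally one fiscal year).

    Fiscal-year strata are assigned by exam date; the bracketing source
    visits may cross fiscal-year boundaries and still count.  Output is
    sorted by (exam_date, patient_id, target, source) and is invariant to
    input row order.
    """
    events: list[SharedUseEvent] = []
    exams = claims.imaging_exams
    exams = exams[exams["modality"] == modality]
    if fiscal_year_ is not None:
        fy = exams["service_date"].map(fiscal_year)
        exams = exams[fy == fiscal_year_]
    if exams.empty:
        return []

    for patient, pv in claims.visits[
        claims.visits["patient_id"].isin(exams["patient_id"].unique())
    ].groupby("patient_id"):
        idx = _PatientIndex(pv)
        p_exams = exams[exams["patient_id"] == patient]
        for _, exam in p_exams.iterrows():
            target = str(exam["facility_id"])
            when = pd.Timestamp(exam["service_date"])
            day = (when - pd.Timestamp("1970-01-01")).days
            if not _condition1(idx, target, day, params.isolation_window_days):
                continue
            candidates = _qualifying_sources_idx(idx, target, day, params)
            if not candidates:
                continue
            if params.multi_source_policy == "nearest":
                chosen = [select_source(candidates)]
            else:
                chosen = [c.facility_id for c in candidates]
            for src in chosen:
                events.append(
                    SharedUseEvent(
                        patient_id=str(patient),
                        source_facility_id=src,
                        target_facility_id=target,
                        exam_date=when,
                        modality=modality,
                        fiscal_year=fiscal_year(when),
                    )
                )
    events.sort(
        key=lambda e: (e.exam_date, e.patient_id, e.target_facility_id, e.source_facility_id)
    )
    return events


# ---------------------------------------------------------------------------
# exhaustive reference implementation


def brute_force_oracle(
    claims: ClaimsTable,
    modality: str,
    fiscal_year_: Optional[int] = None,
    params: DetectionParams = DetectionParams(),
) -> list[SharedUseEvent]:
    """Reference detector: exhaustive enumeration over all exams, facilities
    and visit-date pairs, with no indexing or pruning.  Semantics identical
    to :func:`detect_shared_use`; intended for testing and generator
    verification on small inputs.
    """
    rows = [
        (
            str(r.patient_id),
            str(r.facility_id),
            pd.Timestamp(r.service_date),
            bool(r.is_imaging_exam),
            str(r.modality),
        )
        for r in claims.visits.itertuples(index=False)
    ]
    iso = params.isolation_window_days
    cont = params.continuity_window_days
    events: list[SharedUseEvent] = []

    for (p, t, d, is_exam, mod) in rows:
        if not is_exam or mod != modality:
            continue
        if fiscal_year_ is not None and fiscal_year(d) != fiscal_year_:
            continue
        # Condition 1: the exam is the only imaging visit at t within +/- iso
        n_near = sum(
            1
            for (p2, f2, d2, ex2, _m2) in rows
            if p2 == p and f2 == t and ex2 and abs((d2 - d).days) <= iso
        )
        if n_near != 1:
            continue
        # Conditions 2 & 3: candidate source facilities via all visit pairs
        candidates = []
        facilities = sorted({f2 for (p2, f2, _d2, _e2, _m2) in rows if p2 == p and f2 != t})
        for s in facilities:
            s_dates = [d2 for (p2, f2, d2, _e2, _m2) in rows if p2 == p and f2 == s]
            s_exam_dates = [d2 for (p2, f2, d2, e2, _m2) in rows if p2 == p and f2 == s and e2]
            best = None
            for a in s_dates:
                for b in s_dates:
                    if a >= b or not (a <= d <= b):
                        continue
                    if (b - a).days > cont:
                        continue
                    if any(a <= x <= b for x in s_exam_dates):
                        continue
                    n_in = sum(1 for x in s_dates if a <= x <= b)
                    if n_in < 2:
                        continue
                    width = (b - a).days
                    if best is None or width < (best[1] - best[0]).days or (
                        width == (best[1] - best[0]).days and a > best[0]
                    ):
                        best = (a, b, n_in)
            if best is not None:
                a, b, n_in = best
                gap = min(abs((x - d).days) for x in s_dates if a <= x <= b)
                candidates.append((s, a, b, n_in, gap))
        if not candidates:
            continue
        if params.multi_source_policy == "nearest":
            chosen = [min(candidates, key=lambda c: (c[4], -c[3], c[0]))[0]]
        else:
            chosen = [c[0] for c in candidates]
        for s in chosen:
            events.append(
                SharedUseEvent(
                    patient_id=p,
                    source_facility_id=s,
                    target_facility_id=t,
                    exam_date=d,
                    modality=modality,
                    fiscal_year=fiscal_year(d),
                )
            )
    events.sort(
        key=lambda e: (e.exam_date, e.patient_id, e.target_facility_id, e.source_facility_id)
    )
    return events
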