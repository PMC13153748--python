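"""Synthetic claims generator with a planted shared-use network.

Real receipt (rezept) databases cannot be redistributed, so testability rests
on simulation: the generator plants a known directed collaboration network
among facilities, emits visit records whose episodes satisfy the three
shared-use detection conditions by construction, and returns the intended
events as ground truth.  Rule *violations* can be injected deliberately —
episodes that fail exactly one labelled condition — and background noise
visits are added per patient.

Exactness guarantee: after forward simulation every patient's records are
re-checked with the exhaustive detection oracle; if background noise happens
to create or corrupt a qualifying episode, that patient's noise is resampled
(bounded retries, then :class:`GenerationError`).  Ground truth therefore
holds exactly, not just with high probability, under the default detection
parameters and the nearest-source policy.

Randomness is hierarchical: one master seed, with per-patient substreams
derived from (seed, patient index) so that enlarging the population does not
reshuffle existing patients.  Identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .claims import ClaimsTable, fiscal_year_span
from .detection import DetectionParams, SharedUseEvent, brute_force_oracle

STUDY_START = pd.Timestamp("2016-04-01")
STUDY_END = pd.Timestamp("2020-03-31")
STUDY_FISCAL_YEARS = (2016, 2017, 2018, 2019)

_MAX_NOISE_RETRIES = 50


class GenerationError(RuntimeError):
    """The configuration is infeasible or verification retries are exhausted."""


class PlantedEdge(NamedTuple):
    source: str
    target: str
    modality: str
    fiscal_year: int
    n_events: int


class NonEvent(NamedTuple):
    """An episode deliberately violating exactly one detection condition."""

    patient_id: str
    source_facility_id: str
    target_facility_id: str
    exam_date: pd.Timestamp
    modality: str
    fiscal_year: int
    violated_condition: int


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic claims table.

    The default date span mirrors the four Japanese fiscal years 2016-2019;
    every regular patient is enrolled for the whole span so the population
    filter is a no-op unless ``n_uncovered_patients`` > 0.
    """

    n_facilities: int = 30
    n_patients: int = 60
    n_communities: int = 1
    planted_edges: Optional[list[PlantedEdge]] = None
    reciprocity_fraction: float = 0.0
    within_community_prob: float = 0.3
    between_community_prob: float = 0.01
    events_per_edge: int = 1
    modality: str = "CT"
    fiscal_year: int = 2016
    noise_visit_rate: float = 2.0
    violation_mix: dict[int, int] = field(default_factory=dict)
    n_uncovered_patients: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_facilities < 1 or self.n_patients < 1:
            raise GenerationError("n_facilities and n_patients must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_facilities:
            raise GenerationError("need 1 <= n_communities <= n_facilities")
        if not 0.0 <= self.reciprocity_fraction <= 1.0:
            raise GenerationError("reciprocity_fraction must lie in [0, 1]")
        if self.noise_visit_rate < 0:
            raise GenerationError("noise_visit_rate must be nonnegative")
        if any(c not in (1, 2, 3) or k < 0 for c, k in self.violation_mix.items()):
            raise GenerationError("violation_mix maps condition in {1,2,3} to a count >= 0")
        if self.planted_edges is not None:
            for e in self.planted_edges:
                if e.source == e.target:
                    raise GenerationError(f"planted edge with source == target: {e.source}")
                if e.n_events < 1:
                    raise GenerationError(f"planted edge {e.source}->{e.target} needs n_events >= 1")


@dataclass
class PlantedTruth:
    """Generator-side ground truth (valid under default detection params)."""

    events: list[SharedUseEvent]
    non_events: list[NonEvent]
    community_of: dict[str, int]
    edges: list[PlantedEdge] = field(default_factory=list)


def facility_ids(n: int) -> list[str]:
    return [f"F{i:04d}" for i in range(n)]


def plant_network(config: GeneratorConfig) -> tuple[list[PlantedEdge], dict[str, int]]:
    """Sample the planted directed edge set and the community layout.

    Facilities are split into ``n_communities`` contiguous blocks; each
    unordered pair is connected with ``within_community_prob`` inside a block
    and ``between_community_prob`` across blocks.  Exactly
    ``round(reciprocity_fraction * D)`` of the D connected dyads receive both
    directions; the rest get one seeded-random direction.  Every directed
    edge carries ``events_per_edge`` intended events in the configured
    (modality, fiscal year) stratum.
    """
    fids = facility_ids(config.n_facilities)
    blocks = np.array_split(np.arange(config.n_facilities), config.n_communities)
    community_of = {}
    for c, block in enumerate(blocks):
        for i in block:
            community_of[fids[i]] = c

    rng = np.random.default_rng([config.seed, 1])
    dyads = []
    for i in range(config.n_facilities):
        for j in range(i + 1, config.n_facilities):
            p = (
                config.within_community_prob
                if community_of[fids[i]] == community_of[fids[j]]
                else config.between_community_prob
            )
            if rng.random() < p:
                dyads.append((fids[i], fids[j]))
    if config.reciprocity_fraction > 0 and not dyads:
        raise GenerationError(
            "reciprocity_fraction > 0 requested but no connected dyads were planted"
        )

    n_mutual = int(round(config.reciprocity_fraction * len(dyads)))
    mutual_idx = set(rng.choice(len(dyads), size=n_mutual, replace=False)) if dyads else set()
    edges: list[PlantedEdge] = []
    for k, (u, v) in enumerate(dyads):
        if k in mutual_idx:
            directed = [(u, v), (v, u)]
        else:
            directed = [(u, v)] if rng.random() < 0.5 else [(v, u)]
        for s, t in directed:
            edges.append(PlantedEdge(s, t, config.modality, config.fiscal_year, config.events_per_edge))
    return edges, community_of


# ---------------------------------------------------------------------------
# episode construction (all offsets in days)


def _sample_exam_day(rng, fy: int, pre_margin: int, post_margin: int) -> pd.Timestamp:
    fy_start, fy_end = fiscal_year_span(fy)
    lo = max(fy_start, STUDY_START + pd.Timedelta(days=pre_margin))
    hi = min(fy_end, STUDY_END - pd.Timedelta(days=post_margin))
    if lo > hi:
        raise GenerationError(
            f"fiscal year {fy} with margins ({pre_margin}, {post_margin}) days does not "
            f"fit inside the enrollment span {STUDY_START.date()}..{STUDY_END.date()}"
        )
    return lo + pd.Timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _event_episode(rng, patient: str, edge: PlantedEdge) -> tuple[list[tuple], SharedUseEvent]:
    d1 = int(rng.integers(1, 81))
    d2 = int(rng.integers(1, 81))
    e = _sample_exam_day(rng, edge.fiscal_year, d1, d2)
    rows = [
        (patient, edge.target, e, True, edge.modality),
        (patient, edge.source, e - pd.Timedelta(days=d1), False, "NONE"),
        (patient, edge.source, e + pd.Timedelta(days=d2), False, "NONE"),
    ]
    for _ in range(int(rng.integers(0, 3))):  # optional mid-course visits
        off = int(rng.integers(-d1, d2 + 1))
        rows.append((patient, edge.source, e + pd.Timedelta(days=off), False, "NONE"))
    event = SharedUseEvent(
        patient_id=patient,
        source_facility_id=edge.source,
        target_facility_id=edge.target,
        exam_date=e,
        modality=edge.modality,
        fiscal_year=edge.fiscal_year,
    )
    return rows, event


def _violation_episode(
    rng, patient: str, source: str, target: str, modality: str, fy: int, condition: int
) -> tuple[list[tuple], NonEvent]:
    if condition == 1:
        # a second imaging exam at the target inside the isolation window
        d1, d2 = int(rng.integers(1, 81)), int(rng.integers(1, 81))
        g = int(rng.integers(1, 92))
        e = _sample_exam_day(rng, fy, d1, max(d2, g))
        rows = [
            (patient, target, e, True, modality),
            (patient, target, e + pd.Timedelta(days=g), True, modality),
            (patient, source, e - pd.Timedelta(days=d1), False, "NONE"),
            (patient, source, e + pd.Timedelta(days=d2), False, "NONE"),
        ]
    elif condition == 2:
        # bracketing source visits exist but span more than the 6-month window
        d1, d2 = int(rng.integers(92, 121)), int(rng.integers(92, 121))
        e = _sample_exam_day(rng, fy, d1, d2)
        rows = [
            (patient, target, e, True, modality),
            (patient, source, e - pd.Timedelta(days=d1), False, "NONE"),
            (patient, source, e + pd.Timedelta(days=d2), False, "NONE"),
        ]
    elif condition == 3:
        # two close source visits, both strictly after the exam date
        g1 = int(rng.integers(1, 31))
        g2 = g1 + int(rng.integers(1, 61))
        e = _sample_exam_day(rng, fy, 0, g2)
        rows = [
            (patient, target, e, True, modality),
            (patient, source, e + pd.Timedelta(days=g1), False, "NONE"),
            (patient, source, e + pd.Timedelta(days=g2), False, "NONE"),
        ]
    else:  # pragma: no cover - guarded by config validation
        raise GenerationError(f"unknown violation condition {condition}")
    non_event = NonEvent(patient, source, target, e, modality, fy, condition)
    return rows, non_event


def _noise_rows(rng, patient: str, fids: list[str], rate: float) -> list[tuple]:
    n = int(rng.poisson(rate))
    span = (STUDY_END - STUDY_START).days
    rows = []
    for _ in range(n):
        fac = fids[int(rng.integers(0, len(fids)))]
        day = STUDY_START + pd.Timedelta(days=int(rng.integers(0, span + 1)))
        rows.append((patient, fac, day, False, "NONE"))
    return rows


def _verify_patient(
    rows: list[tuple],
    facilities_df: pd.DataFrame,
    patient: str,
    modality: str,
    expected: set[tuple],
) -> bool:
    """Oracle check: the patient's rows yield exactly the intended events."""
    visits = pd.DataFrame(
        rows, columns=["patient_id", "facility_id", "service_date", "is_imaging_exam", "modality"]
    )
    enr = pd.DataFrame(
        [(patient, STUDY_START, STUDY_END)], columns=["patient_id", "start_date", "end_date"]
    )
    mini = ClaimsTable(visits=visits, enrollments=enr, facilities=facilities_df)
    got = {e.key() for e in brute_force_oracle(mini, modality, None, DetectionParams())}
    return got == expected


def generate_claims(config: GeneratorConfig) -> tuple[ClaimsTable, PlantedTruth]:
    """Simulate a claims table realizing the planted network exactly.

    Each intended event and each injected violation occupies its own patient;
    remaining patients contribute background noise only.  Raises
    :class:`GenerationError` when the config cannot be realized (too few
    patients for the requested episodes, infeasible windows, or persistent
    noise collisions).
    """
    fids = facility_ids(config.n_facilities)
    if config.planted_edges is not None:
        edges = list(config.planted_edges)
        community_of = {f: 0 for f in fids}
        extra = sorted(({e.source for e in edges} | {e.target for e in edges}) - set(fids))
        if extra:
            raise GenerationError(f"planted edges reference unknown facilities: {extra[:5]}")
    else:
        edges, community_of = plant_network(config)

    rng_master = np.random.default_rng([config.seed, 0])
    bed_counts = rng_master.choice(
        [0, 0, 0, 19, 50, 100, 200, 400], size=len(fids), replace=True
    )
    facilities_df = pd.DataFrame({"facility_id": fids, "bed_count": bed_counts.astype(int)})

    # episode plan: one patient per intended event, then per violation
    plan: list[tuple] = []  # ("event", edge) or ("violation", source, target, mod, fy, cond)
    for edge in edges:
        for _ in range(edge.n_events):
            plan.append(("event", edge))
    rng_viol = np.random.default_rng([config.seed, 3])
    for cond in sorted(config.violation_mix):
        for _ in range(config.violation_mix[cond]):
            if edges:
                edge = edges[int(rng_viol.integers(0, len(edges)))]
                s, t = edge.source, edge.target
            else:
                s, t = rng_viol.choice(fids, size=2, replace=False)
            plan.append(("violation", s, t, config.modality, config.fiscal_year, cond))

    if len(plan) > config.n_patients:
        raise GenerationError(
            f"n_patients={config.n_patients} is fewer than the {len(plan)} planted episodes"
        )

    all_rows: list[tuple] = []
    events: list[SharedUseEvent] = []
    non_events: list[NonEvent] = []
    patients = [f"P{i:05d}" for i in range(config.n_patients)]

    for pidx, patient in enumerate(patients):
        rng_p = np.random.default_rng([config.seed, 2, pidx])
        if pidx < len(plan):
            item = plan[pidx]
            if item[0] == "event":
                ep_rows, event = _event_episode(rng_p, patient, item[1])
                expected = {event.key()}
                stratum_modality = item[1].modality
            else:
                _, s, t, mod, fy, cond = item
                ep_rows, non_event = _violation_episode(rng_p, patient, s, t, mod, fy, cond)
                expected = set()
                stratum_modality = mod
        else:
            ep_rows, event, non_event = [], None, None
            expected = set()
            stratum_modality = config.modality

        ok = False
        for _ in range(_MAX_NOISE_RETRIES):
            noise = _noise_rows(rng_p, patient, fids, config.noise_visit_rate)
            rows = ep_rows + noise
            if not rows:
                ok = True
                break
            if _verify_patient(rows, facilities_df, patient, stratum_modality, expected):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place background noise for patient {patient} without "
                f"corrupting the planted episode after {_MAX_NOISE_RETRIES} retries"
            )
        all_rows.extend(rows)
        if pidx < len(plan):
            if plan[pidx][0] == "event":
                events.append(event)
            else:
                non_events.append(non_event)

    enrollments = [(p, STUDY_START, STUDY_END) for p in patients]
    # optional patients with a coverage gap, excluded by the population filter
    rng_gap = np.random.default_rng([config.seed, 4])
    for g in range(config.n_uncovered_patients):
        pid = f"G{g:05d}"
        end = STUDY_START + pd.Timedelta(days=int(rng_gap.integers(200, 900)))
        enrollments.append((pid, STUDY_START, end))
        day = STUDY_START + pd.Timedelta(days=int(rng_gap.integers(0, (end - STUDY_START).days)))
        all_rows.append((pid, fids[int(rng_gap.integers(0, len(fids)))], day, True, config.modality))

    visits = pd.DataFrame(
        all_rows, columns=["patient_id", "facility_id", "service_date", "is_imaging_exam", "modality"]
    )
    enr = pd.DataFrame(enrollments, columns=["patient_id", "start_date", "end_date"])
    claims = ClaimsTable(visits=visits, enrollments=enr, facilities=facilities_df)
    truth = PlantedTruth(events=events, non_events=non_events, community_of=community_of, edges=edges)
    return claims, truth


def truth_to_frames(truth: PlantedTruth) -> dict[str, pd.DataFrame]:
    """Tabular views of the ground truth for CSV export."""
    ev = pd.DataFrame(
        [e.key() for e in truth.events],
        columns=[
            "patient_id", "source_facility_id", "target_facility_id",
            "exam_date", "modality", "fiscal_year",
        ],
    )
    nev = pd.DataFrame(truth.non_events, columns=NonEvent._fields)
    comm = pd.DataFrame(
        sorted(truth.community_of.items()), columns=["facility_id", "community"]
    )
    return {"events": ev, "non_events": nev, "communities": comm}
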