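"""Annual summary tables, nonparametric tests, and the end-to-end pipeline.

Three report tables mirror the standard presentation of a shared-use study:

* **volume summary** — per (fiscal year, modality): total imaging exams in
  the filtered population, detected shared-use exams, and their proportion
  per 100 examinations (``100 * shared / total``);
* **facility summary** — per (fiscal year, modality, role): how many
  facilities acted as sources (requesting) or targets (performing), with
  mean/SD of per-facility event counts and of bed counts;
* **network metrics** — per stratum: n, m, density, reciprocity, Louvain
  modularity and community count.

Year-to-year facility characteristics are compared with the Kruskal–Wallis
test, CT vs MRI with the Mann–Whitney U test (both via scipy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .claims import ClaimsTable, MODALITIES, fiscal_year, filter_population
from .detection import DetectionParams, SharedUseEvent, detect_shared_use, events_to_frame
from .network import (
    DirectedNetwork,
    Partition,
    UndefinedMetricError,
    build_network,
    density,
    export_network,
    louvain,
    reciprocity,
)

logger = logging.getLogger(__name__)

Stratum = tuple[int, str]  # (fiscal_year, modality)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def shared_use_proportion(shared: int, total: int) -> Optional[float]:
    """Shared-use exams per 100 examinations, rounded to 3 decimals for
    display; None (reported empty) when there are no examinations."""
    if total == 0:
        return None
    return round(100.0 * shared / total, 3)


def volume_summary(
    claims: ClaimsTable, events_by_stratum: dict[Stratum, list[SharedUseEvent]]
) -> pd.DataFrame:
    """Per-stratum examination volumes and shared-use proportions."""
    exams = claims.imaging_exams.copy()
    exams["fiscal_year"] = exams["service_date"].map(fiscal_year)
    totals = exams.groupby(["fiscal_year", "modality"]).size()

    strata = sorted(set(totals.index) | set(events_by_stratum))
    rows = []
    for fy, mod in strata:
        total = int(totals.get((fy, mod), 0))
        shared = len(events_by_stratum.get((fy, mod), []))
        rows.append(
            {
                "fiscal_year": fy,
                "modality": mod,
                "total_exams": total,
                "shared_exams": shared,
                "proportion_per_100": shared_use_proportion(shared, total),
            }
        )
    return pd.DataFrame(rows, columns=[
        "fiscal_year", "modality", "total_exams", "shared_exams", "proportion_per_100",
    ])


def facility_summary(
    claims: ClaimsTable, events_by_stratum: dict[Stratum, list[SharedUseEvent]]
) -> pd.DataFrame:
    """Source/target facility counts with request and bed-count statistics.

    ``requests_mean``/``requests_sd`` summarize per-facility event counts
    (requests made for sources, received for targets); SDs use the n-1
    denominator and are empty when fewer than two facilities have the role.
    """
    beds = claims.facilities.set_index("facility_id")["bed_count"]
    rows = []
    for (fy, mod), events in sorted(events_by_stratum.items()):
        frame = events_to_frame(events)
        for role, col in (("source", "source_facility_id"), ("target", "target_facility_id")):
            if frame.empty:
                counts = pd.Series(dtype=int)
            else:
                counts = frame.groupby(col).size()
            fac = counts.index.tolist()
            n_fac = len(fac)
            row = {
                "fiscal_year": fy,
                "modality": mod,
                "role": role,
                "facility_count": n_fac,
                "requests_mean": float(counts.mean()) if n_fac else None,
                "requests_sd": float(counts.std(ddof=1)) if n_fac >= 2 else None,
                "beds_mean": float(beds.reindex(fac).mean()) if n_fac else None,
                "beds_sd": float(beds.reindex(fac).std(ddof=1)) if n_fac >= 2 else None,
            }
            rows.append(row)
    return pd.DataFrame(rows, columns=[
        "fiscal_year", "modality", "role", "facility_count",
        "requests_mean", "requests_sd", "beds_mean", "beds_sd",
    ])


# ---------------------------------------------------------------------------
# nonparametric tests


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", degenerate=True)
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U (min of the two U's) with normal
    approximation, tie correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney needs nonempty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(len(x) * len(y) / 2.0, 1.0, "mann_whitney", degenerate=True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
    return TestResult(u, float(res.pvalue), "mann_whitney")


def yearwise_tests(facility_table: pd.DataFrame, events_by_stratum) -> pd.DataFrame:
    """Kruskal–Wallis across fiscal years of per-facility request counts and
    bed counts, per (modality, role); Mann–Whitney CT vs MRI on per-facility
    request counts pooled over years."""
    per_fac: dict[tuple, dict[int, pd.Series]] = {}
    for (fy, mod), events in sorted(events_by_stratum.items()):
        frame = events_to_frame(events)
        if frame.empty:
            continue
        for role, col in (("source", "source_facility_id"), ("target", "target_facility_id")):
            per_fac.setdefault((mod, role), {})[fy] = frame.groupby(col).size()

    rows = []
    for (mod, role), by_year in sorted(per_fac.items()):
        groups = [by_year[fy].to_numpy() for fy in sorted(by_year)]
        if len(groups) >= 2:
            r = kruskal_wallis(groups)
            rows.append(
                {
                    "comparison": "across_years",
                    "modality": mod,
                    "role": role,
                    "quantity": "requests",
                    "method": r.method,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                }
            )
    for role in ("source", "target"):
        ct = [v for fy_map in [per_fac.get(("CT", role), {})] for v in fy_map.values()]
        mri = [v for fy_map in [per_fac.get(("MRI", role), {})] for v in fy_map.values()]
        if ct and mri:
            r = mann_whitney(np.concatenate([s.to_numpy() for s in ct]),
                             np.concatenate([s.to_numpy() for s in mri]))
            rows.append(
                {
                    "comparison": "ct_vs_mri",
                    "modality": "CT|MRI",
                    "role": role,
                    "quantity": "requests",
                    "method": r.method,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows, columns=[
        "comparison", "modality", "role", "quantity", "method", "statistic", "p_value",
    ])


# ---------------------------------------------------------------------------
# end-to-end pipeline


def network_metrics_row(net: DirectedNetwork, part: Partition) -> dict:
    row = {
        "fiscal_year": net.fiscal_year,
        "modality": net.modality,
        "n": net.n,
        "m": net.m,
        "density": None,
        "reciprocity": None,
        "modularity": part.q,
        "n_communities": len(part.communities()),
    }
    try:
        row["density"] = density(net)
    except UndefinedMetricError:
        pass
    try:
        row["reciprocity"] = reciprocity(net)
    except UndefinedMetricError:
        pass
    return row


def run_pipeline(
    claims: ClaimsTable,
    out_dir: Union[str, Path],
    study_start=None,
    study_end=None,
    params: DetectionParams = DetectionParams(),
    modalities: Sequence[str] = MODALITIES,
    seed: int = 0,
    resolution: float = 1.0,
    reciprocity_convention: str = "dyadic",
    graph_format: str = "graphml",
) -> dict[str, pd.DataFrame]:
    """Extract population -> detect shared use -> build networks -> metrics.

    Writes volume_summary.csv, facility_summary.csv, network_metrics.csv,
    events.csv, tests.csv, communities.csv and one graph file per stratum to
    ``out_dir``; returns the tables in memory.  Stage progress and row counts
    are logged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if study_start is None:
        study_start = claims.enrollments["start_date"].min() if len(claims.enrollments) else None
    if study_end is None:
        study_end = claims.enrollments["end_date"].max() if len(claims.enrollments) else None

    # stage 1: study population
    if study_start is not None:
        filtered = filter_population(claims, study_start, study_end)
    else:
        filtered = claims
    logger.info("stage population: %d visits, %d patients kept",
                len(filtered.visits), filtered.enrollments["patient_id"].nunique())

    # stage 2: shared-use detection per stratum
    exams = filtered.imaging_exams
    fys = sorted(exams["service_date"].map(fiscal_year).unique()) if len(exams) else []
    events_by_stratum: dict[Stratum, list[SharedUseEvent]] = {}
    for fy in fys:
        for mod in modalities:
            try:
                events_by_stratum[(fy, mod)] = detect_shared_use(filtered, mod, fy, params)
            except Exception as exc:  # pragma: no cover - stage context for callers
                raise RuntimeError(f"detection failed for stratum FY{fy}/{mod}") from exc
    frames = [events_to_frame(ev) for ev in events_by_stratum.values() if ev]
    all_events = pd.concat(frames, ignore_index=True) if frames else events_to_frame([])
    logger.info("stage detect: %d events over %d strata", len(all_events), len(events_by_stratum))

    # stages 3-5: networks, communities, measurements
    metric_rows, comm_rows = [], []
    for (fy, mod), events in sorted(events_by_stratum.items()):
        net = build_network(events, modality=mod, fiscal_year=fy)
        part = louvain(net, seed=seed, resolution=resolution)
        row = network_metrics_row(net, part)
        if row["reciprocity"] is not None and reciprocity_convention != "dyadic":
            row["reciprocity"] = reciprocity(net, convention=reciprocity_convention)
        metric_rows.append(row)
        for fac, c in sorted(part.community_of.items()):
            comm_rows.append({"fiscal_year": fy, "modality": mod, "facility_id": fac, "community": c})
        if net.n:
            suffix = "graphml" if graph_format == "graphml" else "tsv"
            export_network(net, out / f"network_{mod}_{fy}.{suffix}", partition=part, format=graph_format)

    tables = {
        "volume_summary": volume_summary(filtered, events_by_stratum),
        "facility_summary": facility_summary(filtered, events_by_stratum),
        "network_metrics": pd.DataFrame(metric_rows, columns=[
            "fiscal_year", "modality", "n", "m", "density", "reciprocity",
            "modularity", "n_communities",
        ]),
        "events": all_events,
        "tests": yearwise_tests(None, events_by_stratum),
        "communities": pd.DataFrame(comm_rows, columns=[
            "fiscal_year", "modality", "facility_id", "community",
        ]),
    }
    for name, df in tables.items():
        df_out = df.copy()
        if name == "events" and len(df_out):
            df_out["exam_date"] = pd.to_datetime(df_out["exam_date"]).dt.strftime("%Y-%m-%d")
        df_out.to_csv(out / f"{name}.csv", index=False, encoding="utf-8")
        logger.info("wrote %s.csv (%d rows)", name, len(df))
    return tables
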