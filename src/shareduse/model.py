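"""Model/Results facade over the shared-use pipeline.

``SharedUseNetworkModel`` is built from a claims table (or the three CSVs),
holds the detection and network parameters, and ``fit()`` runs population
filtering, event detection, network construction and community detection for
every (fiscal year, modality) stratum.  The returned
``SharedUseNetworkResults`` carries the per-stratum networks, partitions and
report tables, offers the year-wise and modality-wise nonparametric
comparisons, and prints a compact ``summary()``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import pandas as pd

from .claims import ClaimsTable, MODALITIES, fiscal_year, filter_population, read_claims
from .detection import DetectionParams, SharedUseEvent, detect_shared_use, events_to_frame
from .network import DirectedNetwork, Partition, build_network, louvain
from .reporting import (
    Stratum,
    facility_summary,
    network_metrics_row,
    volume_summary,
    yearwise_tests,
)


class SharedUseNetworkModel:
    """Shared-use collaboration network analysis of an outpatient claims table.

    Parameters
    ----------
    claims
        Validated :class:`~shareduse.claims.ClaimsTable`.
    params
        Detection windows and multi-source policy.
    modalities
        Imaging modalities to analyse (default CT and MRI).
    study_start, study_end
        Study window for the population filter; defaults to the span of the
        enrollment table.  Pass ``filter=False`` to skip filtering.
    """

    def __init__(
        self,
        claims: ClaimsTable,
        params: DetectionParams = DetectionParams(),
        modalities: Sequence[str] = MODALITIES,
        study_start=None,
        study_end=None,
        filter: bool = True,
    ):
        self.claims = claims
        self.params = params
        self.modalities = tuple(modalities)
        self.study_start = study_start
        self.study_end = study_end
        self.filter = filter

    @classmethod
    def from_csv(cls, visits_path, enrollments_path, facilities_path, **kwargs) -> "SharedUseNetworkModel":
        return cls(read_claims(visits_path, enrollments_path, facilities_path), **kwargs)

    def fit(self, seed: int = 0, resolution: float = 1.0) -> "SharedUseNetworkResults":
        claims = self.claims
        if self.filter and len(claims.enrollments):
            start = self.study_start or claims.enrollments["start_date"].min()
            end = self.study_end or claims.enrollments["end_date"].max()
            claims = filter_population(claims, start, end)

        exams = claims.imaging_exams
        fys = sorted(exams["service_date"].map(fiscal_year).unique()) if len(exams) else []
        events: dict[Stratum, list[SharedUseEvent]] = {}
        networks: dict[Stratum, DirectedNetwork] = {}
        partitions: dict[Stratum, Partition] = {}
        for fy in fys:
            for mod in self.modalities:
                ev = detect_shared_use(claims, mod, fy, self.params)
                events[(fy, mod)] = ev
                net = build_network(ev, modality=mod, fiscal_year=fy)
                networks[(fy, mod)] = net
                partitions[(fy, mod)] = louvain(net, seed=seed, resolution=resolution)
        return SharedUseNetworkResults(self, claims, events, networks, partitions)


class SharedUseNetworkResults:
    """Fitted per-stratum events, networks, communities and report tables."""

    def __init__(self, model, filtered_claims, events, networks, partitions):
        self.model = model
        self.filtered_claims = filtered_claims
        self.events = events
        self.networks = networks
        self.partitions = partitions

    # -- tables ---------------------------------------------------------------

    @property
    def events_frame(self) -> pd.DataFrame:
        frames = [events_to_frame(ev) for ev in self.events.values() if ev]
        return pd.concat(frames, ignore_index=True) if frames else events_to_frame([])

    def volume_table(self) -> pd.DataFrame:
        return volume_summary(self.filtered_claims, self.events)

    def facility_table(self) -> pd.DataFrame:
        return facility_summary(self.filtered_claims, self.events)

    def metrics_table(self) -> pd.DataFrame:
        rows = [
            network_metrics_row(self.networks[s], self.partitions[s])
            for s in sorted(self.networks)
        ]
        return pd.DataFrame(rows, columns=[
            "fiscal_year", "modality", "n", "m", "density", "reciprocity",
            "modularity", "n_communities",
        ])

    def compare(self) -> pd.DataFrame:
        """Kruskal–Wallis across fiscal years and Mann–Whitney CT vs MRI on
        per-facility request counts."""
        return yearwise_tests(None, self.events)

    def summary(self) -> str:
        lines = ["Shared-use collaboration network analysis", "=" * 42]
        vt = self.volume_table()
        lines.append("Examination volumes and shared use (per 100 exams):")
        lines.append(vt.to_string(index=False))
        mt = self.metrics_table()
        if len(mt):
            disp = mt.copy()
            for col in ("density", "reciprocity", "modularity"):
                disp[col] = disp[col].map(lambda x: f"{x:.3g}" if pd.notna(x) else "")
            lines.append("")
            lines.append("Network metrics per (fiscal year, modality):")
            lines.append(disp.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SharedUseNetworkResults: {len(self.events)} strata, "
            f"{sum(len(v) for v in self.events.values())} events>"
        )
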