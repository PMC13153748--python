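# shareduse

Network analysis of **collaborative CT/MRI equipment use** among medical
facilities, reconstructed from outpatient insurance claims.

Japan operates more CT and MRI scanners per capita than any other OECD
country, and regional health planners encourage facilities without scanners
to refer patients to neighbours that have them.  Whether that collaboration
actually happens is visible — indirectly — in administrative claims: a
patient under ongoing care at clinic *S* who receives a single, isolated
imaging exam at hospital *T* was in all likelihood referred by *S*.
`shareduse` turns long-format claims into a directed **facility referral
network** per fiscal year and modality, and quantifies its structure.

Audience: health-services researchers and prefectural planners working with
claims (receipt/rezept-style) extracts, and methodologists who need a
testbed with planted ground truth.

## The detection rule and the network metrics

A **shared-use event** for an imaging exam of patient *p* at facility *T*
on date *e* requires:

1. **Isolation** — *T* performs no other diagnostic imaging exam (CT or MRI)
   for *p* within ±91 days of *e* (a fixed-length 3-month window);
2. **Continuity** — some other facility *S* has visits by *p* on dates
   *v₁ ≤ e ≤ v₂* with *v₂ − v₁ ≤ 182* days (6-month window) and ≥ 2 visits
   in [*v₁*, *v₂*];
3. **Containment / no self-imaging** — the exam date lies inside that visit
   bracket and *S* performed no imaging exam for *p* inside it.

Each event contributes a directed edge *S → T* (source → target), weighted
by event count, in the (fiscal year, modality) stratum of the exam date.
Per network with *n* nodes and *m* distinct edges:

- **density** = *m* / (*n*(*n*−1));
- **dyadic reciprocity** = *a* / (*a* + *b* + *c*), mutual pairs over all
  connected pairs (edge-wise convention 2*a*/(2*a*+*b*+*c*) available);
- **modularity** *Q* and **Louvain** communities on the symmetrized
  weighted graph, with seeded restarts and exhaustive-enumeration
  cross-checks at small *n*.

Because real receipt databases cannot be redistributed, the package ships a
**synthetic claims generator** that plants a known referral network
(communities, mutual-dyad fraction, events per edge), injects labelled
violations of each condition, and verifies every patient against an
exhaustive brute-force detector so the ground truth is exact.

## Worked example

```python
import shareduse as s

cfg = s.GeneratorConfig(n_facilities=15, n_patients=100,
                        within_community_prob=0.25, events_per_edge=2,
                        reciprocity_fraction=0.3, noise_visit_rate=2.0, seed=7)
claims, truth = s.generate_claims(cfg)
results = s.SharedUseNetworkModel(claims).fit(seed=0)
print(results.summary())
```

prints

```
Shared-use collaboration network analysis
==========================================
Examination volumes and shared use (per 100 exams):
 fiscal_year modality  total_exams  shared_exams  proportion_per_100
        2016       CT           80            80               100.0
        2016      MRI            0             0                 NaN

Network metrics per (fiscal year, modality):
 fiscal_year modality  n  m density reciprocity modularity  n_communities
        2016       CT 15 40    0.19        0.29      0.292      4
        2016      MRI  0  0                              0      0
```

All 80 planted events were detected (here every exam is a planted
shared-use exam, so the proportion is 100 per 100); the recovered network
has 15 facilities and 40 directed edges, a density of 0.19, and a dyadic
reciprocity of 0.29 — within one mutual pair of the configured 0.3.
`results.volume_table()`, `facility_table()`, `metrics_table()` and
`compare()` (Kruskal–Wallis across years, Mann–Whitney CT vs MRI) return
the underlying DataFrames.

The same pipeline is scriptable:

```bash
shareduse generate --config gen.yaml --out data/
shareduse detect --visits data/visits.csv --enrollments data/enrollments.csv \
    --facilities data/facilities.csv --modality CT --out events.csv
shareduse network --events events.csv --metrics-out metrics.csv \
    --communities-out communities.csv --graph-out net.graphml
shareduse run --config pipeline.yaml   # all five stages at once
```

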