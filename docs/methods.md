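# Methods

## Data model and study population

The unit of observation is a **visit**: one patient contacting one facility
on one calendar date, optionally with a diagnostic imaging exam (CT or
MRI).  Dates carry no time component; duplicate identical visit rows are
collapsed with a logged count.  Fiscal years follow the Japanese
convention — April 1 through March 31, labelled by the starting calendar
year — because the insurers that produce such claims report by Japanese FY.

The population filter retains a patient only if (a) a **single** enrollment
span covers the entire study window and (b) the patient has at least one CT
or MRI exam dated inside it.  "Continuous coverage" is deliberately strict:
a gap of any length excludes, since claims alone cannot distinguish short
administrative gaps from genuine disenrollment.  Non-adherence to medical
advice (an exclusion that appears in real study protocols) is not
computable from claims and is not modelled.

## Shared-use detection

"3 months" and "6 months" are fixed windows of **91** and **182 days**;
calendar-month arithmetic is ambiguous across month lengths, and
fixed-length windows make the rule order-free and testable.

*Condition 1 (isolation)* is read in its strongest form: every 91-day
window containing the exam holds only that one imaging visit at the
target, which is equivalent to "no other imaging exam at the target within
±91 days".  The weaker existential reading ("there exists some 3-month
window in which the exam is alone") is almost vacuously true and detects
nearly everything.  Isolation counts **both** modalities regardless of the
stratum under analysis — a facility that performed an MRI a month before
the index CT is clearly providing ongoing imaging care, not one-off
shared use.

*Conditions 2–3 (continuity and containment)* require a visit bracket
*v₁ ≤ e ≤ v₂* at a candidate source with *v₂ − v₁ ≤ 182* and ≥ 2 visits
inside, and additionally **no imaging exam at the source inside the
bracket** — this operationalizes "requesting but not conducting" the exam.
All visit rows count toward the bracket (the claims give no reliable way to
separate consultation types).  The reported bracket is the tightest
qualifying one; ties on width resolve to the later-starting window.

When several facilities qualify, the default **nearest** policy attributes
the event to the facility whose in-bracket visit is closest in time to the
exam (ties: larger visit count, then lexicographically smallest id), so
each exam yields at most one event.  A one-event-per-qualifying-source
policy (`all`) is available, since the attribution choice is a genuine
modelling decision rather than a fact of the data.

Fiscal-year strata are assigned by **exam date**; brackets may cross FY
boundaries.

A `brute_force_oracle` re-derives the full semantics by exhaustive
enumeration over exams × facilities × visit-date pairs, sharing no code
with the indexed detector.  Detector ≡ oracle (set equality) is asserted
over randomized studies with injected violations and noise.

## Synthetic claims generator

The generator's defaults mirror the study conditions the package targets:
four Japanese fiscal years (2016-04-01 … 2020-03-31), every regular patient
enrolled for the whole span, facility bed counts drawn from a clinic-heavy
mix (0–400 beds) so that source/target bed-count contrasts are visible.

A planted network is laid out first: facilities split into contiguous
community blocks; each unordered pair connects with `within_community_prob`
inside a block and `between_community_prob` across blocks; exactly
`round(reciprocity_fraction · D)` of the D connected dyads become mutual
(a fraction, not a per-dyad probability — the recovery contract promises
the realized mutual share, and a Bernoulli split would leave sampling
noise of ≈ 0.035 at 200 dyads).  Every directed edge carries
`events_per_edge` intended events.

Each intended event occupies its own patient: an exam at the target at day
*e* and source visits at *e−d₁* and *e+d₂* with d₁, d₂ ∈ [1, 80] (bracket
width ≤ 160 < 182).  Violation episodes fail exactly one condition:
a second target exam within 91 days (condition 1); a bracket of width
184–240 days (condition 2); two close source visits both strictly after
the exam (condition 3).  Background noise adds Poisson-distributed
non-imaging visits at random facilities and dates.

Because noise can accidentally manufacture a qualifying source, every
patient's records are **verified with the brute-force oracle** and the
patient's noise is resampled on collision (up to 50 retries, then a
generation error).  Ground truth is therefore exact — under the default
windows and the nearest policy, which is the regime all recovery claims
refer to.  Randomness is hierarchical (`(seed, patient index)` substreams),
so identical configs are byte-identical and enlarging the population never
reshuffles existing patients.

What the generator does **not** emulate: disease trajectories, seasonal or
weekday visit patterns, facility geography, costs, coding noise, or
realistic prefecture-scale volumes.  Passing recovery tests shows the
pipeline is correct under the rule's own assumptions, not that the rule
captures true referral intent in real data.

## Networks and metrics

Nodes are facilities appearing in ≥ 1 event of the stratum — facilities
with no shared-use activity are unknowable from events alone and would
dilute density arbitrarily.  Density uses **distinct ordered pairs**
(unweighted m); published density magnitudes (~3×10⁻³ on a few hundred
nodes) are consistent with counting connections, not events.  Reciprocity
is **dyadic** by default (mutual pairs / connected pairs); the edge-wise
convention 2a/(2a+b+c) sits behind a flag because the conventional a, b, c
notation does not determine which was meant.

Modularity is Newman–Girvan Q on the symmetrized weighted projection
(w_ij = sum of both directed weights), the domain on which classical
Louvain is defined.  The Louvain implementation does seeded-shuffle local
moving (move set: all neighbouring communities plus isolation into a fresh
community), aggregation, and repetition until no pass improves; pass-level
Q values are recorded and are non-decreasing by construction.  Greedy local
moving can stall in order-dependent local optima, so the procedure restarts
`n_restarts` (default 10) times — the first from the classical all-singleton
start, the rest from random initial partitions — and keeps the best Q.
Gains below 1e-10 are treated as noise.  An exhaustive set-partition
enumeration (feasible to ~10 nodes, Bell(8) = 4140 partitions) serves as
the independent optimum reference in tests; the random graph suite for that
comparison is drawn from the package's own planted-network generator, i.e.
sparse small-integer-weight graphs of the kind the pipeline actually
produces.

## Reporting and tests

The volume table reports shared exams **per 100 examinations**
(100 · shared/total, displayed to 3 decimals); underlying CSVs keep full
precision.  Facility summaries use the sample SD (n−1), left empty below
two facilities.  Year-to-year comparisons use Kruskal–Wallis (tie-corrected
H, χ² reference); CT vs MRI uses the two-sided Mann–Whitney U (normal
approximation with tie and continuity corrections, reporting min(Uₓ, Uᵧ)).
Degenerate all-identical inputs return H = 0 / p = 1 with a flag rather
than an error.  Which per-facility quantity feeds the CT-vs-MRI comparison
is not standardized; the pipeline uses per-facility request counts and
labels the output accordingly.

## Problem sizes and determinism

The test and acceptance experiments use deliberately small studies — 100
randomized configs of ≤ 200 patients for oracle parity, a 50-facility /
400-patient study for reciprocity recovery (~250 dyads), 20 seeds of the
4×25 planted-community layout for ARI, 200 generator-drawn graphs of ≤ 8
nodes for the exhaustive-optimum comparison, and 1000 replicates for test
calibration — sizes at which the exhaustive oracles remain tractable while
every property still has power.  All randomness flows from explicit seeds;
reruns are byte-identical.

## Known limitations

- Attribution under the nearest policy is heuristic; claims cannot confirm
  referral intent, and simultaneous care at two facilities can misattribute.
- A single enrollment span per patient; multi-span coverage histories are
  treated as gaps.
- Community detection on the symmetrized graph discards edge direction;
  directed-modularity variants are out of scope.
- The generator's one-episode-per-patient layout avoids episode
  interference by construction; real patients with several qualifying
  episodes per year are exercised only implicitly (nothing in the detector
  assumes one episode, and the oracle-parity suite covers multi-exam
  patients arising from condition-1 violations).
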