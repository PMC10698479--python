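# Methods

This note documents the models, conventions and numerical choices behind
`focalscan`, and what its synthetic scenarios do and do not establish.

## Observation model and edge weights

An observation dataset consists of a group roster with half-open membership
intervals `[entry, exit)`, session logs (focal follows with a focal id;
scan sessions with the list of visible individuals), and dyadic events
(timestamp, behaviour, actor, recipient, method). Timestamps are ISO-8601
in files and plain seconds internally; a session belongs to a membership
interval by its start time.

The network for one behaviour and one method has edge weight

```
W[i, j] = (events between i and j) / exposure(i, j)
```

where the **co-presence exposure** is the accumulated focal observation
time in hours (FAS) or the count of scan sessions (ABS) during which both
individuals were resident in the group. Two conventions here deserve
comment:

* *FAS exposure is observation time, not calendar time.* The field
  description ("the amount of time in which both members of the dyad were
  present") can be read either way. Observation hours put FAS weights in
  events per observed hour, exactly parallel to the ABS events-per-session
  scale, and make weights invariant to gaps in the field schedule. The
  calendar reading is implemented behind `exposure_mode="calendar_hours"`.
* *ABS exposure counts sessions where both were resident, not co-visible.*
  Visibility varies within a session and the per-session visible list is a
  snapshot; residency is the denominator that matches the FAS convention.

Dyads whose exposure is zero (never co-resident during observation) get
weight 0 and a `zero_exposure` flag rather than a missing value, so metric
code has no missing-data branch. Networks are undirected by default (counts
symmetrized before dividing); a directed mode exists for aggression but is
not used in the headline pipeline, since all global metrics are defined on
the undirected form. Node order is lexicographic by id everywhere, making
every matrix byte-reproducible.

## Metrics

Degree and density are unweighted (an edge wherever the rate is positive);
eigenvector, betweenness, modularity and centralization are weighted.

* **Degree** `k_i / (n-1)` in [0, 1].
* **Eigenvector** — leading eigenvector of `W` by power iteration with a
  diagonal shift `W + w_max I` (same eigenvectors, guarantees a spectral
  gap so bipartite-like graphs converge), uniform start, successive-change
  tolerance 1e-10 (cap 1e5 iterations), max-normalized so the most central
  animal scores 1. All-zero networks return zeros; on disconnected networks
  the vector reflects the dominant component and a structure warning is
  emitted.
* **Betweenness** — shortest paths under edge length `1/w` (stronger ties
  are shorter — the dominant convention for affiliation-rate networks),
  Brandes accumulation counting all geodesics, divided by `(n-1)(n-2)/2`.
* **Density** `m / (n(n-1)/2)`.
* **Modularity** — weighted Newman–Girvan `Q` of the best partition found
  by deterministic greedy agglomeration (merge the pair with the largest
  positive gain; ties broken lexicographically by community label, so runs
  are reproducible). `exact=True` enumerates all partitions (n ≤ 12) and is
  oracle-tested against an independent enumeration; greedy is the default
  at pipeline scale.
* **Centralization** `C = Σ_i (c_max − c_i) / [(n−1) − √(n−1)]`, the
  Freeman-style index with the star-graph normalizer so values are
  comparable across group sizes. The star bound makes `C ∈ [0, 1]` for
  connected binary graphs; on weighted or disconnected networks a single
  dominant dyad can push `C` slightly above 1 (supremum
  `(n−2)/[(n−1)−√(n−1)]`). We keep the conventional normalizer and document
  the bound rather than clipping.

These conventions are fixed and oracle-tested (networkx references for the
standard metrics, brute-force enumeration for modularity and betweenness on
small graphs) rather than tuned to reproduce any particular published
value, since the exact normalizers used by other software are not always
stated.

## Robustness

Two diagnostics ask whether the observed network has stabilized:

* **Accumulation curves** — one network per 30-day block of the study,
  built from all data up to the block's end (a per-month mode exists) and
  restricted to individuals resident at that time; the metric (group mean
  for local metrics) is plotted against cumulative effort. Density can
  genuinely drop when an individual departs and its edges vanish.
  **Stabilization effort** is the smallest cumulative effort after which
  every subsequent relative change stays below ε = 5% (the threshold is a
  package choice; only the qualitative "flattening" is inherited from field
  practice). The final period cannot vacuously count as stable, and a curve
  that keeps fluctuating returns an open flag.
* **Uncertainty index** — for each of B = 1000 replicates, every event's
  recipient is redrawn uniformly among the actor's co-resident groupmates,
  the network rebuilt and the metric recomputed; the index is the width
  `q_0.975 − q_0.025` of the replicate distribution. Reshuffling conserves
  each actor's event count by construction. Recipients are drawn
  independently per event (resampling, not a permutation — the scheme is
  underdetermined in field descriptions and this one is simplest); in a
  two-animal group the reshuffle is the identity and the width is exactly
  0. Replicates are vectorized over events, and monthly widths use
  cumulative datasets by default (per-month behind a flag). One caveat: the
  width of edge-count-based metrics (degree, density) tracks the occupancy
  variance of reshuffled events over dyads, which *rises* until roughly one
  event per dyad has accumulated and only then falls — so the familiar
  month-on-month decline of the uncertainty index presumes a reasonably
  well-sampled first month.

## Protocol comparison

* **Local metrics.** The ABS value of each individual is the outcome of a
  logit-link beta regression in the mean–precision parameterization
  (`y ~ Beta(μφ, (1−μ)φ)`, `logit μ = Xβ + u_group`), with the FAS value,
  species, and optionally their interaction as predictors and a normal
  group random intercept. Outcomes at the [0, 1] boundary are first
  compressed with the Smithson–Verkuilen transform
  `y' = (y(N−1) + ½)/N`. The marginal likelihood integrates the random
  intercept by *adaptive* Gauss–Hermite quadrature: a 1-d Newton search
  finds each group's conditional mode and curvature (the Laplace
  approximation), and 15 (pipeline) or 9 (replicated simulations) nodes are
  centred there. Optimization is L-BFGS-B on `(β, log φ, log σ)` with an
  analytic gradient in the fixed-effects case; Wald standard errors come
  from a numerical Hessian. The implementation reproduces `glmmTMB`
  coefficients to ~1e-5 on shared data.
* **Model selection.** Null (no FAS term), main-effects, and interaction
  models are compared by `AIC = 2k − 2 logL`; among models within 2 AIC of
  the minimum the one with fewest parameters is selected.
* **Permutation null.** Because metrics of individuals in the same network
  are not independent, the selected model's FAS slope is re-tested against
  a node-swap null: node identities of each group's ABS network are
  shuffled within group (equivalently, the outcome metric's assignment to
  individuals is permuted within group, preserving the random-intercept
  design), the model refitted, and the one-tailed p computed with the
  add-one estimator `p = (1 + #{β* ≥ β̂})/(B + 1)`, which can never be 0.
  Replicate seeds are spawned from the master seed so enlarging B leaves
  earlier replicates unchanged. Refits use the full mixed model by default;
  a fixed-effects mode exists for replicated calibration studies, where the
  null rejection rate at p ≤ 0.05 with B = 19 is exactly 1/20 under
  exchangeability and verified by simulation.
* **Global metrics.** One value per group and method; Pearson's test with
  `t = r√((n−2)/(1−r²))` on n−2 degrees of freedom, run with and without
  listed group exclusions (mirroring the practice of re-testing after
  removing groups with known demographic upheaval), plus a leave-one-out
  sweep to flag influential groups.

## Synthetic scenario generator

The generator emulates the study system, not any particular dataset:

* **Demography.** Groups of 10–60 adults (~60% female), all present from
  the study origin; departures follow a constant hazard calibrated so the
  expected whole-study retention matches the target (0.69–0.84 in the
  presets, as reported for the field groups). No immigration: turnover is
  departure-only, which is the part that affects exposure denominators.
* **Latent structure.** A dominance rank permutation and matrilines whose
  sizes are Dirichlet-skewed (real matrilines vary strongly in size; a
  uniform assignment would make affiliation structure nearly flat and leave
  centrality with no signal to recover). Ordered-dyad rate matrices per
  behaviour, each normalized so its off-diagonal mean equals the style's
  base rate: grooming `∝ exp(κ·kin + 2d·rank-score of recipient)` (kin- and
  up-hierarchy-biased, increasing with despotism `d`); huddling symmetric
  with a style-independent kin bias — the despotic presets differ from the
  tolerant one in huddling *frequency* (rarity multipliers 0.15 and 0.01
  versus 1.0), not structure, because rarity is the mechanism under study;
  aggression concentrated on down-rank dyads with the up-rank share
  shrinking to 0 at `d = 1`. Base rates (events/h/dyad: grooming 0.05–0.06,
  huddling 0.05, aggression 0.02–0.04) were chosen once to yield monthly
  event volumes of the same order as the field protocols report.
* **Observation.** FAS: each subject is targeted for two 10-minute follows
  per week on random days (randomized daily order, 08:00–12:00); during a
  follow, events between the focal and each co-resident are Poisson with
  mean `(λ_ij + λ_ji) × duration`, the actor chosen proportionally.
  ABS: twelve 10-minute sessions per week (13:00–17:00, so the protocols
  never overlap in time); each resident is visible independently with
  probability v = 0.9, and events among visible dyads are Poisson thinned
  by a detection efficiency η = 0.75 (a single-factor stand-in for
  everything an observer scanning a group misses). Both simulators assert
  their defining invariants on every log: FAS events involve the focal;
  ABS events involve only visible individuals.
* **Reproducibility.** All randomness flows from one master seed through a
  spawned seed tree (master → group → population/FAS/ABS), so outputs are
  byte-identical across runs and partial re-simulation is stable.

What the generator does **not** contain: behavioural contagion or bouts
(events are instantaneous and independent), diurnal or seasonal rhythm,
spatially explicit movement or proximity-driven visibility (visibility is
i.i.d. Bernoulli), observer bias beyond the uniform η, immigration, or rank
dynamics. Passing tests on these scenarios therefore show that the
*pipeline* is correct and that the directional findings follow from the
sampling processes themselves; they do not certify behaviour on data with
temporal structure the generator omits.

## Problem sizes

The test suite and the acceptance script run scaled-down scenarios — two to
three groups of 12–20 animals over 4–12 months, bootstrap/permutation
replicates between 19 and 10⁴ depending on what the check needs — sizes
chosen so the full suite exercises every code path at desk scale. The
pipeline itself handles the full eight-group design
(`study_design_config()`, up to 60 animals and 18 months per group) with
B = 1000.

## Known limitations

* Modularity's greedy agglomeration is a local optimizer; it is exact-mode
  checked only for n ≤ 12, and on larger groups `Q` is a lower bound on the
  optimum (the standard caveat for all agglomerative community detection).
* Centralization can exceed 1 on weighted networks dominated by one dyad
  (see above); comparisons across networks remain valid, the [0, 1] scale
  reading does not.
* The beta GLMM assumes a single grouping level and a scalar random
  intercept; crossed or nested designs are out of scope.
* Months are fixed 30-day blocks from the dataset origin, not calendar
  months.
* Wald intervals and AIC rely on the usual asymptotics; with 8 groups the
  random-intercept variance itself is estimated imprecisely (its coverage
  is not certified — only the slope's is).
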