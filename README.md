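# focalscan

Social network analysis of animal groups from the two behavioural sampling
protocols field primatologists actually use — and a toolbox for asking
whether they measure the same thing.

In **focal-animal sampling (FAS)** an observer follows one animal for a
fixed interval (here 10 minutes) and records every social interaction that
animal is involved in. In **all-occurrences behaviour sampling (ABS)** the
observer scans a (sub)group for 10 minutes and records every instance of the
target behaviours among the animals visible. FAS yields rich but slow
per-individual data; ABS covers many dyads at once but may miss events.
Whether networks built from the two protocols agree — per behaviour
(grooming, huddling, aggression) and per species social style (tolerant vs
despotic macaques) — decides which protocol a study can rely on.

`focalscan` provides, as an importable library with a thin CLI:

* **Network construction** — edge weights are dyadic interaction *rates*:
  event counts divided by the co-presence exposure of the dyad, i.e. the
  observation hours (FAS) or number of scan sessions (ABS) during which both
  animals were resident in the group, so membership turnover does not bias
  weights.
* **Six standard metrics** — local: degree `k_i/(n-1)` (unweighted),
  eigenvector centrality `c_i` (weighted, power iteration, max-normalized),
  betweenness `b_i` (weighted, edge length `1/w`, Brandes, normalized by
  `(n-1)(n-2)/2`); global: density `D = m / (n(n-1)/2)`, weighted
  Newman–Girvan modularity `Q` (deterministic greedy agglomeration, exact
  enumeration for small groups), and Freeman-style eigenvector
  centralization `C = Σ_i (c_max − c_i) / [(n−1) − √(n−1)]`.
* **Robustness diagnostics** — metric trajectories over cumulative monthly
  datasets, an effort-to-stabilization estimate, and a bootstrap
  *uncertainty index*: the width of the 95% interval of a metric's
  distribution under 1000 recipient reshuffles.
* **Protocol comparison** — per-individual metrics: logit-link beta mixed
  regression (ABS metric ~ FAS metric × species, group random intercept,
  adaptive Gauss–Hermite quadrature), AIC model selection with a parsimony
  rule, and node-swap permutation p-values; per-group global metrics:
  Pearson correlation tests with outlier-exclusion reruns.
* **A synthetic study generator** — macaque-like groups with dominance
  ranks, skewed matrilines and species-style presets (`tolerant_bonnet`,
  `despotic_rhesus`, `despotic_longtailed`), demographic turnover, and
  faithful simulators of both observation protocols, so every analysis is
  testable end-to-end without field data.

## Worked example

```python
import focalscan as fs

config = fs.ScenarioConfig(
    groups=[fs.GroupConfig(name="Temple", size=12, style="despotic_rhesus",
                           retention=1.0, months=4)],
    seed=7,
)
group = fs.make_scenario(config).groups["Temple"]
net = fs.build_network(group.events, group.roster, group.focal_sessions,
                       behaviour="grooming", method="FAS")
ms = fs.compute_metrics(net)
print(f"density        {ms.density:.3f}")
print(f"modularity     {ms.modularity:.3f}")
print(f"centralization {ms.centralization:.3f}")
```

prints

```
density        0.606
modularity     0.162
centralization 0.518
```

— in this simulated despotic group 61% of dyads groomed at least once, the
network splits only weakly into clusters (Q = 0.16), and one high-ranking
animal dominates indirect connectedness (C = 0.52, about half the maximal
star-like concentration). The `examples/` directory has one short script per
capability (simulation, metrics, robustness, comparison, full pipeline);
each prints the numbers it computes and what they mean. The same pipeline
runs from the shell:

```bash
focalscan all --config scenario.yaml --seed 17 --out results/ --B 1000
```

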