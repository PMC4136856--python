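# corridorscape

Quantitative corridor planning for wildlife in fragmented mountain
landscapes, built as a Python library around a fully synthetic, ground-truth
valley system.

Conservation corridors are often drawn from expert opinion.  This package
implements the quantitative alternative end to end: estimate where the focal
species actually is from imperfect survey data, turn that estimate into a
movement-cost surface, identify corridors with least-cost and circuit-theory
models, and test how much candidate management actions (habitat restoration,
residence relocation, a road tunnel) would improve them.  It is aimed at
quantitative ecologists and conservation analysts who want a tested,
seed-reproducible reference implementation of this workflow — every stage
can be exercised against landscapes whose generating parameters are known.

## The models

**Occupancy with imperfect detection.** Sites are occupied with probability
ψ and, if occupied, detected on a 5-day camera occasion with probability p,
both logit-linear:

    logit(ψ_i) = β₀ + β·x_i          logit(p_it) = α₀ + α·w_it
    L_i = ψ_i ∏_t p_it^y_it (1−p_it)^(1−y_it) + (1−ψ_i)·1[all y_it = 0]

Maximum likelihood, AIC ranking of all covariate subsets, Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), and model averaging (zero substitution)
over the ΔAIC ≤ 2 set give one predictive equation, validated against
independent sign transects by rank-based AUC with a 1-km confirmed-absence
rule.

**Connectivity.** The suitability map inverts to cost = 1 + 99·(1 − ψ).
Cells form an 8-neighbour graph with edge weight mean(cost)·distance;
Dijkstra yields accumulated-cost and backlink rasters and least-cost paths
(5 × 5 source/sink points → 25 candidate pathways, compared by cost per
100 m).  The same surface, read as resistance, defines a resistor network
solved by sparse Kirchhoff elimination for current density, effective
resistance, and buffered omnidirectional current maps.

**Scenario statistics.** Landscape edits re-derive every dependent layer;
the fixed 25 pathway geometries are re-costed; scenarios are compared by
two-way ANOVA (scenario + pathway) and paired t-tests with Holm's
step-down correction at family-wise α = 0.05.

## Worked example

`examples/02_fit_occupancy.py` simulates a 240-site camera survey on a
generated valley landscape and refits the full selection chain:

```
240 sites, up to 10 five-day occasions, naive detection rate 0.21
selected detection covariates: ['lure', 'temperature']

top of the model-selection table:
                                       occupancy_covariates  K     AIC  delta_AIC  AIC_weight  cumulative_weight
 elevation, slope, bamboo, forest_age, dist_large_residence 10 1096.61       0.00        0.31               0.31
 elevation, slope, bamboo, forest_age, dist_road, dist_l... 11 1096.68       0.08        0.30               0.60
            elevation, slope, bamboo, forest_age, dist_road 10 1097.57       0.97        0.19               0.79

model-averaged coefficients (standardized logit scale) and importance weights:
  elevation              importance 1.00   coef -1.57
  bamboo                 importance 1.00   coef +2.07
  dist_large_residence   importance 0.76   coef +0.70
```

Detection is helped by scent lure and hindered by warm weather; occupancy
favours low elevation, bamboo and mature forest, and suffers near roads and
large residences — and the covariates present in every top model carry
importance 1.00.  `examples/05_scenarios.py` then compares management
options on the bundled valley fixture:

```
mean movement-cost index (per 100 m) by scenario:
  baseline        4796 +/- 36 SE
  restoration     4424 +/- 32 SE
  relocation      4796 +/- 36 SE
  tunnel          4274 +/- 41 SE

Holm-corrected paired t-tests:
  restoration  vs baseline     t = -69.83  p_holm = 1.2e-28  (significant)
  relocation   vs baseline     t =    nan  p_holm = 1        (not significant)
  tunnel       vs baseline     t = -25.91  p_holm = 1.4e-18  (significant)
  tunnel       vs restoration  t =  -7.07  p_holm = 5.3e-07  (significant)
```

Restoration and the tunnel significantly cheapen dispersal, relocating
residences does not, and the tunnel is the single most effective action.

The other example scripts cover landscape simulation (`01`), map validation
(`03`, AUC 0.97 with 62 presences / 58 confirmed absences), corridor and
circuit mapping (`04`), and the one-command pipeline (`06`, also available
as `corridorscape run --out runs/demo`).

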