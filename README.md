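# firestand

Spatial point-pattern analysis of fire-mediated tree mortality in mapped
forest stands.

## The problem

Dry conifer forests that historically burned every few years carried fewer,
larger trees arranged in a fine-grained mosaic of clumps, single trees and
openings.  A century of fire exclusion has filled those openings with dense,
small, shade-tolerant trees.  When fire returns, the two structures respond
very differently: heterogeneous stands lose clustered pockets of small trees
and keep their large-tree skeleton, while homogenized stands lose almost
everything.  Quantifying that contrast requires treating a stand as a
*marked point pattern* — tree stems as points, with species, diameter
(dbh), and crown attributes as marks — and asking second-order questions:
are trees aggregated, are neighbors alike in size, are fire-killed trees
clustered, and is mortality density-dependent?

`firestand` is a library for exactly this workflow, aimed at forest and
fire ecologists working with stem maps (tree censuses with coordinates).
It provides:

- **`stem_data`** — a validated stem-map container over pandas, delimited
  I/O with configurable column mapping, and stand-structure summaries
  (trees/ha, basal area, quadratic mean diameter, canopy base height as the
  10th-percentile crown base).
- **`synthetic_forest`** — a two-layer stand generator (Thomas cluster
  process plus a hard-core dispersed overstory, with cluster-coupled
  lognormal diameters) and presets for *historical* (≈300–430 trees/ha,
  QMD 42–48 cm, strongly clustered and size-segregated) and *contemporary*
  (≈680–850 trees/ha, QMD 32–36 cm, weakly clustered, low crowns) stands,
  so every stage runs without field data or a fire model.
- **`fire_effects`** — per-tree crown consumption from a neighborhood
  surrogate (consumption rises with local basal area, falls with crown
  base height), and deterministic mortality classification
  p = logistic(b0 + b1·C + b2·C² + b3·dbh + b4·C·dbh), killed iff p ≥ 0.5,
  with species-keyed coefficient tables.
- **`spatial_stats`** — pair correlation functions g(r) (homogeneous and
  inhomogeneous, translation edge correction on rectangles), bivariate
  g₁₂(r), the mortality contrasts
  g_cluster(r) = g_dead,dead − g_alive,dead and
  g_densdep(r) = g_dead,all − g_alive,all, the r-mark correlation k_dbh(r)
  and the normalized mark variogram γ_dbh(r) = mean ½(dbhᵢ−dbhⱼ)²/s², plus
  an edge-renormalized Epanechnikov kernel intensity field.
- **`inference`** — null models (inhomogeneous Poisson from the estimated
  intensity, random labeling, random marking) and studentized max-|z|
  global envelopes: with 399 simulations at α = 0.05 the critical value is
  the 380th order statistic of the null maxima, a single excursion anywhere
  in r ∈ (0, 15] m is significant, and each curve is condensed to an
  r-averaged z effect size.
- **`group_dynamics`** — tree groups by 6-m chaining (connected
  components), size classes (single, 2–4, 5–9, 10–19, 20+), tree-flow
  matrices between prefire and postfire classes (Sankey-ready), and the
  two distribution tests: rank-based location test and a signed
  likelihood-ratio test (SLRT) for equality of coefficients of variation.
- **`pipeline`** — `run_scenario` / `compare_scenarios`: one master seed,
  deterministic per-stage seeds, plain-text outputs.

## Worked example

```bash
python examples/pattern_statistics.py
```

```
historical stand, n = 410 trees on 1 ha
g_all: significant=True  r-averaged z=+3.55  (aggregation if > 0)
gamma_dbh: significant=True  r-averaged z=-2.10  (size segregation if < 0)
```

The generated historical stand is significantly aggregated relative to an
inhomogeneous Poisson null (the pair correlation escapes the 399-simulation
global envelope, mean z ≈ +3.6), and neighboring trees are significantly
more alike in diameter than random marking allows (normalized mark
variogram below 1, mean z ≈ −2.1) — the classic frequent-fire signature.

```bash
python examples/burn_and_classify.py
```

```
historical     n= 294  mean consumption= 55.0%  mortality= 38.1% of stems  surviving mean dbh= 49.7 cm  (prefire  46.1 cm)
contemporary   n= 738  mean consumption= 83.6%  mortality= 85.6% of stems  surviving mean dbh= 42.4 cm  (prefire  30.5 cm)
```

The same fire mechanism, applied to both stand structures, consumes far
more canopy in the dense low-crowned contemporary stand and kills most of
its stems; in both eras the survivors are larger than the prefire average.

## Limitations

The surrogate fire is a statistical stand-in, not fire physics; mortality
coefficients shipped with the package are illustrative, not published
regressions — supply your own table for real analyses.  See
`docs/methods.md` for the full model description, parameter defaults, and
numerical conventions.
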