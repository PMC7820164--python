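# Methods

This note documents the models, estimators, defaults and numerical
conventions implemented in `firestand`, and what the synthetic study
conditions do and do not show about real stands.

## Stem maps and structure summaries

A stem map is a table of trees (unique id; x, y in meters inside a
rectangular window; species code; dbh in cm; optionally height, crown base
height in m, crown consumption fraction, alive/killed status).  Coordinates
are continuous, Euclidean, conventionally 0-based at the window's lower-left
corner; all statistics are invariant to rigid translation.  Structure
summaries: trees/ha; basal area Σπ(dbh/200)² per ha; quadratic mean
diameter √(Σdbh²/n) (≥ the arithmetic mean by Jensen's inequality); canopy
base height as the empirical 10th percentile of crown base heights using
the linear-interpolation quantile convention.  A minimum-dbh census filter
is an explicit reader option (field censuses often truncate at ~9–10 cm);
default none.

## Synthetic stand generator

Two superposed layers:

1. **Clustered layer** — Thomas process: Poisson parents with intensity κ
   (m⁻²), Poisson(μ) offspring per parent displaced by isotropic Gaussian
   N(0, σ²I).  Parents are simulated in a 4σ buffer around the window so
   boundary clusters are not thinned; offspring landing outside the window
   are discarded (no toroidal wrap).  The closed-form pair correlation
   g(r) = 1 + exp(−r²/4σ²)/(4πσ²κ) provides an independent oracle for the
   estimator.  The Thomas form was chosen over alternatives (e.g. Matérn
   cluster) precisely for this closed form.
2. **Overstory layer** — n_large trees with a hard minimum spacing
   r_inhibit, placed by sequential rejection (dart throwing) with a global
   cap of 10,000 proposals; infeasible packings raise an error.  This
   emulates the dispersed, fire-resistant large-tree component.

Diameters are lognormal.  For clustered trees,
log dbh = log(median) + s·(√c·G_cluster + √(1−c)·ε) with one standard
normal G per cluster and ε per tree: `mark_coupling` c is exactly the
fraction of log-diameter variance carried at cluster level.  c > 0 yields
the size-segregation signature (normalized mark variogram < 1 and r-mark
correlation below the stand mean at short range); c = 0 yields spatially
independent marks (variogram ≈ 1 everywhere).  Crown base height follows
cbh = cbh_median·(dbh/median_dbh)^0.7·lognormal noise, capped at 90% of a
saturating height-diameter allometry; heights are carried for realism but
unused by the statistics.

### Era presets

| parameter | historical | contemporary |
|---|---|---|
| κ (parents/m²) | 0.003 | 0.012 |
| σ (m) | 3 | 6 |
| μ (offspring) | 11.2 | 6 |
| large trees /ha (spacing) | 15 (≥12 m) | 8 (≥10 m) |
| dbh median (log-sd) | 37 cm (0.35) | 28 cm (0.35) |
| large-tree dbh median | 90 cm | 80 cm |
| mark_coupling | 0.6 | 0.2 |
| cbh_median | 4 m | 1.6 m |
| species mix | pine-dominated | fir/cedar-dominated |

These reproduce, in expectation, stand densities of ≈350 vs ≈730 trees/ha
and QMD ≈45 vs ≈33 cm — the documented contrast between frequent-fire and
fire-excluded mixed-conifer structure — with tight, well-separated clumps
and strong size segregation historically versus diffuse, overlapping
clusters of intermixed sizes today.  The fir/cedar-dominated contemporary
mix reflects shade-tolerant infill during fire exclusion.  Presets are
parameterized by window, so per-hectare conditions are independent of plot
size.

**What the generator does not emulate:** multi-scale aggregation and
long-range density gradients of real stands, species-specific spatial
niches, regeneration dynamics, and edge-truncated group structure.
Passing tests on these synthetics demonstrates correctness of the
estimators and the directional mechanisms, not quantitative agreement with
any particular field plot.

## Fire effects

**Surrogate consumption.**  For tree i, NBA_i = basal area of neighbors
within `radius` (default 6 m, the group-linkage scale; basal area rather
than stem count, so big-tree clumps count as heavy fuel concentrations):

consumption_i = logistic(a0 + a1·z(NBA_i) − a2·z(CBH_i) + ε_i),
ε ~ N(0, noise_sd²).

z(·) standardizes within the map by default.  The era presets instead use
fixed reference scales (NBA: mean 0.9 m², sd 0.6; CBH: mean 3 m, sd 2 —
midpoints between the two preset conditions) so that absolute stand
density matters and the denser, lower-crowned condition receives
systematically more consumption; with within-map standardization the mean
logit would be a0 regardless of density, which cannot express the
cross-stand severity contrast.  Preset gains a0 = 1.1, a1 = 1.5, a2 = 2.4,
noise 0.3 were set from the preset stands' NBA/CBH distributions to target
mean crown consumption near 50% (historical) vs 85% (contemporary), the
direction and rough magnitude of the open-vs-dense severity contrast; the
gains are identical across eras so all divergence comes from structure.

**Mortality.**  p = logistic(b0 + b1·C + b2·C² + b3·dbh + b4·C·dbh) with C
in percent (the coefficient-table contract declares the percent scale);
killed iff p ≥ 0.5 (threshold configurable), deterministically.  The
shipped coefficient table is *illustrative only* — shaped so that death
rises with consumption, falls with diameter, and firs are more vulnerable
than thick-barked pines — and is not a published regression; user tables
load from delimited text keyed by species, with a `__default__` row for
unlisted species.  Externally simulated fires join by tree id through a
two-column consumption table.

## Pattern statistics

Distances are binned into 1-m annuli with centers 0.5 … 14.5 m (r ∈ (0,15];
no estimate at r = 0).  All pair statistics use the translation (Ohser)
edge correction: each ordered pair carries weight 1/T with
T = (W−|dx|)(H−|dy|), exact on rectangles.  The pair-correlation estimator
is ĝ(r_k) = Σ 1/(λᵢλⱼT) / A_k over ordered pairs in ring k, A_k the ring
area; with constant λ̂² = n(n−1)/|W|² the homogeneous estimator has
expectation exactly 1 under CSR, and with the true λ plugged in the
inhomogeneous estimator has expectation 1 under an inhomogeneous Poisson
process.  The bivariate ĝ₁₂ divides by the type-2 intensity (not
symmetric); a point may belong to both types (type2 = all trees), with
self-pairs excluded, and the normalization n₁n₂−|overlap| makes
ĝ₁₂(all, all) bit-identical to the univariate estimator (shared code path).
Empty rings give 0 for pair correlations and NaN for mark statistics.

Mark statistics are ratio estimators with the same translation weights in
numerator and denominator: k_mark(r) is the weighted mean mark of the
second point of pairs at lag r, reported in mark units with the stand mean
as reference; the mark variogram is the weighted mean of ½(mᵢ−mⱼ)²,
divided (when normalized) by the sample variance (ddof = 1), which is
exactly the expectation of the pairwise semivariance under independent
marks, so independent marks give 1.

The mortality contrasts are g_cluster = ĝ_dead,dead − ĝ_alive,dead and
g_densdep = ĝ_dead,all − ĝ_alive,all, both 0 in expectation under random
labeling.

**Intensity field.**  2-D Epanechnikov kernel (support = bandwidth,
default 20 m) on a 1-m grid, per-point edge renormalization by the kernel
mass inside the window, so the field integrates to n.  λ is read at the
nearest cell center; values are floored at 10⁻⁹ before division.  For
normalizing a pattern by its *own* estimate, `points_lambda` subtracts the
self-contribution k_e(0)/w_i (leave-one-out); without it every point
inflates its own intensity and ĝ is biased low at all lags.

## Null models and global envelopes

Three nulls: **inhom_poisson** (points redrawn from the Epanechnikov
intensity estimate of the observed pattern, conditioned on n by default to
isolate second-order structure; an unconditioned mode exists),
**random_label** (alive/killed permuted over fixed locations — the correct
conditioning for mortality given the prefire pattern), **random_mark**
(dbh permuted over fixed locations).

All curves (observed + n_sim nulls, default 399) are studentized bin-wise
with the pooled mean and sd; pooling keeps the observed curve exchangeable
with the nulls under H0, so the rank-based test is exact.  The global
critical value c is the ⌈(n_sim+1)(1−α)⌉-th smallest of the null maxima
M_j = max_r |z_j(r)| (with 399 simulations and α = 0.05: the 380th order
statistic, size exactly 20/400); the observed curve is significant iff
M_0 > c, equivalently iff it leaves the back-transformed band m(r) ± c·s(r)
anywhere.  This symmetric two-sided max-|z| construction is the
studentized-envelope equivalent of banding the 2.5–97.5 percentiles of the
z curves.  Bins with zero pooled sd contribute z = 0 (warned); bins that
are NaN in any curve are excluded.  The r-averaged z is the **signed**
mean of the observed z over the grid (an aggregation measure should carry
its direction; the |z| average is also reported).  Lowering α can only
raise c, so significance is monotone in α.

In the pipeline, the aggregation statistics (g_all, g_alive) are the
*ordinary* pair correlation tested against the inhomogeneous-Poisson null:
the inhomogeneity lives in the null model, not in the estimator
normalization.  Normalizing the empirical estimator by the data-estimated
intensity instead would absorb most of the fine-scale clustering into the
null (the 20-m kernel reconstructs cluster positions) and systematically
depress the observed curve at lags beyond the cluster scale; the
chosen construction asks the interpretable question "does the observed
pairing exceed what the smoothed density surface alone produces?".  The
inhomogeneous estimator remains available and is calibration-tested
against inhomogeneous Poisson draws with known intensity.

## Tree groups

Groups are connected components of the graph joining trees at distance
≤ linkage (6 m default); the threshold is inclusive — a pair at exactly
6.000 m is one group — which matters for hand-constructed cases.  Size
classes: single, 2–4, 5–9, 10–19, 20+.  Groups truncated by the window
edge are counted whole as observed (no fractional edge correction).  The
flow matrix assigns each tree one count from its prefire class to its
postfire class (survivors regrouped from scratch at the same linkage) or
to "killed"; row sums equal prefire class totals, and since the survivor
set is a subset of the trees, regrouping can split but never merge prefire
groups.

**Comparisons** (groups as units): the location test defaults to the
unpaired rank-sum (Mann–Whitney, normal approximation with tie correction,
exact for small untied samples) because era samples of groups are
structurally unpaired; a paired signed-rank form is exposed behind
`paired=True` for matched designs.  CV equality uses a signed
likelihood-ratio test under a normal model: the constrained fit profiles
the likelihood over the common CV τ (for fixed τ the per-sample MLE mean
solves nτ²μ² + (Σx)μ − Σx² = 0 in closed form; the 1-D profile is
maximized numerically with a bounded Brent search, tolerance 1e-10), and
R = sign(cv₁−cv₂)·√(2(l₁−l₀)) is referred to N(0,1) (two-sided; R² is the
χ²₁ LRT statistic).  A modified variant subtracts a parametric Monte Carlo
estimate of R's null mean before computing p — useful below n ≈ 20; at the
group-sample sizes of interest the unmodified test is already calibrated
(measured size ≈ 0.05 at n = 50 in the acceptance checks).  Degenerate
inputs (no variation in either sample) return statistic 0, p = 1.
Bonferroni adjustment multiplies p by the number of parallel comparisons
(default 3, for a three-plot design) and caps at 1.

## Pipeline and reproducibility

A scenario runs: load/generate → consumption → mortality → prefire
{g_all, k_dbh, γ_dbh} → postfire {g_alive} and mortality contrasts
{g_cluster, g_densdep} under random labeling (both contrasts share one set
of label permutations) → groups, flow, comparisons → plain-text artifacts
(stem maps, per-statistic envelope tables, verdict summary, flow matrix +
edge list, run log with library versions and seeds).  Stage k derives its
seed as (master·100003 + k) mod (2³¹−1), so stages re-run in isolation and
a run is byte-reproducible from the master seed.  Any stage failure aborts
with the stage name, leaving partial outputs and a FAILED_STAGE marker.

Default analysis settings: r_max 15 m, ring 1 m, bandwidth 20 m,
n_sim 399, α 0.05, linkage 6 m.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the statistical checks at
sizes chosen to give stable rates on a single CPU: calibration on 100 CSR
patterns (λ = 0.04/m², 1 ha); the Thomas oracle on 50 patterns (4 ha);
envelope size on 150–200 replicates of ~100-point patterns with 99 nulls;
density-dependence recovery on 30–50 one-hectare historical stands;
SLRT size on 1,000 replicates (n = 50 per sample); the era contrast on
paired 2-ha scenarios with 99 null simulations.  The estimator-vs-oracle
checks are exact (no tolerance beyond floating-point).  With 99 rather
than 399 nulls the envelope test keeps exact size 5/100 by the same order
statistic rule; 399 is the default for single analyses.

## Known limitations

- The surrogate fire is phenomenological: no spread, heat transfer, scorch
  physics, delayed mortality, or bark-beetle interactions.
- Shipped mortality coefficients are illustrative, not published values.
- No K/L functions, nearest-neighbor statistics, anisotropy, or
  replicated-pattern pooling; plots are analyzed separately.
- Group statistics ignore edge truncation of groups; group-size inference
  near windows' edges is biased accordingly.
- The inhomogeneous-Poisson null conditions on the observed count by
  default; unconditioned runs change envelope widths slightly.
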