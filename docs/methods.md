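# Model and methods

`beescape` simulates wild central-place-foraging pollinators — parameterized
here for common early-active bumble bees — on categorical land-use rasters,
and uses the simulation to compare agri-environment interventions. This note
documents the model equations, the parameter choices, what the synthetic
landscapes do and do not emulate, and the numerical decisions.

## Seasonal structure

A year has two floral periods: period 1 (oilseed-rape flowering, late
April–early June) and period 2 (late June–late August). Queens found nests in
spring (one queen = one nest = one colony), forage alone in period 1, and
raise workers; a fraction `p_w` of those workers forages in period 2; the
resources they gather determine how many new queens the colony produces at
the season's end. New queens overwinter in their natal cell and disperse the
next spring.

## Foraging and visitation

The rate at which cell *i* receives visits from the foragers nesting in cell
*j* during period *k* is

    V(j→i) = X_kj · F_ki e^(−d_ij/β) / Σ_q F_kq e^(−d_qj/β) · ρ_F^d_ij

with `X` the forager raster (queens in period 1, `p_w·W` in period 2), `F`
the floral-value raster (coverage × attractiveness), `d_ij` the Euclidean
distance between cell centers, `β` the mean foraging distance of an
exponential kernel, and `ρ_F` a per-meter survival rate. Foragers are assumed
to know the full resource distribution within reach: the denominator
allocates each forager's visits over all reachable flowers, so a farther but
richer cell can out-compete a nearer poor one. With `ρ_F = 1` (the default;
no en-route mortality) visitation is exactly conservative: ΣV = ΣX.

The kernel is truncated to zero beyond the 99th percentile of the exponential
distance distribution (`−β ln 0.01` ≈ 2.44 km for β = 530 m) — a
computational cutoff applied consistently in the numerator and the
normalization. All sums are evaluated as FFT convolutions with a precomputed
stencil; a brute-force double loop over cell pairs is kept in the test suite
as the oracle, and the two agree to 1e−10 on random landscapes.

Resources collected per nest in cell *i* are the foragers-per-nest times the
kernel-weighted mean floral value around the nest:

    R_ki = (X_ki / N_i) · Σ_j F_kj e^(−d_ij/β) / Σ_j e^(−d_ij/β)

There is no floral depletion, hence no exploitation competition; the
"apparent competition" the model produces is purely redistribution of a
finite forager pool. The summation set of the denominator equals that of the
numerator (the truncated disc), making the second factor a weighted mean.

## Colony growth

Resources map to offspring through the CDF `G(R; a, b)` of a lognormal
distribution parameterized by its **median** `a` (resources at which half the
maximum output is reached) and **variance** `b`:

    W_i   = Q_i · w_max · G(R_1i; a_w, b_w)       workers
    Q_E,i = Q_i · q_max · G(R_2i; a_q, b_q)       new queens

`G(0) = 0`, `G(a) = 0.5` exactly, saturating at 1. The log-scale variance σ²
is recovered from `(a, b)` by solving `(e^{σ²}−1)e^{2 ln a + σ²} = b` with a
bracketed root-finder (brentq on [1e−12, 50], tolerance ~1e−15). Note that
with the default `b = 2a`, σ is small (≈0.14 for the worker function, ≈0.011
for the queen function), so both responses are steep, nearly threshold-like
at `R = a` — the queen response in particular switches from ~0 to ~full
output over a few percent of resources. This steepness is a direct
consequence of parameterizing by (median, variance) at these values and
shapes much of the model's landscape-scale behavior (see Calibration).

## Overwinter dispersal and settlement

Expected queen arrivals redistribute the produced queens with an exponential
kernel of mean `β̃` (1,000 m, roughly twice the foraging distance), weighted
by how attractive destination cells are for nesting:

    A_i = w_i · Σ_j Q_E,j e^(−d_ij/β̃) / Σ_q w_q e^(−d_qj/β̃) · ρ_N^d_ij

The default destination weight `w` is the nesting-capacity raster (queens
search out nesting habitat); a literal self-weighted variant (w = current
queens) is available via `dest_weight` but is circular at settlement time and
confines the population to its current support, so it is not the default.
Arrivals are then truncated at the cell's capacity `NQ · n_max · cell_area`
— density-dependent mortality of nest-searching queens — and the realized
colony count is an independent Poisson draw per cell with the truncated
intensity. This draw is the model's only stochasticity; queens whose entire
reachable destination weight is zero are lost.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| n_max | nests in a best-quality cell | nests/ha | 19.6 |
| β | mean foraging distance | m | 530 |
| β̃ | mean nest-search distance | m | 1,000 |
| a_w, b_w | worker growth median / variance | resource units | 100 / 200 |
| a_q, b_q | queen growth median / variance | resource units | 15,000 / 30,000 |
| w_max | max workers per queen | — | 600 |
| q_max | max new queens per colony | — | 160 |
| p_w | proportion of workers foraging | — | 0.5 |
| ρ_F, ρ_N | per-meter survival (foraging / nest search) | 1/m | 1.0 |
| kernel quantile | truncation of the exponential kernel | — | 0.99 |

Variances default to twice their medians; `a_q` is a calibration constant
chosen so that realistic landscapes hold pollinators without saturating
before interventions are applied. Internal state is per 25 × 25 m cell
(0.0625 ha); `n_max` is converted once, in the nesting raster.

## Resource rasters

Floral value per cell and period is `coverage × attractiveness`; nesting
capacity is `NQ · n_max · cell_area`. Cells are mixtures of their patch land
use and the grassy margin habitat on field-block edges, combined by area
weighting with `f_edge = min(1, edge_length · margin_width / cell_area)`.
The original per-land-use scores were expert-elicited and are not public; the
shipped lookup table is this package's own fixture, chosen to respect every
qualitative constraint of the study system (margins: maximum nesting quality,
very low floral value; oilseed rape: strong period-1 pulse, nothing in period
2; flower strips: maximum period-2 attractiveness, high coverage, negligible
nesting) and calibrated as described below.

## Management interventions

* **Widened field margins**: margin width 2.4 m → 4.8 m for every field-block
  edge. Adds nesting capacity along edges; floral value on cereal borders is
  unchanged (margins share the cereal's very low floral score) and on
  oilseed-rape borders is diluted.
* **Flower strips**: 25 × 50 m strips (1 × 2 cells) covering 1.25% of the
  agricultural land, re-placed every year (annual plowing assumption). The
  supplementary placement algorithm of the original study is unavailable;
  ours is a deterministic two-scale greedy stand-in for "place where most
  beneficial": candidate cell pairs are scored by kernel-weighted reachable
  nesting capacity minus kernel-weighted existing period-2 floral supply
  (both max-normalized), the best pair seeds a cluster filled with up to 80
  strips within 1.25 km, and subsequent cluster seeds must lie ≥2.5 km from
  earlier ones. Clustering matters: a lone 0.125-ha strip shifts the
  kernel-weighted floral mean of its neighborhood by a few resource units,
  far below the ~50-unit queen-production threshold, so only strip clusters
  can start self-sustaining forage neighborhoods, while the spacing spreads
  them over distinct flower-poor regions. Placement uses baseline resources
  only, so all scenarios of a landscape-year share identical strip cells.
* Scenarios compose commutatively (margins then strips ≡ strips then
  margins), and baseline is the identity.

## Synthetic landscapes

The generator emulates intensively farmed southern-Swedish landscapes as
rectangular field-block tessellations (mean block area `mean_field_size`),
with per-block land use: seminatural grassland (clustered, see below),
non-habitat, or arable with a 7-year crop calendar of cereal, flowering ley
and oilseed rape. Ley occupies 2-year phases whose start years follow a
landscape-level Dirichlet weight vector (`ley_year_alpha = 0.5`), which
synchronizes rotations across blocks: total flowering-ley cover fluctuates
strongly between years while the long-run share stays at `ley_frac`. Oilseed
rape is assigned within the remaining years to meet `osr_target` on average,
moving between blocks from year to year. The edge raster books one 25-m side
per agricultural cell that faces non-agricultural land or the raster
exterior, and shared arable/arable block borders once (a single margin strip
between two fields). Sweeping `mean_field_size` from ~3 to ~60 ha and
`osr_target` from ~0.005 to ~0.16 spans edge areas of ~16–76 ha and
oilseed-rape areas of ~6–400 ha within a 3-km buffer, with the two gradients
uncorrelated across an ensemble (|r| < 0.3).

Seminatural grassland is spatially clustered: a smooth random field rank-
scaled and raised to `seminatural_clustering = 6` modulates per-block
probability, and the top 1.5% of blocks always form one compact complex — a
permanent refugium, as in real mixed farmland. What the generator does *not*
emulate: real geography (roads, settlements, watercourses), non-rectangular
field shapes, correlated crop choices of individual farms, and any land-use
change between rotation cycles. Passing tests on these landscapes therefore
demonstrate the model's process logic and emergent dynamics, not predictions
for any real landscape.

## Calibration of the study conditions

Because the queen growth function is nearly a threshold at `a_q` and the only
density dependence is the nesting-capacity ceiling, the model has three
landscape-scale regimes: extinction (nowhere crosses the threshold),
saturation (a stable reproducing core pins every cell within queen-dispersal
reach at its capacity ceiling), and an intermediate source–sink regime. Only
the third reproduces the study system's documented behavior — flower-limited
populations, nesting saturation only when floral resources are added, strong
flower-strip effects that grow over years, weak margin effects. The shipped
lookup table and generator defaults were calibrated once to place typical
landscapes in that regime and then frozen: nesting capacity concentrated in
field margins (NQ = 1) and spread thinly over arable land; small clustered
seminatural refugia whose late flowers keep local colonies above the queen
threshold every year; flowering ley as the fluctuating, rotation-driven late
forage that pushes larger regions above threshold only in ley-rich years.
Under these conditions flower strips act through two channels: immediately,
they draw the finite forager pool away from other late-season flowers
(apparent competition, visible as a first-year drop in per-flower visitation
to non-strip flowers); over years, strip clusters form permanent
queen-production cores whose output fills the surrounding settlement-limited
plains, so the population effect builds up with time — many-fold larger than
the margin effect, which merely adds capacity where queen supply, not
nesting, is limiting.

## Simulation protocol

A run replays a rotation (default 7 landscape-years) for `n_cycles` cycles
(default 5 → 35 years), after a burn-in of one baseline cycle that levels
off the population from its initialization (`Q ~ Poisson(init_fill ·
capacity)`, `init_fill = 0.5`). The burn-in population carries over; because
burn-in is always baseline and shares the run's seed, every scenario of a
landscape starts its first treated year with identical colonies (analysts
can drop year 1, which the output's `year` column makes easy). Responses are
aggregated over cells whose centers lie within a circular buffer (default
3 km) around the raster center: colonies/ha, mean workers and new queens per
colony, visitation per unit flower area per period (also restricted to
non-strip flowers), mean visitation per ha of oilseed rape, and the
covariates oilseed-rape area and edge area (structural heterogeneity).
Extinction is a legitimate trajectory (logged, not raised). Determinism: all
randomness flows from one `numpy` PCG64 generator seeded in the
configuration; identical configurations give byte-identical response tables.

The scenario experiments in the test suite and acceptance script use
20 (resp. 10) landscapes of 12 × 12 km with a 3-km buffer, field-size and
oilseed-rape gradients, a 7-year burn-in and 14 treated years; the stability
runs use 5 × 5 km constant landscapes (no rotation, seminatural share 0.20
spread evenly — a configuration whose populations persist) for 35 treated
years. These sizes keep a full run of every check within a few minutes on
one CPU while leaving the dispersal scales small relative to the landscape.

## Numerical choices and degenerate inputs

* FFT convolutions (scipy `fftconvolve`) with tiny negative round-off
  clamped to zero; oracle agreement to 1e−10, conservation to 1e−9 relative.
* Sources with zero normalization (no reachable flowers / no reachable
  nesting weight) contribute zero visits / lose their queens (logged).
* `R` is defined as 0 where a cell has no nests; foragers in a cell without
  nests are an error.
* Ties in strip placement break by row-major cell order, making placement
  order-independent and reproducible.
* Cell distances are measured center-to-center; the self-distance is 0.
* Degenerate growth parameters (a ≤ 0, b ≤ 0), negative rasters, incongruent
  grids, unknown land-use codes and out-of-range periods all raise
  immediately with the offending value named.

## Known limitations

* No floral depletion: adding foragers never reduces per-forager resource
  intake, so exploitation competition is absent by construction.
* Two floral periods only; finer phenology would need more period columns in
  the lookup table (the raster machinery is period-agnostic).
* One species at a time; no males or within-colony caste dynamics; winter
  mortality beyond settlement truncation is not modeled.
* The near-threshold queen growth function makes landscape persistence
  knife-edged: small changes in late-season floral supply can flip a
  landscape between regimes. This mirrors the parameterization, not a
  numerical defect.
* The strip-placement heuristic and the resource lookup table are this
  package's own stand-ins for unavailable expert-elicited inputs; absolute
  response magnitudes depend on them, directional contrasts proved robust
  across the tested ensembles.
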