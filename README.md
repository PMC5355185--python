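# beescape

A spatially explicit, process-based model of wild central-place-foraging
pollinators (parameterized for common early-active bumble bees) on
agricultural land-use rasters. It predicts flower visitation rates and
multi-year colony population dynamics, and simulates agri-environment
interventions — widened grassy field margins and late-flowering flower
strips — to compare their effects on pollinator populations and pollination
service.

It is written for landscape ecologists and ecosystem-service modelers who
want visitation predictions that respect *behavior* (resource-dependent
foraging from a nest) and *demography* (within-season colony growth,
between-season queen dispersal), rather than distance-to-habitat scores.

## The model in brief

A season has two floral periods (early: oilseed-rape bloom; late: the rest).
Queens forage in period 1, a fraction p_w of their workers in period 2. The
rate at which cell *i* is visited by foragers nesting in cell *j* is

    V(j→i) = X_j · F_i e^(−d_ij/β) / Σ_q F_q e^(−d_qj/β) · ρ_F^d_ij

an exponential-kernel central-place foraging rule in which each forager
allocates its visits over all reachable flowers in proportion to floral
value F and distance (mean foraging distance β = 530 m, kernel truncated at
its 99th percentile). Resources collected per nest are the foragers-per-nest
times the kernel-weighted mean floral value around the nest. Colony output
saturates through the CDF G of a lognormal distribution given by its median
a and variance b:

    W = Q · w_max · G(R₁; a_w, b_w)        workers (w_max = 600)
    Q_E = Q · q_max · G(R₂; a_q, b_q)      new queens (q_max = 160)

New queens disperse to nesting habitat with a longer kernel (β̃ = 1,000 m),
expected arrivals are truncated at the cell's nesting capacity
NQ · n_max (n_max = 19.6 nests/ha) — density-dependent mortality — and
realized as a Poisson draw, the model's only stochasticity. Pollination
service is reported as visitation per unit flower area, per period and
separately for oilseed rape. See `docs/methods.md` for the full account.

## Worked example

Generate a 12 × 12 km synthetic mixed-farmland landscape, then compare
fourteen treated years of baseline, flower strips (1.25% of cropland,
re-sown annually) and widened margins (2.4 m → 4.8 m), all sharing a
seven-year burn-in:

```python
import beescape as b

lut = b.default_lookup()
spec = b.LandscapeSpec(extent=12000, mean_field_size=10, osr_target=0.12, seed=2)
rotation = b.generate_landscape(spec)
print(b.landscape_covariates(rotation[0], lut, buffer_radius=3000))

for name in ("baseline", "strips", "margins"):
    cfg = b.SimulationConfig(rotation=rotation, lut=lut,
                             scenario=b.Scenario.from_name(name),
                             n_cycles=2, seed=11, buffer_radius=3000)
    df = b.run_simulation(cfg)
    later = df[df.year > 1]
    print(name, round(later.colonies_per_ha.mean(), 2),
          round(df.visit_per_flower_p2_nonstrip.iloc[0]))
```

Output:

```
(372.25, 41.75)
baseline 1.08 18227
strips 2.36 9690
margins 1.16 18344
```

The landscape holds 372 ha of oilseed rape and 42 ha of field margins inside
the 3-km analysis buffer. Flower strips more than double the bumble bee
population (1.08 → 2.36 colonies/ha over years 2–14) while widened margins
add only 7% — nesting habitat is not what limits these populations. In the
very first treated year, before any population response, the strips *cut*
per-flower visitation to the other late-season flowers nearly in half
(18,227 → 9,690 visits per hectare of flowers): the new forage draws a
finite forager pool away from existing flowers (apparent competition). That
deficit shrinks in later years as the population grows.

The same workflow is available from the shell:

```
beescape make-landscapes --out ls0 --extent 12000 --seed 2
beescape simulate --landscape-dir ls0 --scenario strips --seed 11 --out strips.csv
beescape scenario-compare --landscape-dir ls0 --seed 11 --out factorial.csv
```

`simulate` writes one row per treated year (colonies/ha, workers and new
queens per colony, per-flower visitation per period — also restricted to
non-strip flowers — oilseed-rape visitation, and landscape covariates);
`scenario-compare` runs the 2 × 2 factorial and writes tidy long-format CSV.

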