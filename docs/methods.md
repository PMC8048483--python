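# Methods

## Model overview

`canopysim` is a functional–structural plant model of rosette canopies.
The state is a set of plants; each plant is an ordered list of leaves; each
leaf is a straight petiole (elevation `petiole_angle` ∈ [0°, 90°] above the
horizontal, azimuth fixed at initiation) carrying a planar elliptical
lamina whose plane contains the petiole axis. Coordinates are z-up SI
metres with the soil at z = 0 and the plot centred on the origin; organ
dimensions are kept in millimetres and biomass in milligrams. The model
advances in 24 h steps; within a day the order is fixed: leaf initiation →
light transport → signal evaluation → hyponasty/elongation responses →
photosynthesis → allocation → growth → metric recording, so responses
always act on the morning canopy state.

### Canopy architecture

Successive leaves are placed at the 137.5° golden angle; the first
azimuth is drawn per plant from the stand's seeded RNG (the only
architectural randomness). Laminas have a fixed 2:1 length:width aspect;
lamina area follows biomass through the specific leaf area (SLA), so
`L = √(8·SLA·m/π)`. Petiole length follows petiole biomass through a
linear density, stretched by the elongation multiplier on triggered days
(length is state, so later untriggered growth does not undo it). There is
no senescence, abscission or reproduction; biomass and dimensions are
monotone non-decreasing.

### Light transport

A Monte-Carlo tracer transports three bands (PAR, R, FR) with shared
geometric paths and per-band importance weights. The source is a
cosine-weighted diffuse "overcast sky" (growth-chamber-like) emitting PAR
220 µmol m⁻² s⁻¹ on an unobstructed horizontal plane at R:FR = 2.3; a
collimated vertical mode exists for analytic tests. The domain is
**laterally periodic** over the plot footprint: rays leaving one side
re-enter on the opposite side. This is the standard device for simulating
the interior of a larger canopy; it makes the empty-scene identity exact
in expectation (mean soil PAR = source PAR for any angular model) and
closes the energy ledger without a side-leakage term. It also means a
reduced stand (6×6) behaves like the interior of a large one, which is how
the test suite keeps scenario contrasts affordable.

Laminas interact with rays through per-band absorptance/reflectance/
transmittance (defaults: PAR 0.85/0.075/0.075, R 0.90/0.05/0.05,
FR 0.10/0.45/0.45 — typical green-leaf contrast chosen so one to two leaf
layers push R:FR below the 0.5 trigger; these are calibration knobs, not
measurements). Petioles are opaque black. At a lamina hit each band
deposits its absorbed fraction; the ray continues as a Lambertian
reflection or transmission (sampled 50:50) and band weights are rescaled
by `ρ_band/0.5` or `τ_band/0.5`, which keeps all three bands unbiased on
one sampled path. Termination is by **unbiased Russian roulette** once the
largest relative band weight falls below 10⁻³ (survivors double their
weight), with a 40-bounce safety cap feeding the same roulette. A hard
bounce cap without roulette would silently lose a large share of FR energy
(FR absorptance is only 0.10) and break the per-band conservation contract
`emitted = absorbed + soil + escaped (± 3 MC SE)` that the tests enforce.

Soil tiles under the central canopy plants (an 8×8 grid over the
middle-16 footprint, 100 cm² at default layout) tally PAR; each lamina tip
carries a small non-occluding sensor disc (radius 5 mm) whose ray
crossings accumulate R and FR weights. The disc samples the tip's local
light environment; sensors crossed by fewer than 5 rays are flagged
low-confidence and treated as not-triggered. A sensor with zero FR flux
reports `inf`, never a division error.

### Neighbour detection and responses

A leaf is triggered on a day iff it touches a lamina of *another* plant
(within 2 mm, 3D) or its tip R:FR is strictly below 0.5. Touch distance
between two elliptical laminas has no closed form, so laminas are sampled
densely (16 boundary + 9 interior points) after a bounding-sphere
prefilter; the approximation error is of order the sample spacing, well
inside the behavioural role of the 2 mm tolerance. Same-plant contact is
ignored by default (neighbour detection, configurable). Triggered leaves
gain `hyponasty_rate` degrees of petiole elevation, hard-capped at 80°,
irreversibly — the experimental fading of hyponasty is deliberately not
modelled — and their petiole growth is stretched by
`1 + elongation_multiplier`. One shared trigger drives both responses.

Phenotypes: canopy plants use the run's hyponasty rate (1–20°/day) with
elongation multiplier 0.5; weak-SAS competitors 0°/day and 0.15;
strong-SAS competitors 16°/day and 0.5. A control phenotype (threshold 0,
touch off) disables all responses.

### Growth physiology

Photosynthesis is a linear light-use efficiency: daily carbon (mg) =
LUE × absorbed PAR (mol) integrated over a 9 h photoperiod. A leaf-level
biochemical model would add parameters without changing the causal chain
under test (light interception → biomass). Carbon (plus the labile pool)
is allocated to lamina and petiole sinks in proportion to an
age-dependent demand: each organ expands over a 12-day window following a
symmetric Beta(3,3) curve scaled to its potential size (lamina 14 mg,
petiole 3.5 mg), with demand capped by remaining potential. Supply beyond
total demand stays in the pool. New leaves appear when plant age crosses
plastochron multiples (1.5 d, max 15 leaves), paid from the pool at seed
dimensions (0.25 mg lamina, 0.05 mg petiole, 30° initial elevation);
germinating plants receive a 1.2 mg seed reserve. Mass balance is exact:
Δ(organ biomass + pool) per day = assimilation (+ seed endowment on the
germination day).

### Calibration

The quantitative growth defaults (LUE 900 mg mol⁻¹, SLA 45 mm² mg⁻¹,
plastochron 1.5 d, the sink potentials and seed reserve above) are a
*joint calibration*, chosen once so that a 10×10 stand at 2.5 cm spacing
with minimal hyponasty (1°/day) closes its canopy — central soil PAR
below 60 µmol m⁻² s⁻¹ — within ~30 days, the closure behaviour the
scenario design presupposes. They are documented as a calibration, not a
measurement; individual values (e.g. the LUE, which also absorbs
respiration and the day/night cycle) should not be read as physiological
estimates.

## Scenarios and outputs

Scenario 1: 10×10 canopy monoculture. Scenarios 2/3 add 16 competitors
(weak/strong SAS) at evenly interspersed between-plant positions
symmetric about the plot centre, germinating 3 days late. The canopy
hyponasty rate is swept over {1, 5, 10, 15, 20}°/day; each scenario×rate
runs `n_stands` independently seeded replicates for 44 days. Daily
metrics: mean central soil PAR, canopy biomass (g m⁻²) over the middle 16
plants' footprint, mean competitor biomass (g) over the middle 4
(edge exclusion), LAI, vertical cover fraction and mean leaf angle.
Replicate summaries report mean ± SD; a one-way ANOVA with unprotected
pairwise LSD comparisons (α = 0.05, pooled-MSE t tests, compact letters)
is available for rate sweeps. All randomness derives from one master seed
via `SeedSequence` keys (scenario, rate, stand, day), so stands are
bit-reproducible and independent.

## Emergent behaviour (computed by the tests and acceptance script)

Slow-hyponasty canopies keep laminas flat, intercept more light per unit
area, close early and darken the soil; fast-folding canopies (15–20°/day)
tilt toward vertical and let substantially more PAR through at day 30.
Shade-blind competitors consequently end day 44 heavier under fast
canopies than slow ones. A shade-avoiding competitor under a minimally
hyponastic canopy escapes the suppression that crushes the shade-blind
phenotype, while moderately reducing canopy hyponasty (20°→10°) deepens
the suppression of even the shade-avoiding invader — the directions the
scenario design was built to probe. Under a wide-open 20°/day canopy the
shade-blind (flat-leaved) competitor actually outgrows the shade-avoiding
one here: steep leaves pay an interception penalty that only pays off when
there is shade to escape.

## Test problem sizes

The full design (10 stands × 44 days × 5 rates × ~2×10⁵ rays/day) is a
cluster-scale computation. The package's test suite runs the same code at
sizes chosen for a single CPU: full 10×10 geometry for the closure bound
(30 days, 3,000 rays/day, one stand), and 6×6 stands with 4 competitors,
2,000 rays/day and 1–2 replicates for the scenario contrasts, relying on
the periodic domain for interior-like behaviour. Stochastic assertions are
phrased as the pooled contrasts the experiment claims (fast {15,20} vs
slow {1,5,10}, plus the extreme-rate comparison) rather than strict
per-step monotonicity, which adjacent-rate MC noise cannot support at any
affordable replication.

## Known limitations

- No root systems, senescence, reproduction or water/nutrient limitation;
  biomass is monotone, so late-season decline cannot appear.
- Hyponasty does not relax and lamina shape does not respond to shade
  (no lamina-size plasticity); the lamina is rigid with the petiole, which
  makes steep leaf angles maximally costly for interception.
- The two-band R/FR treatment uses fixed broadband optics; no blue-light
  or spectral detail beyond three bands.
- Touch detection is sample-based, not exact ellipse–ellipse distance.
- The growth module is a deliberately minimal LUE/sink-demand stand-in for
  a calibrated physiological model; absolute biomass values are
  order-of-magnitude plausible, not predictions.
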