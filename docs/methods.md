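# Model description and methods

This note documents the model as implemented: its assumptions, the meaning
and provenance of every tunable parameter, the numerical choices, and what
the synthetic test scenes do and do not demonstrate.

## 1. Scope and state

The package simulates a square plot of *Brassica nigra* plants from 31 March
for 124 days at latitude 52°N, exchanging light through a common 3-D canopy.
Each plant is a tree of axes made of phytomers (internode + leaf + axillary
meristem); the state of every organ (mass, dimensions, age, damage,
senescence) is explicit.  Below-ground resources, chemical defence,
oviposition and predation are out of scope.

## 2. Environment

Daily weather is a sinusoidal synthetic series for the Netherlands:
temperature mean 9.5 °C, amplitude 7.5 °C, warmest day 199; daily insolation
3–45 mol PAR m⁻² d⁻¹ peaking at day 172.  Thermal time accumulates
`max(0, T − T_base)` with `T_base = 7 °C`, chosen so that the 60 days after
31 March accumulate ≈236 growing degree days (gdd) — the anchor that places
herbivore introduction (230 gdd) at day ≈60.  A CSV weather series can be
substituted.

Light is discretised into 8 direct sources on the solar path (weights ∝ sin
solar elevation) and 16 diffuse sources on three equal-solid-angle rings
(uniform sky by default, standard-overcast optional), with a 0.5 diffuse
fraction.  All sources carry red and far-red power in the fixed incident
ratio R:FR = 1.2.

## 3. Light transport

**Absorbed PAR.**  A forward Monte-Carlo path tracer intersects rays with
the triangulated canopy on a 2-D uniform grid.  The plot is torus-periodic:
rays (and triangles straddling an edge, as shifted instances) wrap across
the boundary, which is equivalent in expectation to the classic approach of
replicating the plot many times and averaging.  Surface events are sampled
per PAR optics (absorb 1−ρ−τ, Lambertian reflect ρ = 0.10, transmit
τ = 0.05); after 5 bounces Russian roulette applies.  The ground absorbs.
Ray entry points are importance-sampled over the canopy footprint swept
along each source direction (energy outside that window is booked to the
ground analytically), which keeps sparse April canopies well sampled; the
per-day ray budget is additionally boosted (up to 64×4000) while total leaf
area is below 3 % of the plot.  These measures exist because per-plant noise
in early growth is amplified by competition into an artificial size
hierarchy; the reference protocol's averaging over hundreds of plot copies
suppresses the same noise.

**Tip R:FR.**  Each leaf tip casts one shadow ray per source; every leaf
crossed multiplies red and far-red transmission by its band transmittance
(τ_red = 0.05, τ_fr = 0.40; reflectances 0.05/0.40; internodes opaque).
Additionally a deterministic fan of 16 probe rays (elevation rings +25°,
−15°, −50°) samples the surroundings: foliage found there contributes
reflected flux ∝ band reflectance × that organ's relative irradiance,
scaled by `reflect_gain = 2.5`.  This term stands in for multiple scattering
— far-red enrichment near neighbours *before* overt shading — and is the
signal that lets crowded stands express shade avoidance early.  It is
switched off (`n_reflect = 0`) in the closed-form oracle tests.  Tip R:FR
and each leaf's relative-irradiance signal are smoothed with exponential
moving averages (weights 0.5 and 0.4) to tame daily Monte-Carlo noise.

## 4. Carbon physiology

Per-leaf daily assimilation uses the saturating response
`A = A_max(1 − e^{−αI/A_max})` on the photoperiod-mean absorbed flux, with
`A_max = 30 µmol m⁻² s⁻¹` acclimated by the leaf's relative irradiance
(`A_max · clamp(rel, 0.1, 1)^0.5`) and quantum efficiency `α = 0.018` mol
CO₂ per mol absorbed photons.  α is deliberately below leaf-level textbook
values: it compensates for using a daily mean flux in a concave response
and absorbs within-day saturation losses.  Maintenance respiration is
0.035 g g⁻¹ d⁻¹ at 20 °C (Q₁₀ = 2) on standing mass; growth respiration is
the classic 1.39 g CH₂O per g structural mass.

Every organ accumulates *potential* mass by integrating its beta growth
curve (leaves: t_e = 234, t_m = 167 gdd; internodes 258/216; seed sinks
500/300) with the day's shade-avoidance modifiers applied to the potential
dimensions.  Demand = backlog to that accumulated potential (× 1.39); the
pool is shared proportionally; leaf demand closes when the growth window
ends (determinate growth), while internode and seed backlogs persist.  The
daily identity `assimilation + Δreserves = maintenance + 1.39 × growth` is
asserted every step and aborts the run on violation.

## 5. Architecture and shade avoidance

Leaves are planar ovate blades (area = 0.7 × length × width) at the golden
angle around the stem; blade pitch interpolates 70°→15° from vertical with
the shade fraction S.  Potential leaf length is drawn per phytomer from
N(0.285, 0.026) m; the length/width ratio interpolates 1.756→2.5 with S.
The *systemic* switch — triggered when the irradiance-weighted mean tip
R:FR of live main-stem leaves drops below 0.8, and latching — multiplies
potential leaf length by 0.55 and moves the main-stem phytomer target from
the N(29, 5) draw to the N(27, 1) draw.  Leaf-length reduction acts only
through this systemic route (the local dose–response drives width, angle
and internodes); a config flag can make it local instead.

Internodes draw potential length from N(0.045, 0.01) m, elongate up to 3.5×
under shade, capped at `int_len_max = 0.05` m (a mechanical limit;
without it, thin tip internodes elongate for free).  Extension costs only
thin-stem volume at the initial radius r₀ = 0.8 mm; the mass sink follows a
unit-pipe vascular cross-section (½ π r₀² per distal phytomer), making the
stem the major sink the system needs for realistic allocation.  Rendered
radii obey the classic pipe model: a parent's cross-section is the sum of
its daughters', radii never shrink.

Axillary meristems (except the 3 basal ranks) break at most one per day,
bottom-up, when released from apical dominance (60 gdd, or any time after
flowering), under favourable carbon (surplus, demand satisfaction ≥ 0.35,
or post-flowering), and local R:FR ≥ 0.65.  Immature branches (< 100 gdd)
abort after 5 consecutive days below R:FR 0.65, or one per 5-day window of
empty reserves.  Branch phytomer targets decline acropetally
(0.55 × (main target − rank)); branch leaves and internodes carry reduced
potentials (× 0.68 / × 0.6).  Each axis flowers at its target and gains an
aggregate seed sink with capacity `k_seed = 108 g m⁻²` × its
irradiance-weighted leaf area at flowering — the sink scales with the
axis's assimilate status, which is what separates well-lit from suppressed
axes.  The main raceme (bolting) adds up to 0.20 m of height, saturating
with seed mass.

Leaves senesce at 720 gdd of age, or after 8 days below 2 % relative
irradiance (only past 100 gdd of age).  Reported biomass is the harvestable
standing mass (live organs + seed); shed tissue is tracked as litter, and
grown = standing + litter + eaten holds exactly.

## 6. Herbivores

Caterpillars follow the measured feeding/growth laws (a_f = 7.68×10⁻⁴ m²
g⁻¹ gdd⁻¹; w = 10.61 C^0.7747 g, floored at 1.86×10⁻⁵ g and capped at the
0.178 g pupation ceiling).  Leaf choice uses the logistic age-preference
curve with midpoint m = 150 gdd and steepness s = 0.03 gdd⁻¹ (declared
defaults; only rP ratios matter).  Movement happens when the leaf senesces,
runs out, or at each of four evenly spaced moults; pupation at 210 gdd or
the weight ceiling; a herbivore on a defoliated plant pupates at its
current weight (logged as "starved").  Agents never change host plant.
Daily thermal time is integrated in 0.25-gdd substeps so the explicit
recursion stays within 1 % of a 0.01-gdd reference integration; each
substep's feeding demand remains exactly `a_f · w · Δgdd`.

Infestation places `n` herbivores per plant at 230 gdd in one of three
patterns: homogeneous (all plants, one type), heterogeneous (checkerboard
of infested and clean plants) or alternating (checkerboard of young-leaf
(h = 0.8) and old-leaf (h = 0.2) feeders).

## 7. Daily loop and determinism

Fixed order: weather → scene assembly (morning structure) → PAR trace +
R:FR sensing → shade-avoidance modifiers → herbivore feeding (damage
reduces the day's assimilating area) → photosynthesis → maintenance,
allocation, growth → phytomer production, branching, senescence, pipe
update.  Three independent RNG streams (plant draws, light, herbivores)
make every run bit-reproducible; changing the light seed leaves plant
draws untouched.

## 8. Calibration

With the measured/optimized plant and herbivore constants fixed, the
declared defaults above (α, maintenance, k_seed, branch factors, senescence,
internode cap, vascular fraction, reflect gain) were adjusted so that the
evaluation campaign reproduces the reference stand means — biomass
152.2 → 12.4 g, yield 28 → 3.3 g, branches 22.4 → 10.6 and heights
1.48 → 1.28 m from 1 to 25 plants m⁻² — within 20 % (10 % for heights).
The high-density phenotype is fully emergent through the R:FR machinery;
no code path switches on density.

## 9. Problem sizes

Evaluation plots use 4 plants (1 and 4 m⁻²) or 16 plants (25 m⁻²) on a
torus.  The package's desk-scale protocol runs 3 replicate seeds per density
at 4000 base rays per day (boosted while sparse); the full field protocol
(10 replicates, larger ray budgets) is a parameter change.  The acceptance
suite's herbivory checks use 2 seeds and herbivore numbers {5, 20}; the
full factorial {5, 10, 15, 20} × 5 replicates is available through
`fspherb.experiments.herbivory_campaign`.

## 10. What the synthetic fixtures show — and don't

The layered-canopy scene verifies Beer's-law interception for random
horizontal foliage; the layered-sensor scene verifies the R:FR transmission
product; the caterpillar oracle verifies the feeding/growth integration.
They validate the physical submodels, not field realism: real canopies have
clumped, curved, moving foliage, real weather has day-to-day variance, and
real stands have soil heterogeneity none of which these scenes represent.
Passing them means the machinery is right, while the stand-level calibration
(§8) is the evidence that the assembled model behaves like the reference
system at the two calibrated densities plus one validation density.

## 11. Known limitations

Single-day light integration (no diurnal loop); one-hit scattered-light
probing with a tuned gain instead of full dual-band path tracing; no organ
collision or leaf curvature; aggregate seed sinks (no pod geometry); mean
seed weight only as a derived report; plant-to-plant size hierarchy at high
density is stronger than in the averaged-light reference protocol, so
suppressed individuals can senesce their entire leaf area before day 124.
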