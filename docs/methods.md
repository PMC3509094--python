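# Methods

`reefconnect` models the fate of broadcast-spawned coral larvae in a reef
archipelago: a depth-averaged tidal circulation model drives a Lagrangian
random-walk larval transport model, from which self-seeding, reef-to-reef
connectivity, total seeding and lagoon residence times are computed and
confronted with (generated) field surveys of coral cover and juvenile
densities. A separate module treats decadal-scale long-distance drift from
an upstream source reef. This note records the model equations, the
defaults and why they hold, what the synthetic domain does and does not
emulate, and the numerical choices a user re-deriving results will want.

## Hydrodynamic model

The solver integrates the linearised depth-averaged shallow-water
equations on an Arakawa-C grid (elevation η at cell centres, u/v at cell
faces; x east, y north, cell size `dx`, default 500 m):

    du/dt = −g ∂η/∂x − C_d |u| u / H + τ_wx /(ρ H) + F_x
    dv/dt = −g ∂η/∂y − C_d |v| v / H + τ_wy /(ρ H) + F_y
    ∂η/∂t = −∂(Hu)/∂x − ∂(Hv)/∂y

with total depth `H = h + η`, quadratic bottom drag `C_d` (2.5×10⁻³,
multiplied by 4 over reef flats), bulk wind stress `τ_w = ρ_a C_w |W| W`
(`C_w` = 1.3×10⁻³), and a steady wave body force `F` over swell-exposed
reef flats. Momentum advection and Coriolis are omitted: the target is a
low-latitude (~7° N) archipelago at 500-m resolution where the pressure
gradient, friction and forcing terms dominate; this keeps the scheme
linear except in the drag.

**Time stepping** is explicit forward–backward: momentum first (friction
semi-implicit, `u_new = u*/(1 + Δt C_d|u|/H)`, unconditionally stable),
then flux-form continuity using the updated transports. Flux-form
continuity conserves volume to round-off; the per-step residual (volume
change minus boundary flux minus sponge source) is tracked and a run
warns above 10⁻⁶ relative. The gravity-wave CFL bound Δt ≤ 0.7·dx/√(2gH)
is enforced at construction (8 s at 500 m / 80 m). A semi-implicit free
surface was considered and rejected: at the domain sizes used the
explicit scheme costs well under a millisecond per step, so the extra
machinery of an implicit elevation solve buys nothing.

**Open boundaries.** The tide (single M2-like sinusoid, 12.42-h period,
scaled to the prescribed 1.6-m range) is clamped on the western boundary
through the pressure-gradient ghost cell; the eastern boundary clamps the
total eastward current and the northern/southern boundaries the total
northward current, each decomposed as low-frequency far field plus tidal
component, `U = U₀ + U′(t)`. A 10-cell sponge on the western side relaxes
both elevation and velocity toward the forced boundary values with a
quadratically ramped rate (60-s timescale at the wall). Relaxing
velocities as well as elevation matters: elevation-only damping leaves
the layer impedance-mismatched and reflective; with both, a normally
incident wave packet returns with under 10 % of the amplitude an
untreated boundary would reflect (the test suite measures this with a
two-run channel experiment). Forcing ramps up over 6 h to avoid shocking
the initial state.

**Wetting and drying.** Faces with total depth below 0.05 m are frozen.
Reef flats generated at 0.5 m below datum therefore dry around low tide
— deliberate, since intertidal barrier flats are what chokes lagoon
exchange.

**Reef-flat wave forcing.** Swell breaking on a reef flat drives a
cross-reef current. This is parameterized as a steady body force
`F = c_w H_s² / H` along the swell propagation direction, applied only to
reef cells with deep ocean (> 30 m) within two cells up-swell — the
barrier flank facing the incoming swell. Sheltered lagoon patch reefs get
no wave forcing; early experiments that forced every reef face spuriously
stirred the lagoon interior. The coefficient `c_w` = 10⁻³ s⁻² is a
calibration knob set to give 0.1–0.5 m/s cross-reef flow for a 1-m swell,
which is the observed magnitude range on exposed flats.

## Synthetic archipelago

`make_archipelago` builds a parametric two-lagoon system: an elliptical
barrier-reef ring (default 14 × 27 km semi-axes) around a central land
island, the annulus split into a northern and a southern lagoon at 20 m
depth, embedded in 80-m ocean (the mixed-layer cap). Each lagoon is
filled with clustered reef patches until its reef density — the fraction
of lagoon cells shallower than 5 m below datum, land included in the
denominator — hits its target (defaults 0.26 north, 0.41 south, within
±0.03 by construction). Reef density is a bathymetric quantity, distinct
from coral cover (the live-coral fraction of reef substrate).

Structure, not just cell counts, carries the dynamics, and the defaults
encode the qualitative architecture of a dense Rock-Islands-like matrix
versus a sparse, well-flushed lagoon:

* **Choked openings.** The barrier is a 2-km-wide flat at 0.5 m (drying
  at low tide) broken by narrow 8-m-deep passages. Wide, deep openings
  were tried first and produced vigorous tidal through-flow and residual
  (rectified) currents of 3–5 cm/s everywhere — no water body retains
  larvae against that. Choking the openings drops the median interior
  residual to ~1–2 cm/s and produces genuine stagnant zones.
* **Patch cores.** Patches of radius ≥ 3 cells carry a core inside their
  reef rim: with probability `islet_fraction` a raised-limestone islet
  (land), otherwise a sheltered 15-m pool — a micro-atoll. The pools are
  the main retention habitat: enclosed by draggy, intermittently drying
  flats, their exchange with the lagoon is weak, so larvae released there
  lose mass mainly by K = 1 m²/s diffusion.
* **Fragmentary sparse barrier.** The northern (sparse) lagoon's barrier
  arc is additionally broken open at lagoon depth over a fraction
  (default 0.35) of random 10° segments, letting the mean flow sweep
  east-to-west through it. The dense southern rim stays continuous.

With these defaults the three signature behaviours emerge from the
physics rather than being imposed: boundary-layer > far-field > interior
mean currents (sticky water), a longer e-folding residence time in the
dense lagoon (≈6.3 vs ≈4.3 days at this domain scale), and higher
self-seeding at dense-lagoon sites — stable across particle seeds in the
test suite.

What the generator does **not** emulate: real coastline geometry,
baroclinic and wind-event variability, wave spectra, larval behaviour and
mortality, and — most importantly — the spatial extent of a real
archipelago. The domain is 60 × 80 km, roughly half-scale, so absolute
retention and residence values are several-fold smaller than a full-scale
system would give (residence times of days rather than weeks, mean
self-seeding well under 10 %). Passing tests therefore certify orderings
and mechanisms, not field-scale magnitudes.

## Larval transport

Passive neutral particles; no behaviour or mortality. Each active
particle moves by the archived flow (bilinear in space on the staggered
grid, linear in time between snapshots) plus an independent Gaussian step
per axis with standard deviation √(2KΔt) — the random Markov walk
realisation of a horizontal eddy diffusivity K, default 1 m²/s, the
canonical sub-grid value for ~500-m patches. Particle Δt defaults to
60 s, far below the cell-crossing time at typical speeds. Releases follow
the standard protocol: 3×3-cell sites (1500 m square), 5,000 larvae per
cell (45,000 per site) released uniformly over a 30-minute window and
tracked 120 h, matching the ~5-day pre-competency period. Statuses are
absorbing: `exported` on crossing an open boundary, `stranded` only under
the optional "strand" land rule; the default rule reflects a particle
that steps onto land back to its previous position. One seeded generator
drives all draws in fixed order, so a seed reproduces trajectories
bitwise.

## Connectivity statistics

Sites are placed quasi-evenly by seeded k-means over reef cells, each
centroid snapped to the nearest non-overlapping all-water 3×3 block. At
the 120-h census (a single-snapshot position count, not
cumulative presence):

* self-seeding(j) = % of site j's released larvae inside its own
  footprint;
* connectivity S[i][j] = larvae from j inside site i's footprint
  (imports are the off-diagonal);
* total seeding(i) = Σ_j S[i][j] = self-seeded + imported.

Column sums never exceed releases; the remainder is at large or exported.
Residence time of a lagoon is the e-folding time of its active-particle
concentration — the first time C(t) ≤ C(0)/e (a 64 % decrease), linearly
interpolated — from a dedicated uniform release over the lagoon's
subtidal (≥ 5 m) waters. Restricting to subtidal water matters: particles
sitting immobile on drying reef-flat tops are reef retention, not lagoon
water-mass residence, and counting them stalls the decay curve. When a
series decays but never reaches 1/e within the record, the crossing
estimator is undefined and a log-linear fit estimator is available
(`method="fit"`).

## Regional drift

Long-distance connectivity uses monthly mean currents only. Each month's
vector is projected on the source→destination bearing (default 400 km to
the southwest) and displacements accumulate at 30.44 days/month; negative
projections push the virtual patch backward. A start month is favorable
if the cumulative displacement reaches the separation within the
competency limit (100 days); consecutive favorable start months merge
into one window. Two spawning-window denominators are exposed because
neither is canonical: record-months ÷ 4 (168 months → 42) and 4 calendar
months per record year (168 → 56); the pipeline reports the former.
Patch dilution en route follows the 2-D Fickian point-release solution
mixed over the surface layer, peak `M /(4π t √(DxDy) · depth)`.

The altimetry generator draws monthly speeds from a Beta distribution on
[0.05, 0.25] m/s with mean 0.12 (ENSO-scale event variability) and von
Mises directions about a northwest drift. The windows-and-fraction
statistics of a generated series are therefore stochastic summaries of
that generative model, not reproductions of any particular observed
record.

## Survey generator and model–field comparison

Site placement is stratified — 30 outer-reef, 30 patch-reef, 20 bay sites
drawn uniformly from the matching habitat masks. Coral cover responds
linearly to self-seeding, `cover = a + b·selfseed + ε`, ε ~ N(0, sd),
defaults a = 15.8 %, b = 0.19, sd = 8 % (the noise level that makes the
cover fit weak, R² ≈ 0.2, at the field-observed predictor spread), cover
clipped to [0, 100]. Juvenile broadcaster (Acropora) counts over the
15 m² of sampled quadrats are Poisson with log λ = c₀ + c₁·totalseed
(c₀ = 0, c₁ = 0.03 per percentage point, i.e. ~1–7 juveniles per site
across the seeding range); brooders (Pocillopora, Stylophora) are
stationary Poisson background, since brooding recruitment is continuous
and local and a spawning-event model has nothing to say about it. The
count model is a package design choice — the only noise in the juvenile
link is Poisson sampling, which makes the link strongly recoverable; an
observed field correlation of ~0.3 reflects additional ecological noise
the generator does not model. A negative-binomial option is exposed.

The comparison joins each survey site to its nearest seeding site within
4 km and reports: OLS of cover on each of {self-seeding, imports, total
seeding} (t-based inference, 95 % CIs), Spearman rank correlation
(mid-ranks for ties) of each juvenile density on each predictor, and
Moran's I of juvenile Acropora per habitat stratum. Coordinates are
treated as planar throughout.

## Spatial statistics

Implemented from their defining equations (no geostatistics dependency):
the Matheron empirical semivariogram; weighted (by pair count)
least-squares fit of the Gaussian model γ(h) = nugget +
(sill−nugget)(1−exp(−(h/range)²)) with box constraints; ordinary kriging
via the augmented semivariance system with the weights-sum-to-one
constraint (exact interpolation at zero nugget; a singular system gets
one diagonal-jitter retry); Moran's I with k-nearest (k = 8,
row-standardized) weights by default, inverse-distance optional, and a
two-sided permutation p-value (≥ 999 permutations, seed-controlled,
measured as deviation from E[I] = −1/(n−1)). Every one of these is pinned
against a brute-force oracle (double loops, direct solves) on ≥ 100
randomized inputs in the test suite; OLS and Spearman delegate to
statsmodels/scipy and are pinned the same way.

## Pipeline and reproducibility

Stages run in dependency order (domain → flow → track → connect →
compare → regional); disabling a prerequisite makes dependents refuse
with a stage-named error. One global seed spawns per-stage sub-seeds via
`SeedSequence`, so a fixed seed reproduces the whole artifact bundle
bitwise; every output directory carries a manifest with seed and a hash
of the scientific configuration. Every numeric default is listed in
`DEFAULT_PROVENANCE` with its origin (protocol study condition vs
package design choice), and a test diffs that table against the actual
dataclass defaults in both directions.

Problem sizes: the bundled end-to-end study (`demo_config`) runs the
120×160-cell domain with 10–20 sites at 1,000 larvae per cell, a 240-h
flow archive, and 8,000 residence particles per lagoon — a few minutes on
one CPU. The full protocol (50 sites × 45,000 larvae) is the
config default and runs unchanged, just longer.

## Known limitations

* Half-scale domain: absolute retention/residence magnitudes are not
  field-scale (orderings are the tested claims).
* Linearised momentum: no tidal-jet vortices or wake eddies beyond what
  friction asymmetry rectifies; sub-grid stirring is folded into K.
* Single tidal constituent; no spring–neap cycle.
* Export through open boundaries is absorbing — larvae cannot re-enter.
* The kriging surface generator is provided but the comparison uses
  per-site values, not kriged fields, as predictors.
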