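# reefconnect

Biophysical larval-dispersal and reef-connectivity modelling for
archipelago lagoons.

`reefconnect` answers a question that matters to anyone designing marine
protected areas around coral reefs: **where do the larvae go?** It couples
a 2-D depth-averaged tidal circulation model to a Lagrangian random-walk
larval transport model, computes per-reef self-seeding, reef-to-reef
connectivity and lagoon residence times, and compares those model fields
against field surveys of coral cover and juvenile coral density. A
synthetic-domain module generates complete two-lagoon reef archipelagos
(bathymetry, forcing, altimetry-like current records, stratified surveys)
with known ground truth, so the whole pipeline runs and is tested without
any external data.

## The model in brief

**Circulation.** Linearised shallow-water equations on an Arakawa-C grid
(500-m cells, 80-m mixed-layer depth cap):

    ∂u/∂t = −g ∂η/∂x − C_d|u|u/H + τ_w/(ρH) + F_wave
    ∂η/∂t = −∇·(H **u**)

with quadratic bottom drag (elevated over reef flats), wind stress, a
wave-breaking body force on swell-exposed reef flats, wetting/drying, an
M2 tide clamped on the western open boundary (`U = U₀ + U′(t)` current
decomposition on the others) and a 10-cell absorbing sponge layer.

**Larvae.** Passive particles advected by the archived flow plus a random
Markov walk with eddy diffusivity K = 1 m² s⁻¹ (Gaussian steps of
sd √(2KΔt)); 5,000 larvae per cell released from 3×3-cell (1,500-m)
seeding sites over 30 minutes and tracked 120 h (the pre-competency
period). At the census:

* self-seeding(j) — % of site j's larvae still inside its own footprint,
* connectivity S[i][j] — larvae from site j found at site i,
* total seeding(i) = Σ_j S[i][j],
* residence time τ — time for a lagoon's particle concentration to fall
  to 1/e (a 64 % decrease).

**Statistics.** Ordinary kriging under a Gaussian variogram, Moran's I
with permutation inference, OLS and Spearman rank correlation link the
modelled seeding fields to surveyed coral cover and juvenile densities.

The emergent behaviour the package demonstrates is the *sticky-water*
effect: a dense reef matrix deflects the mean circulation around the
archipelago, so boundary-layer currents u₂ exceed the far-field u₁, the
interior u₃ is slowest (u₂ > u₁ > u₃), and the dense lagoon both holds
its water longer and re-seeds its own reefs more than the sparse one.

## Worked example

Run the reduced end-to-end study (120×160-cell two-lagoon archipelago,
10 seeding sites at 1,000 larvae per cell, ~4 minutes on one CPU):

```python
import json
from reefconnect import demo_config, run_pipeline

res = run_pipeline(demo_config(seed=1))
print(json.dumps(res.summary(), indent=2, default=float))
```

prints

```json
{
  "config_hash": "c7602cf0c4e4c2f3",
  "seed": 1,
  "reef_densities": {
    "northern_lagoon": 0.267162471395881,
    "southern_lagoon": 0.41018306636155605
  },
  "sticky_water_m_per_s": {
    "far_field": 0.12818790972232819,
    "boundary_layer": 0.32821550965309143,
    "interior": 0.033689532428979874
  },
  "self_seeding_mean_pct": 0.3944444444444445,
  "self_seeding_range_pct": [0.0, 2.988888888888889],
  "residence_days": {
    "northern_lagoon": 4.258447515861047,
    "southern_lagoon": 6.346970266822719
  },
  "regional": {
    "mean_speed_m_per_s": 0.12110920908554457,
    "transit_days_at_mean_speed": 38.22690003994268,
    "n_windows": 7,
    "favorable_start_months": 12,
    "window_months": 42,
    "seeding_fraction_pct": 28.571428571428573,
    "dilution_peak_per_m3": 2.558432084167556e-06
  }
}
```

Reading the numbers: the generator realised the requested reef densities
(26.7 % sparse north vs 41.0 % dense south). Under a 0.12 m s⁻¹ westward
far-field current with a 1.6-m tide, the mean current accelerates to
0.33 m s⁻¹ in the boundary layer flanking the archipelago while the
interior sits at 0.034 m s⁻¹ — the sticky-water ordering u₂ > u₁ > u₃.
The dense southern lagoon flushes in 6.3 days against 4.3 days for the
broken-barrier northern lagoon, and its sites retain more of their own
larvae (site-level self-seeding up to ~3 % at this reduced domain scale).
The regional block summarises a generated 168-month current record:
mean speed 0.12 m s⁻¹, a 400-km drift covered in ~38 days at that speed,
and the favorable-window bookkeeping over the record.

`res` also carries the full artifacts — connectivity matrix
(`res.matrix`), per-site summary (`res.site_summary`), generated survey
and comparison table (`res.comparison.table`) — and `cfg.output_dir`
writes them all as rasters/CSV/JSON with a manifest. The same pipeline is
scriptable from the shell:

```bash
reefconnect run --seed 1 --out runs/demo
reefconnect regional --seed 4
```

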