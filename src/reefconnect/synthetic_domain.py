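"""Synthetic archipelagos, boundary forcing, altimetry and survey tables.

Every downstream stage of the pipeline (flow, transport, connectivity,
spatial statistics) is exercised on generated inputs with the statistical
structure the analysis assumes, so no external bathymetry, altimetry or
field data are required:

* a two-lagoon reef archipelago with contrasting reef densities
  (sparse northern lagoon vs a dense, Rock-Islands-like southern matrix),
* M2 tidal + low-frequency boundary forcing (1.6-m range, ~0.12 m/s
  far-field current by default),
* monthly altimetry-like surface-current series with El Niño / La Niña
  scale variability (~0.05–0.25 m/s), and
* stratified coral surveys (30 outer / 30 patch / 20 bay sites) whose
  coral cover responds linearly to self-seeding and whose juvenile
  broadcast-spawner densities follow a log-link on total seeding.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_grids import BathymetryGrid, RegionMask, reef_density, reef_mask
from .hydrodynamics import M2_PERIOD_S, BoundaryForcing

__all__ = [
    "ArchipelagoSpec", "AltimetrySpec", "SurveySpec",
    "make_archipelago", "make_forcing", "make_altimetry",
    "place_survey_sites", "make_survey",
]


# ---------------------------------------------------------------------------
# Archipelago
# ---------------------------------------------------------------------------

@dataclass
class ArchipelagoSpec:
    """Parametric two-lagoon archipelago.

    The archipelago is an ellipse of barrier reef around a central land
    island; the annulus between island and barrier splits into a northern
    and a southern lagoon whose interiors are filled with random patch-reef
    clusters until each hits its target reef density (fraction of lagoon
    cells shallower than 5 m, land cells counted in the denominator).
    """

    n_x: int = 120
    n_y: int = 160
    dx: float = 500.0                   # m
    ocean_depth: float = 80.0           # m (mixed-layer cap)
    lagoon_depth: float = 20.0          # m
    reef_depth: float = 0.5             # m, reef flats near LWD (dry at low tide)
    passage_depth: float = 8.0          # m, reef passages
    islet_fraction: float = 0.5         # patches with raised-limestone land cores
    pool_depth: float = 15.0            # m, sheltered pools inside micro-atolls
    archipelago_semiaxes_km: tuple[float, float] = (14.0, 27.0)
    island_semiaxes_km: tuple[float, float] = (4.0, 11.0)
    ring_width_cells: int = 4
    passage_centers_deg: tuple[float, ...] = (55.0, 125.0, 235.0, 305.0)
    passage_half_width_deg: float = 4.0
    north_target_density: float = 0.26
    south_target_density: float = 0.41
    # fraction of the barrier arc broken into gaps, per lagoon: a sparse
    # reef system has a fragmentary barrier that lets the mean flow sweep
    # through, a dense one a nearly continuous rim
    north_barrier_gap_fraction: float = 0.35
    south_barrier_gap_fraction: float = 0.0
    patch_radius_cells: tuple[int, int] = (2, 4)
    patch_cluster_prob: float = 0.7     # new patches attach to existing ones
    boundary_layer_km: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.north_target_density, self.south_target_density):
            if not 0.0 <= t <= 1.0:
                raise ValueError("target reef densities must lie in [0, 1]")


def _fill_patches(depth, land, candidates, reef, target_count, rmin, rmax,
                  rng, reef_depth, islet_fraction, pool_depth, cluster_prob,
                  region):
    """Add disc-shaped reef patches on *candidates* until the reef count in
    *region* reaches *target_count*.

    Patches grow as clusters: with probability *cluster_prob* a new disc
    attaches next to an existing patch, building chains and agglomerates.
    Large patches carry a core inside their reef-flat rim — either a
    raised-limestone islet (land) or a sheltered deep pool (a
    micro-atoll), the Rock-Islands-like structures whose enclosed,
    near-stagnant waters make a dense reef matrix retain larvae.
    Switches to single cells near the target so the realized density
    lands within one cell of it."""
    ny, nx = depth.shape
    iy, ix = np.nonzero(candidates & ~reef)
    order = rng.permutation(len(iy))
    pos = 0
    patch_centres: list[tuple[int, int]] = []
    need = target_count - int((reef & region).sum())
    while need > 0:
        if pos >= len(order):
            raise ValueError("target reef density infeasible for the lagoon area")
        k = order[pos]
        pos += 1
        cy, cx = iy[k], ix[k]
        if patch_centres and need > 12 and rng.random() < cluster_prob:
            py, px = patch_centres[rng.integers(len(patch_centres))]
            off = rng.integers(-2 * rmax, 2 * rmax + 1, size=2)
            ay, ax_ = py + off[0], px + off[1]
            if (0 <= ay < ny and 0 <= ax_ < nx and candidates[ay, ax_]
                    and not reef[ay, ax_] and not land[ay, ax_]):
                cy, cx = ay, ax_
        if reef[cy, cx] or land[cy, cx]:
            continue
        if need > 12:
            patch_centres.append((cy, cx))
            r = rng.integers(rmin, rmax + 1)
            core = r - 2 if r >= 3 else 0
            core_is_islet = rng.random() < islet_fraction
            y0, y1 = max(0, cy - r), min(ny, cy + r + 1)
            x0, x1 = max(0, cx - r), min(nx, cx + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            disc = d2 <= r ** 2
            sel = np.zeros_like(reef)
            sel[y0:y1, x0:x1] = disc
            sel &= candidates & ~reef & ~land
            depth[sel] = reef_depth
            reef |= sel
            if core > 0:
                core_sel = np.zeros_like(reef)
                core_sel[y0:y1, x0:x1] = d2 <= core ** 2
                core_sel &= sel
                reef &= ~core_sel
                if core_is_islet:
                    land |= core_sel
                    depth[core_sel] = np.nan
                else:
                    depth[core_sel] = pool_depth
        else:
            depth[cy, cx] = reef_depth
            reef[cy, cx] = True
        need = target_count - int((reef & region).sum())


def make_archipelago(spec: ArchipelagoSpec | None = None
                     ) -> tuple[BathymetryGrid, dict[str, RegionMask]]:
    """Generate the two-lagoon archipelago and its diagnostic region masks.

    Returns the bathymetry grid and masks: ``northern_lagoon`` /
    ``southern_lagoon`` (lagoon proper, inside the barrier ring),
    ``interior``, ``boundary_layer`` and ``far_field`` (sticky-water
    diagnostics, through-flow assumed along the east-west axis),
    and habitat masks ``outer_reef``, ``patch_reef``, ``bay``.
    """
    spec = spec or ArchipelagoSpec()
    rng = np.random.default_rng(spec.seed)
    ny, nx, dx = spec.n_y, spec.n_x, spec.dx

    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    xx, yy = np.meshgrid(x, y)
    cx, cy = nx * dx / 2, ny * dx / 2
    a, b = (s * 1000.0 for s in spec.archipelago_semiaxes_km)
    ai, bi = (s * 1000.0 for s in spec.island_semiaxes_km)
    dxs, dys = xx - cx, yy - cy
    r = np.sqrt((dxs / a) ** 2 + (dys / b) ** 2)       # barrier-normalized radius
    r_isl = np.sqrt((dxs / ai) ** 2 + (dys / bi) ** 2)
    theta = np.degrees(np.arctan2(dys / b, dxs / a)) % 360.0

    r_in = 1.0 - spec.ring_width_cells * dx / a
    depth = np.full((ny, nx), spec.ocean_depth)
    land = np.zeros((ny, nx), dtype=bool)

    lagoon_area = (r < r_in) & (r_isl > 1.0)
    depth[lagoon_area] = spec.lagoon_depth
    ring = (r >= r_in) & (r <= 1.0)
    depth[ring] = spec.reef_depth
    in_passage = np.zeros((ny, nx), dtype=bool)
    for c in spec.passage_centers_deg:
        d = np.abs((theta - c + 180.0) % 360.0 - 180.0)
        in_passage |= d <= spec.passage_half_width_deg
    depth[ring & in_passage] = spec.passage_depth
    # fragmentary barrier arcs: random 10-degree segments missing entirely
    # (open at lagoon depth), letting the mean flow sweep through
    seg = (theta // 10.0).astype(int)
    gap_roll = rng.random(36)
    broken = np.zeros((ny, nx), dtype=bool)
    for half, frac in ((dys >= 0, spec.north_barrier_gap_fraction),
                       (dys < 0, spec.south_barrier_gap_fraction)):
        if frac > 0:
            broken |= half & (gap_roll[seg] < frac)
    depth[ring & broken & ~in_passage] = spec.lagoon_depth
    land[r_isl <= 1.0] = True
    depth[land] = np.nan

    north_region = (r < r_in) & (dys >= 0)
    south_region = (r < r_in) & (dys < 0)
    reef = np.zeros((ny, nx), dtype=bool)
    reef[~land & (depth < 5.0)] = True
    for region, target in ((north_region, spec.north_target_density),
                           (south_region, spec.south_target_density)):
        candidates = region & lagoon_area
        target_count = int(round(target * region.sum()))
        if target_count > 0:
            _fill_patches(depth, land, candidates, reef, target_count,
                          spec.patch_radius_cells[0], spec.patch_radius_cells[1],
                          rng, spec.reef_depth, spec.islet_fraction,
                          spec.pool_depth, spec.patch_cluster_prob, region)

    grid = BathymetryGrid(depth=depth, land_mask=land, dx=dx, origin=(0.0, 0.0))
    water = grid.water_mask
    rm = reef_mask(grid)

    band_norm = spec.boundary_layer_km * 1000.0 / a
    lateral = np.abs(dys / b) > np.abs(dxs / a)   # N/S flanks of the through-flow
    boundary_layer = water & (r > 1.0) & (r <= 1.0 + band_norm) & lateral
    margin = 12
    far_field = np.zeros((ny, nx), dtype=bool)
    far_field[margin:ny - margin, nx - 10:nx - 3] = True
    far_field &= water & (r > 1.3)

    from scipy.ndimage import binary_dilation
    near_island = binary_dilation(land, iterations=2) & water

    masks = {
        "northern_lagoon": RegionMask("northern_lagoon", north_region),
        "southern_lagoon": RegionMask("southern_lagoon", south_region),
        "interior": RegionMask("interior", water & (r < r_in)),
        "boundary_layer": RegionMask("boundary_layer", boundary_layer),
        "far_field": RegionMask("far_field", far_field),
        "outer_reef": RegionMask("outer_reef", rm & (r >= r_in)),
        "patch_reef": RegionMask("patch_reef", rm & (r < r_in)),
        "bay": RegionMask("bay", near_island & ~rm),
    }
    for name in ("northern_lagoon", "southern_lagoon"):
        target = (spec.north_target_density if name == "northern_lagoon"
                  else spec.south_target_density)
        realized = reef_density(grid, masks[name])
        if abs(realized - target) > 0.03:
            raise ValueError(
                f"{name} realized reef density {realized:.3f} misses target {target}"
            )
    return grid, masks


# ---------------------------------------------------------------------------
# Boundary forcing
# ---------------------------------------------------------------------------

def make_forcing(
    tidal_range: float = 1.6,
    mean_current: tuple[float, float] = (-0.12, 0.0),
    wind: tuple[float, float] = (5.0, 45.0),
    swell: tuple[float, float] = (1.0, 90.0),
    duration: float = 15 * 86400.0,
    dt: float = 600.0,
    tidal_current_amp: tuple[float, float] = (0.05, 0.05),
    tidal_period: float = M2_PERIOD_S,
) -> BoundaryForcing:
    """Sinusoidal M2-like tidal + low-frequency boundary forcing.

    Parameters
    ----------
    tidal_range
        Peak-to-trough elevation range at the western boundary, m.
    mean_current
        Low-frequency far-field current ``(u0 east, v0 north)``, m/s.
    wind, swell
        ``(speed m/s, compass direction coming from)`` and
        ``(significant height m, compass direction coming from)``.
    """
    if tidal_range < 0:
        raise ValueError("tidal range must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration + dt, dt)
    omega = 2 * math.pi / tidal_period
    eta = 0.5 * tidal_range * np.sin(omega * t)
    return BoundaryForcing(
        time=t,
        eta=eta,
        u0=mean_current[0],
        v0=mean_current[1],
        u_tide=tidal_current_amp[0] * np.sin(omega * t),
        v_tide=tidal_current_amp[1] * np.sin(omega * t),
        wind_speed=wind[0],
        wind_dir_from_deg=wind[1],
        swell_height=swell[0],
        swell_dir_from_deg=swell[1],
    )


# ---------------------------------------------------------------------------
# Altimetry-like monthly currents
# ---------------------------------------------------------------------------

@dataclass
class AltimetrySpec:
    """Monthly surface-current series emulating altimetry-derived means.

    Speeds are Beta-distributed over ``speed_range`` with mean
    ``mean_speed`` (ENSO-scale month-to-month events); directions are
    von Mises about a mean drift toward the northwest.
    """

    months: int = 168
    mean_speed: float = 0.12            # m/s
    speed_range: tuple[float, float] = (0.05, 0.25)
    concentration: float = 6.0          # Beta concentration (a+b)
    mean_direction_to_deg: float = 315.0  # compass, direction of drift
    direction_kappa: float = 4.0
    start_year: int = 1993
    seed: int = 0

    def __post_init__(self) -> None:
        if self.months < 1:
            raise ValueError("months must be >= 1")
        lo, hi = self.speed_range
        if not (0 <= lo <= self.mean_speed <= hi):
            raise ValueError("need speed_range[0] <= mean_speed <= speed_range[1]")


def make_altimetry(spec: AltimetrySpec | None = None) -> pd.DataFrame:
    """Generate the monthly mean-current table (year, month, u, v, speed)."""
    spec = spec or AltimetrySpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.speed_range
    if hi > lo:
        mean_norm = (spec.mean_speed - lo) / (hi - lo)
        aa = mean_norm * spec.concentration
        bb = (1.0 - mean_norm) * spec.concentration
        speed = lo + (hi - lo) * rng.beta(aa, bb, size=spec.months)
    else:
        speed = np.full(spec.months, lo)
    dir_to = np.degrees(rng.vonmises(math.radians(spec.mean_direction_to_deg),
                                     spec.direction_kappa, size=spec.months))
    rad = np.radians(dir_to)
    months = np.arange(spec.months)
    return pd.DataFrame({
        "year": spec.start_year + months // 12,
        "month": months % 12 + 1,
        "u": speed * np.sin(rad),
        "v": speed * np.cos(rad),
        "speed": speed,
    })


# ---------------------------------------------------------------------------
# Field surveys
# ---------------------------------------------------------------------------

@dataclass
class SurveySpec:
    """Stratified coral-survey generator.

    Coral cover responds linearly to modelled self-seeding,
    ``cover = a + b * selfseed + Normal(0, sd)``; juvenile broadcaster
    (Acropora) counts follow a Poisson log-link on total seeding; brooder
    (Pocillopora, Stylophora) counts are stationary Poisson background,
    reflecting local brooding recruitment that a spawning-event model does
    not resolve.
    """

    n_outer: int = 30
    n_patch: int = 30
    n_bay: int = 20
    cover_intercept: float = 15.8       # %, cover at zero self-seeding
    cover_slope: float = 0.19           # % cover per % self-seeding
    cover_noise_sd: float = 8.0         # %
    juv_log_intercept: float = 0.0      # log expected count per sampled area
    juv_log_slope: float = 0.03         # per % total seeding
    brooder_rates: tuple[float, float] = (2.0, 1.0)  # Pocillopora, Stylophora
    sampled_area_m2: float = 15.0       # 15 x 1 m^2 quadrats per site
    count_model: str = "poisson"        # or "negative_binomial"
    nb_dispersion: float = 10.0
    clip_cover: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_outer, self.n_patch, self.n_bay) < 0:
            raise ValueError("site counts must be >= 0")
        if self.cover_noise_sd < 0:
            raise ValueError("cover noise sd must be >= 0")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")


def place_survey_sites(grid: BathymetryGrid, masks: dict[str, RegionMask],
                       spec: SurveySpec | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Place survey sites uniformly at random within each habitat stratum.

    Strata map to masks: outer -> ``outer_reef``, patch -> ``patch_reef``,
    bay -> ``bay``.
    """
    spec = spec or SurveySpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for stratum, mask_name, n in (("outer", "outer_reef", spec.n_outer),
                                  ("patch", "patch_reef", spec.n_patch),
                                  ("bay", "bay", spec.n_bay)):
        iy, ix = np.nonzero(masks[mask_name].mask)
        if len(iy) < n:
            raise ValueError(
                f"stratum {stratum!r}: {n} sites requested but only "
                f"{len(iy)} cells available"
            )
        pick = rng.choice(len(iy), size=n, replace=False)
        for k in pick:
            rows.append((stratum,
                         (ix[k] + 0.5) * grid.dx + grid.origin[0],
                         (iy[k] + 0.5) * grid.dx + grid.origin[1]))
    df = pd.DataFrame(rows, columns=["stratum", "x", "y"])
    df.insert(0, "site_id", np.arange(len(df)))
    return df


def make_survey(truth: pd.DataFrame, spec: SurveySpec | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """Generate a survey table from per-site seeding truth.

    *truth* must hold one row per site with columns ``site_id``, ``x``,
    ``y``, ``stratum``, ``self_seeding_pct`` and ``total_seeding_pct``.
    """
    spec = spec or SurveySpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    required = {"site_id", "x", "y", "stratum", "self_seeding_pct",
                "total_seeding_pct"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table is missing columns {sorted(missing)}")
    n = len(truth)
    cover = (spec.cover_intercept
             + spec.cover_slope * truth["self_seeding_pct"].to_numpy()
             + rng.normal(0.0, spec.cover_noise_sd, size=n))
    if spec.clip_cover:
        cover = np.clip(cover, 0.0, 100.0)

    mu = np.exp(spec.juv_log_intercept
                + spec.juv_log_slope * truth["total_seeding_pct"].to_numpy())

    def draw(mean):
        mean = np.broadcast_to(np.asarray(mean, float), (n,))
        if spec.count_model == "poisson":
            return rng.poisson(mean)
        r = spec.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    area = spec.sampled_area_m2
    out = truth[["site_id", "x", "y", "stratum"]].copy()
    out["coral_cover_pct"] = cover
    out["juv_acropora_per_m2"] = draw(mu) / area
    out["juv_pocillopora_per_m2"] = draw(spec.brooder_rates[0]) / area
    out["juv_stylophora_per_m2"] = draw(spec.brooder_rates[1]) / area
    return out
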