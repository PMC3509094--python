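"""Seeding-site statistics: self-seeding, connectivity, total seeding,
retention summaries and lagoon residence times.

A seeding site is a 3x3 block of water cells (1500 m x 1500 m at 500-m
cells) smoothing over the cell-to-cell velocity variability of reef
systems.  From the tracked trajectories the module computes, at a census
time of 120 h after spawning:

* self-seeding — the percentage of a site's released larvae still inside
  its own footprint,
* the connectivity matrix — larvae at site i that were released at site j,
* total seeding — self-seeded plus imported larvae per site,

and, per lagoon, the e-folding residence time: the time for the region's
particle concentration to fall by 64%, i.e. to 1/e of its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .core_grids import BathymetryGrid, RegionMask, reef_mask
from .transport import STATUS_ACTIVE, TrajectoryArchive

CENSUS_HOURS = 120.0


@dataclass(frozen=True)
class SeedingSite:
    """A 3x3-cell spawning site."""

    id: int
    cells: tuple[tuple[int, int], ...]   # (iy, ix) pairs
    centre: tuple[float, float]          # metres

    def __post_init__(self) -> None:
        if len(self.cells) != 9:
            raise ValueError("a seeding site is a 3x3 block of 9 cells")


def place_sites(grid: BathymetryGrid, n_sites: int = 50,
                seed: int = 0) -> list[SeedingSite]:
    """Place *n_sites* disjoint 3x3 all-water sites quasi-evenly over reef.

    Site centres start from a k-means partition of the reef cells (even
    coverage weighted by reef area) and are snapped to the nearest
    all-water 3x3 block that does not overlap an already-placed site.
    """
    rm = reef_mask(grid)
    iy, ix = np.nonzero(rm)
    if len(iy) == 0:
        raise ValueError("grid has no reef cells to seed")
    # block-centre candidates: 3x3 neighbourhood entirely water
    valid = binary_erosion(grid.water_mask, structure=np.ones((3, 3)),
                           border_value=0)
    viy, vix = np.nonzero(valid)
    if len(viy) < n_sites:
        raise ValueError("not enough all-water 3x3 blocks to place sites")
    pts = np.column_stack([ix, iy]).astype(float)
    if n_sites == 1:
        centres = pts.mean(axis=0, keepdims=True)
    else:
        if len(pts) < n_sites:
            raise ValueError("fewer reef cells than requested sites")
        centres, _ = kmeans2(pts, n_sites, minit="++", seed=seed)
        centres = centres[np.lexsort((centres[:, 0], centres[:, 1]))]
    tree = cKDTree(np.column_stack([vix, viy]))
    used = np.zeros_like(grid.water_mask)
    sites: list[SeedingSite] = []
    for sid, c in enumerate(centres):
        k = min(len(viy), 200)
        _, cand = tree.query(c, k=k)
        cand = np.atleast_1d(cand)
        placed = False
        for j in cand:
            cy, cx = viy[j], vix[j]
            block = np.s_[cy - 1:cy + 2, cx - 1:cx + 2]
            if used[block].any():
                continue
            used[block] = True
            cells = tuple((cy + dy, cx + dx)
                          for dy in (-1, 0, 1) for dx in (-1, 0, 1))
            centre = (grid.origin[0] + (cx + 0.5) * grid.dx,
                      grid.origin[1] + (cy + 0.5) * grid.dx)
            sites.append(SeedingSite(id=sid, cells=cells, centre=centre))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place site {sid} without overlap; "
                "reduce n_sites or enlarge the domain"
            )
    return sites


@dataclass
class ConnectivityMatrix:
    """Site-by-site larval exchange at the census time.

    ``counts[i, j]`` is the number of larvae released at site j found
    within site i's footprint at the census; the diagonal is self-seeding
    and off-diagonal entries are imports.  Column sums never exceed the
    released count (the remainder is at large or exported).
    """

    counts: np.ndarray       # (n_sites, n_sites)
    released: np.ndarray     # (n_sites,)
    census_h: float
    site_ids: np.ndarray

    @property
    def fractions(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.counts / self.released[None, :]
        return np.where(self.released[None, :] > 0, f, 0.0)

    def self_seeding_pct(self) -> np.ndarray:
        return 100.0 * np.diag(self.fractions)

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.site_ids)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame({
            "site_to": self.site_ids[i.ravel()],
            "site_from": self.site_ids[j.ravel()],
            "count": self.counts.ravel().astype(int),
            "fraction": self.fractions.ravel(),
        })


def _census_site_index(traj: TrajectoryArchive, sites, grid: BathymetryGrid,
                       census_h: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-particle index of the site whose footprint holds it at census
    (-1 if none / not active), plus the active mask."""
    cell_to_site = {}
    for si, site in enumerate(sites):
        for c in site.cells:
            if c in cell_to_site:
                raise ValueError("seeding sites overlap")
            cell_to_site[c] = si
    ens = traj.ensemble_at(census_h * 3600.0)
    active = ens.status == STATUS_ACTIVE
    ix, iy = grid.cell_of(ens.x, ens.y)
    out = np.full(traj.n, -1)
    lookup = np.full((grid.n_y, grid.n_x), -1)
    for (cy, cx), si in cell_to_site.items():
        lookup[cy, cx] = si
    inside = active & (ix >= 0) & (ix < grid.n_x) & (iy >= 0) & (iy < grid.n_y)
    out[inside] = lookup[iy[inside], ix[inside]]
    return out, active


def connectivity_matrix(traj: TrajectoryArchive, sites,
                        grid: BathymetryGrid,
                        census_h: float = CENSUS_HOURS) -> ConnectivityMatrix:
    """Count larvae from each source site inside each destination footprint."""
    n = len(sites)
    at_site, _ = _census_site_index(traj, sites, grid, census_h)
    site_ids = np.array([s.id for s in sites])
    id_to_idx = {s.id: k for k, s in enumerate(sites)}
    src = np.array([id_to_idx[s] for s in traj.site_id])
    counts = np.zeros((n, n))
    released = np.bincount(src, minlength=n).astype(float)
    hit = at_site >= 0
    np.add.at(counts, (at_site[hit], src[hit]), 1.0)
    return ConnectivityMatrix(counts=counts, released=released,
                              census_h=census_h, site_ids=site_ids)


def self_seeding(traj: TrajectoryArchive, site, grid: BathymetryGrid,
                 census_h: float = CENSUS_HOURS) -> float:
    """Percentage of a site's released larvae inside its own footprint
    at the census time."""
    at_site, _ = _census_site_index(traj, [site], grid, census_h)
    mine = traj.site_id == site.id
    released = int(mine.sum())
    if released == 0:
        raise ValueError(f"no particles were released from site {site.id}")
    return 100.0 * float((at_site[mine] == 0).sum()) / released


def total_seeding(matrix: ConnectivityMatrix, site_index: int) -> float:
    """Self-seeded plus imported larvae at a site (row sum of counts)."""
    return float(matrix.counts[site_index, :].sum())


def total_seeding_pct(matrix: ConnectivityMatrix) -> np.ndarray:
    """Per-site total seeding as a percentage of that site's release."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * matrix.counts.sum(axis=1) / matrix.released
    return np.where(matrix.released > 0, pct, 0.0)


def retention_summary(matrix: ConnectivityMatrix) -> dict:
    """Per-site self-seeding percentages with mean / min / max."""
    pct = matrix.self_seeding_pct()
    return {
        "per_site_pct": pct,
        "mean_pct": float(pct.mean()),
        "min_pct": float(pct.min()),
        "max_pct": float(pct.max()),
    }


@dataclass
class ResidenceTimeResult:
    """E-folding residence time of a region."""

    region: str
    times_s: np.ndarray
    concentration: np.ndarray
    tau_days: float        # NaN when undefined
    defined: bool
    method: str = "crossing"


def residence_time(times_s: np.ndarray, concentration: np.ndarray,
                   region: str = "", method: str = "crossing"
                   ) -> ResidenceTimeResult:
    """E-folding residence time from a concentration series.

    ``method="crossing"``: first time C(t) falls to C(0)/e, linearly
    interpolated between samples; flagged undefined if the series never
    decays that far.  ``method="fit"``: least-squares slope of
    ln C(t)/C(0), usable when the series decays but does not reach 1/e
    within the record.
    """
    t = np.asarray(times_s, float)
    c = np.asarray(concentration, float)
    if c[0] <= 0:
        raise ValueError("initial concentration must be positive")
    target = c[0] / np.e
    if method == "crossing":
        below = np.nonzero(c <= target)[0]
        if len(below) == 0:
            return ResidenceTimeResult(region, t, c, float("nan"), False)
        k = below[0]
        if k == 0:
            tau = 0.0
        else:
            f = (c[k - 1] - target) / (c[k - 1] - c[k])
            tau = t[k - 1] + f * (t[k] - t[k - 1])
        return ResidenceTimeResult(region, t, c, tau / 86400.0, True)
    if method == "fit":
        pos = c > 0
        if pos.sum() < 2 or not np.any(c[pos] < c[0]):
            return ResidenceTimeResult(region, t, c, float("nan"), False, "fit")
        slope = np.polyfit(t[pos], np.log(c[pos] / c[0]), 1)[0]
        if slope >= 0:
            return ResidenceTimeResult(region, t, c, float("nan"), False, "fit")
        return ResidenceTimeResult(region, t, c, (-1.0 / slope) / 86400.0,
                                   True, "fit")
    raise ValueError(f"unknown method {method!r}")
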