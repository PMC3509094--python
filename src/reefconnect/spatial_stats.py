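"""Spatial statistics for the model-vs-field comparison.

Ordinary kriging under a Gaussian variogram, Moran's I spatial
autocorrelation with permutation inference, and the regression /
rank-correlation pairings that confront modelled larval seeding with
field coral cover and juvenile densities.  Coordinates are treated as
planar throughout (the analyses span well under a degree of latitude).

The geostatistics (variogram, kriging, Moran's I) are implemented
directly from their defining equations; ordinary least squares and
Spearman's rank correlation delegate to statsmodels / scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform


# ---------------------------------------------------------------------------
# Variogram
# ---------------------------------------------------------------------------

@dataclass
class VariogramModel:
    """Gaussian variogram: gamma(h) = nugget + (sill-nugget)(1 - exp(-(h/range)^2))."""

    nugget: float
    sill: float
    range_: float

    def __post_init__(self) -> None:
        if not (0 <= self.nugget <= self.sill):
            raise ValueError("need 0 <= nugget <= sill")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def gamma(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        g = self.nugget + (self.sill - self.nugget) * (
            1.0 - np.exp(-((h / self.range_) ** 2)))
        return np.where(h == 0, 0.0, g)


def empirical_variogram(points: np.ndarray, values: np.ndarray,
                        bin_width: float,
                        max_lag: float | None = None) -> pd.DataFrame:
    """Matheron estimator of the semivariance per lag bin.

    gamma(h) = mean over pairs in the bin of (z_i - z_j)^2 / 2.
    Empty bins are dropped.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(points)
    if np.all(d == 0):
        raise ValueError("all points are coincident")
    sq = pdist(values[:, None], metric="sqeuclidean") / 2.0
    if max_lag is None:
        max_lag = d.max()
    nbins = max(1, int(math.ceil(max_lag / bin_width)))
    which = np.floor(d / bin_width).astype(int)
    ok = (d > 0) & (which < nbins)
    rows = []
    for b in range(nbins):
        sel = ok & (which == b)
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(((b + 0.5) * bin_width, float(d[sel].mean()),
                     float(sq[sel].mean()), n))
    return pd.DataFrame(rows, columns=["lag", "mean_distance",
                                       "semivariance", "n_pairs"])


def fit_gaussian_variogram(table: pd.DataFrame) -> VariogramModel:
    """Weighted least-squares fit of the Gaussian model to a variogram table.

    Bins are weighted by their pair counts.  Degenerate zero-variance
    data collapse to nugget = sill = 0.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 variogram bins to fit")
    h = table["lag"].to_numpy(float)
    g = table["semivariance"].to_numpy(float)
    w = np.sqrt(table["n_pairs"].to_numpy(float))
    if np.all(g <= 1e-30):
        return VariogramModel(0.0, 0.0, float(h.max()))

    from scipy.optimize import least_squares

    def resid(p):
        nugget, psill, rng = p
        model = nugget + psill * (1.0 - np.exp(-((h / rng) ** 2)))
        return w * (model - g)

    p0 = np.array([0.0 if g[0] < g[-1] else 0.5 * g[0],
                   max(g.max() - min(g[0], g[-1]), 1e-12),
                   max(h.max() / 2.0, 1e-9)])
    sol = least_squares(resid, p0,
                        bounds=([0.0, 0.0, 1e-9 * h.max()],
                                [np.inf, np.inf, 10.0 * h.max()]))
    if not sol.success:
        raise RuntimeError(f"variogram fit failed: {sol.message}")
    nugget, psill, rng = sol.x
    return VariogramModel(float(nugget), float(nugget + psill), float(rng))


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def ordinary_kriging(points: np.ndarray, values: np.ndarray,
                     model: VariogramModel, targets: np.ndarray,
                     return_weights: bool = False):
    """Ordinary-kriging predictions and variances at target locations.

    Solves, per target, the semivariance system with the unbiasedness
    (weights-sum-to-one) Lagrange constraint.  With a zero nugget the
    predictor interpolates the data exactly.  A singular system (e.g.
    duplicate points at zero nugget) triggers one jitter-and-retry before
    raising.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 observations")
    gamma_pp = model.gamma(squareform(pdist(points)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_pp
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    gamma_pt = model.gamma(cdist(points, targets))
    b = np.empty((n + 1, targets.shape[0]))
    b[:n, :] = gamma_pt
    b[n, :] = 1.0
    try:
        lam = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        jitter = max(model.sill, 1.0) * 1e-10
        a2 = a.copy()
        a2[:n, :n] += jitter * (1.0 - np.eye(n))
        try:
            lam = np.linalg.solve(a2, b)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular kriging system (duplicate points with zero "
                f"nugget?): {err}"
            ) from err
    weights = lam[:n, :]
    mu = lam[n, :]
    preds = weights.T @ values
    variances = np.einsum("nt,nt->t", weights, gamma_pt) + mu
    variances = np.maximum(variances, 0.0)
    if return_weights:
        return preds, variances, weights.T
    return preds, variances


def krige_surface(points, values, model, grid, step_cells: int = 1):
    """Kriged prediction raster on a bathymetry grid's cell centres."""
    xs, ys = grid.cell_centres()
    xs = xs[::step_cells]
    ys = ys[::step_cells]
    xx, yy = np.meshgrid(xs, ys)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    preds, var = ordinary_kriging(points, values, model, targets)
    return preds.reshape(len(ys), len(xs)), var.reshape(len(ys), len(xs))


# ---------------------------------------------------------------------------
# Spatial weights and Moran's I
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Site-pair spatial weights (non-negative, zero diagonal)."""

    w: np.ndarray
    scheme: str
    row_standardized: bool

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        if np.any(self.w < 0) or np.any(np.diag(self.w) != 0):
            raise ValueError("weights must be non-negative with zero diagonal")


def knn_weights(points: np.ndarray, k: int = 8,
                row_standardize: bool = True) -> SpatialWeights:
    """k-nearest-neighbour binary weights (optionally row-standardized)."""
    points = np.asarray(points, float)
    n = len(points)
    if k >= n:
        raise ValueError("k must be smaller than the number of sites")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in np.atleast_1d(idx[i]) if j != i][:k]
        w[i, neigh] = 1.0
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    return SpatialWeights(w, f"knn{k}", row_standardize)


def inverse_distance_weights(points: np.ndarray, power: float = 1.0,
                             row_standardize: bool = True) -> SpatialWeights:
    points = np.asarray(points, float)
    d = squareform(pdist(points))
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    return SpatialWeights(w, f"idw{power:g}", row_standardize)


@dataclass
class MoransIResult:
    i: float
    expected: float
    p: float
    permutations: int


def morans_i(values: np.ndarray, weights: SpatialWeights,
             permutations: int = 999, seed: int = 0) -> MoransIResult:
    """Moran's I with a two-sided permutation test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 the total weight.  The p-value is the two-sided
    permutation probability of a deviation from E[I] = -1/(n-1) at least
    as large as observed.
    """
    z = np.asarray(values, float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 sites")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("values have zero variance")
    w = weights.w
    s0 = w.sum()

    def stat(zz):
        return (n / s0) * float(zz @ w @ zz) / float(zz @ zz)

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    zp = rng.permuted(np.broadcast_to(z, (permutations, n)).copy(), axis=1)
    num = np.einsum("pi,ij,pj->p", zp, w, zp)
    i_perm = (n / s0) * num / np.einsum("pi,pi->p", zp, zp)
    extreme = int((np.abs(i_perm - expected)
                   >= abs(i_obs - expected) - 1e-15).sum())
    p = (1 + extreme) / (permutations + 1)
    return MoransIResult(i=i_obs, expected=expected, p=p,
                         permutations=permutations)


# ---------------------------------------------------------------------------
# Regression and rank correlation
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int


def linear_regression(x: np.ndarray, y: np.ndarray,
                      alpha: float = 0.05) -> LinearFit:
    """Ordinary least squares with t-based slope inference and CIs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=alpha)
    return LinearFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), p_slope=float(res.pvalues[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        n=len(x),
    )


def spearman(x: np.ndarray, y: np.ndarray, permutations: int = 0,
             seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties).

    By default the p-value uses the t-approximation; pass a permutation
    count for an exact-style permutation p instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rs, p = stats.spearmanr(x, y)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        extreme = 0
        for _ in range(permutations):
            rp, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(rp) >= abs(rs) - 1e-15:
                extreme += 1
        p = (1 + extreme) / (permutations + 1)
    return float(rs), float(p)


# ---------------------------------------------------------------------------
# Model-vs-field comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Tidy statistic table of every predictor/response pairing."""

    table: pd.DataFrame
    n_joined: int


_JUV_COLUMNS = {
    "juv_acropora_per_m2": "acropora",
    "juv_pocillopora_per_m2": "pocillopora",
    "juv_stylophora_per_m2": "stylophora",
}


def compare_model_to_field(connectivity_summary: pd.DataFrame,
                           survey: pd.DataFrame,
                           weights_scheme: str = "knn",
                           join_radius_m: float = 4000.0,
                           knn_k: int = 8,
                           permutations: int = 999,
                           seed: int = 0) -> ComparisonResult:
    """Confront modelled seeding with surveyed cover and juveniles.

    *connectivity_summary* holds one row per seeding site with columns
    ``x``, ``y``, ``self_seeding_pct``, ``imports_pct`` and
    ``total_seeding_pct``; each survey site is joined to its nearest
    seeding site within *join_radius_m*.  The result table carries OLS
    fits of coral cover on each predictor, Spearman correlations of each
    juvenile density on each predictor, and Moran's I of juvenile
    Acropora per habitat stratum.
    """
    pred_cols = ["self_seeding_pct", "imports_pct", "total_seeding_pct"]
    for c in ("x", "y", *pred_cols):
        if c not in connectivity_summary.columns:
            raise ValueError(f"connectivity summary lacks column {c!r}")
    tree = cKDTree(connectivity_summary[["x", "y"]].to_numpy())
    d, idx = tree.query(survey[["x", "y"]].to_numpy())
    joined = survey.loc[d <= join_radius_m].copy()
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} survey sites joinable within "
            f"{join_radius_m} m of a seeding site"
        )
    for c in pred_cols:
        joined[c] = connectivity_summary[c].to_numpy()[idx[d <= join_radius_m]]

    rows = []
    for pred in pred_cols:
        x = joined[pred].to_numpy()
        fit = linear_regression(x, joined["coral_cover_pct"].to_numpy())
        rows.append((pred, "coral_cover_pct", "ols_r_squared",
                     fit.r_squared, fit.p_slope, fit.slope))
        for col, taxon in _JUV_COLUMNS.items():
            rs, p = spearman(x, joined[col].to_numpy())
            rows.append((pred, f"juv_{taxon}", "spearman_rs", rs, p, np.nan))

    for stratum, grp in joined.groupby("stratum"):
        vals = grp["juv_acropora_per_m2"].to_numpy()
        pts = grp[["x", "y"]].to_numpy()
        if len(grp) < 4 or np.ptp(vals) == 0:
            continue
        if weights_scheme == "knn":
            w = knn_weights(pts, k=min(knn_k, len(grp) - 1))
        else:
            w = inverse_distance_weights(pts)
        res = morans_i(vals, w, permutations=permutations, seed=seed)
        rows.append((f"stratum:{stratum}", "juv_acropora", "morans_i",
                     res.i, res.p, np.nan))

    table = pd.DataFrame(rows, columns=["predictor", "response", "statistic",
                                        "value", "p", "slope"])
    return ComparisonResult(table=table, n_joined=len(joined))
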