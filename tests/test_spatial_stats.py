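import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from reefconnect.spatial_stats import (
    VariogramModel,
    compare_model_to_field,
    empirical_variogram,
    fit_gaussian_variogram,
    inverse_distance_weights,
    knn_weights,
    linear_regression,
    morans_i,
    ordinary_kriging,
    spearman,
)


def random_points(rng, n, scale=10000.0):
    return rng.uniform(0, scale, (n, 2))


# -- brute-force oracles -----------------------------------------------------

def brute_variogram(points, values, bin_width, max_lag):
    nbins = int(np.ceil(max_lag / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, int)
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            h = np.hypot(*(points[i] - points[j]))
            b = int(h // bin_width)
            if 0 < h and b < nbins:
                sums[b] += 0.5 * (values[i] - values[j]) ** 2
                counts[b] += 1
    return {b: sums[b] / counts[b] for b in range(nbins) if counts[b]}


def brute_morans_i(values, w):
    z = values - values.mean()
    n = len(z)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return (n / w.sum()) * num / (z ** 2).sum()


def brute_spearman(x, y):
    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_ols(x, y):
    a = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(a.T @ a, a.T @ y)
    resid = y - a @ coef
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    return coef[1], coef[0], 1.0 - ss_res / ss_tot


class TestVariogram:
    def test_constant_field_has_zero_semivariance(self):
        rng = np.random.default_rng(0)
        pts = random_points(rng, 30)
        tab = empirical_variogram(pts, np.full(30, 4.2), bin_width=2000.0)
        assert np.all(tab["semivariance"] == 0.0)

    def test_two_point_semivariance_is_half_squared_difference(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0]])
        tab = empirical_variogram(pts, np.array([1.0, 4.0]), bin_width=2000.0)
        assert len(tab) == 1
        assert tab["semivariance"][0] == 4.5  # (4-1)^2 / 2

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            empirical_variogram(np.zeros((4, 2)), np.arange(4.0), 100.0)

    def test_matches_brute_force_pairwise_table(self):
        rng = np.random.default_rng(1)
        pts = random_points(rng, 40)
        vals = rng.normal(size=40)
        tab = empirical_variogram(pts, vals, bin_width=1500.0)
        oracle = brute_variogram(pts, vals, 1500.0, pdist(pts).max())
        got = {int(l // 1500.0): s
               for l, s in zip(tab["lag"], tab["semivariance"])}
        assert set(got) == set(oracle)
        for b in oracle:
            assert got[b] == pytest.approx(oracle[b])


class TestVariogramFit:
    def test_recovers_known_model_from_gp_sample(self):
        rng = np.random.default_rng(5)
        model = VariogramModel(nugget=0.0, sill=10.0, range_=5000.0)
        pts = random_points(rng, 200, 20000.0)
        h = squareform(pdist(pts))
        cov = (model.sill - model.nugget) * np.exp(-((h / model.range_) ** 2))
        cov += 1e-8 * np.eye(len(pts))
        vals = rng.multivariate_normal(np.zeros(len(pts)), cov,
                                       method="cholesky")
        tab = empirical_variogram(pts, vals, bin_width=1000.0, max_lag=15000.0)
        fit = fit_gaussian_variogram(tab)
        assert fit.sill == pytest.approx(10.0, rel=0.5)
        assert fit.range_ == pytest.approx(5000.0, rel=0.5)

    def test_zero_variance_collapses_to_null_model(self):
        rng = np.random.default_rng(2)
        pts = random_points(rng, 25)
        tab = empirical_variogram(pts, np.full(25, 1.0), bin_width=2000.0)
        fit = fit_gaussian_variogram(tab)
        assert fit.nugget == 0.0
        assert fit.sill == 0.0

    def test_fit_beats_best_constant_model(self):
        rng = np.random.default_rng(3)
        pts = random_points(rng, 60)
        vals = np.sin(pts[:, 0] / 3000.0) + 0.1 * rng.normal(size=60)
        tab = empirical_variogram(pts, vals, bin_width=1500.0)
        fit = fit_gaussian_variogram(tab)
        h = tab["lag"].to_numpy()
        g = tab["semivariance"].to_numpy()
        w = tab["n_pairs"].to_numpy()
        sse_fit = (w * (fit.gamma(h) - g) ** 2).sum()
        const = (w * g).sum() / w.sum()
        sse_const = (w * (const - g) ** 2).sum()
        assert sse_fit <= sse_const + 1e-9

    def test_too_few_bins_rejected(self):
        tab = pd.DataFrame({"lag": [1.0, 2.0], "semivariance": [1.0, 2.0],
                            "n_pairs": [3, 3]})
        with pytest.raises(ValueError):
            fit_gaussian_variogram(tab)


class TestOrdinaryKriging:
    def test_exact_interpolation_at_zero_nugget(self):
        rng = np.random.default_rng(4)
        pts = random_points(rng, 15)
        vals = rng.normal(size=15)
        model = VariogramModel(0.0, 4.0, 4000.0)
        preds, var = ordinary_kriging(pts, vals, model, pts)
        assert np.allclose(preds, vals, atol=1e-6)
        assert np.all(var < 1e-6)

    def test_constant_data_predicts_constant(self):
        rng = np.random.default_rng(6)
        pts = random_points(rng, 12)
        model = VariogramModel(0.5, 3.0, 3000.0)
        targets = random_points(rng, 20)
        preds, var = ordinary_kriging(pts, np.full(12, 7.0), model, targets)
        assert np.allclose(preds, 7.0, atol=1e-8)
        assert np.all(var >= 0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(7)
        pts = random_points(rng, 20)
        vals = rng.normal(size=20)
        model = VariogramModel(0.2, 2.0, 5000.0)
        targets = random_points(rng, 15)
        _, _, w = ordinary_kriging(pts, vals, model, targets,
                                   return_weights=True)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_five_point_system_matches_direct_solve(self):
        rng = np.random.default_rng(8)
        pts = random_points(rng, 5)
        vals = rng.normal(size=5)
        model = VariogramModel(0.1, 2.0, 4000.0)
        target = np.array([[4000.0, 6000.0]])
        preds, var = ordinary_kriging(pts, vals, model, target)
        # direct assembly of the 6x6 augmented system
        a = np.ones((6, 6))
        a[:5, :5] = model.gamma(squareform(pdist(pts)))
        a[5, 5] = 0.0
        b = np.ones(6)
        b[:5] = model.gamma(np.hypot(*(pts - target[0]).T))
        lam = np.linalg.solve(a, b)
        assert preds[0] == pytest.approx(lam[:5] @ vals)
        assert var[0] == pytest.approx(lam[:5] @ b[:5] + lam[5])

    def test_duplicate_points_with_zero_nugget_recoverable(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5000.0, 0.0]])
        vals = np.array([1.0, 1.0, 3.0])
        model = VariogramModel(0.0, 2.0, 3000.0)
        preds, _ = ordinary_kriging(pts, vals, model,
                                    np.array([[2500.0, 0.0]]))
        assert 1.0 <= preds[0] <= 3.0


class TestMoransI:
    def test_checkerboard_with_rook_weights(self):
        values = np.array([1.0, -1.0, -1.0, 1.0])  # 2x2 checkerboard
        w = np.array([[0, 1, 1, 0],
                      [1, 0, 0, 1],
                      [1, 0, 0, 1],
                      [0, 1, 1, 0]], float)
        from reefconnect.spatial_stats import SpatialWeights

        res = morans_i(values, SpatialWeights(w, "rook", False),
                       permutations=99, seed=0)
        assert res.i == pytest.approx(-1.0)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(9)
        pts = random_points(rng, 16)
        vals = rng.normal(size=16)
        w = knn_weights(pts, k=4)
        res = morans_i(vals, w, permutations=99, seed=1)
        assert res.i == pytest.approx(brute_morans_i(vals, w.w))

    def test_iid_values_rarely_significant(self):
        rng = np.random.default_rng(10)
        pts = random_points(rng, 100)
        w = knn_weights(pts, k=8)
        rejections = 0
        reps = 60
        for r in range(reps):
            vals = rng.normal(size=100)
            res = morans_i(vals, w, permutations=199, seed=r)
            rejections += res.p <= 0.05
        assert rejections / reps <= 0.10

    def test_permutation_p_is_seed_reproducible(self):
        rng = np.random.default_rng(11)
        pts = random_points(rng, 30)
        vals = rng.normal(size=30)
        w = knn_weights(pts, k=5)
        a = morans_i(vals, w, permutations=499, seed=7)
        b = morans_i(vals, w, permutations=499, seed=7)
        assert a.p == b.p

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(12)
        w = knn_weights(random_points(rng, 10), k=3)
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(10), w)

    def test_weight_schemes_are_valid(self):
        rng = np.random.default_rng(13)
        pts = random_points(rng, 20)
        for w in (knn_weights(pts, k=6), inverse_distance_weights(pts)):
            assert np.all(np.diag(w.w) == 0)
            assert np.all(w.w >= 0)
            assert np.allclose(w.w.sum(axis=1), 1.0)


class TestRegressionAndSpearman:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 10, 20)
        fit = linear_regression(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        fit = linear_regression(x, y)
        slope, intercept, r2 = brute_ols(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_regression(np.ones(10), np.arange(10.0))

    def test_monotone_sequences_give_unit_correlation(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_ties_handled_with_midranks(self):
        rng = np.random.default_rng(15)
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        rs, _ = spearman(x, y)
        assert rs == pytest.approx(brute_spearman(x, y))

    def test_permutation_p_option(self):
        rng = np.random.default_rng(16)
        x = np.arange(20.0)
        y = x + rng.normal(scale=2.0, size=20)
        _, p = spearman(x, y, permutations=499, seed=3)
        assert p < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


def make_summary_and_survey(rng, n_sites=20, noise_sd=0.0, link=True):
    xy = rng.uniform(0, 30000, (n_sites, 2))
    self_pct = rng.uniform(0, 60, n_sites)
    imports = rng.uniform(0, 30, n_sites)
    summary = pd.DataFrame({
        "site_id": np.arange(n_sites), "x": xy[:, 0], "y": xy[:, 1],
        "self_seeding_pct": self_pct, "imports_pct": imports,
        "total_seeding_pct": self_pct + imports,
    })
    cover = 15.8 + 0.19 * self_pct + rng.normal(0, noise_sd, n_sites)
    juv = (0.1 + 0.01 * (self_pct + imports) if link
           else rng.uniform(0, 1, n_sites))
    survey = pd.DataFrame({
        "site_id": np.arange(n_sites), "x": xy[:, 0], "y": xy[:, 1],
        "stratum": ["outer"] * (n_sites // 2) + ["patch"] * (n_sites
                                                             - n_sites // 2),
        "coral_cover_pct": cover,
        "juv_acropora_per_m2": juv,
        "juv_pocillopora_per_m2": rng.uniform(0, 1, n_sites),
        "juv_stylophora_per_m2": rng.uniform(0, 1, n_sites),
    })
    return summary, survey


class TestCompareModelToField:
    def test_noise_free_cover_gives_perfect_fit(self):
        rng = np.random.default_rng(17)
        summary, survey = make_summary_and_survey(rng, noise_sd=0.0)
        res = compare_model_to_field(summary, survey, permutations=99)
        row = res.table[(res.table.predictor == "self_seeding_pct")
                        & (res.table.response == "coral_cover_pct")]
        assert row["value"].iloc[0] == pytest.approx(1.0)
        assert row["slope"].iloc[0] == pytest.approx(0.19)

    def test_linked_juveniles_correlate_with_total_seeding(self):
        rng = np.random.default_rng(18)
        summary, survey = make_summary_and_survey(rng, link=True)
        res = compare_model_to_field(summary, survey, permutations=99)
        row = res.table[(res.table.predictor == "total_seeding_pct")
                        & (res.table.response == "juv_acropora")]
        assert row["value"].iloc[0] == pytest.approx(1.0)  # monotone link

    def test_table_covers_all_pairings(self):
        rng = np.random.default_rng(19)
        summary, survey = make_summary_and_survey(rng, noise_sd=3.0)
        res = compare_model_to_field(summary, survey, permutations=99)
        preds = {"self_seeding_pct", "imports_pct", "total_seeding_pct"}
        got = set(res.table[res.table.statistic != "morans_i"].predictor)
        assert got == preds
        assert (res.table.statistic == "morans_i").sum() >= 1

    def test_unjoinable_survey_rejected(self):
        rng = np.random.default_rng(20)
        summary, survey = make_summary_and_survey(rng)
        survey = survey.assign(x=survey.x + 1e6)
        with pytest.raises(ValueError, match="joinable"):
            compare_model_to_field(summary, survey)
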