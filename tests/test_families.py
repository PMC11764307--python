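import numpy as np
import pytest

from mmlsdm.covariates import CovariateGrid
from mmlsdm.errors import (
    CollinearityError,
    DegenerateDataError,
    InsufficientDataError,
)
from mmlsdm.families import (
    fit_family,
    fit_hardcore,
    fit_ippp,
    fit_logistic_occupancy,
    fit_negbin_counts,
    fit_poisson_counts,
)
from mmlsdm.pointprocess import (
    CellData,
    PointPattern,
    Window,
    aggregate,
    intensity_surface,
    simulate_ippp,
    thin,
)
from scipy.special import gammaln


class TestFitIppp:
    def test_intercept_only_closed_form(self, uniform_pattern, pc_grid):
        # MLE lambda = n/|A|; l = n ln(n/|A|) - n; F = integral of lambda = n
        fm = fit_ippp(uniform_pattern, pc_grid, [])
        assert np.isclose(fm.theta[0], np.log(100 / 1250), atol=1e-8)
        assert np.isclose(fm.loglik, 100 * np.log(0.08) - 100, atol=1e-6)
        assert np.isclose(fm.fisher[0, 0], 100.0, atol=1e-6)

    def test_empty_pattern_rejected(self, pc_grid):
        empty = PointPattern(np.empty((0, 2)), Window(50, 25))
        with pytest.raises(DegenerateDataError):
            fit_ippp(empty, pc_grid, [])

    def test_parameter_recovery_within_3se(self, pc_grid):
        theta0 = np.concatenate([[-3.0], 1.0 / pc_grid.sigmas[:4]])
        lam = intensity_surface(pc_grid, [0, 1, 2, 3], theta0)
        hits = 0
        for s in range(20):
            pat = simulate_ippp(lam, pc_grid, seed=100 + s)
            fm = fit_ippp(pat, pc_grid, [0, 1, 2, 3])
            se = np.sqrt(np.diag(np.linalg.inv(fm.fisher)))
            hits += np.all(np.abs(fm.theta - theta0) < 3 * se)
        assert hits >= 18

    def test_duplicated_feature_collinearity(self, pc_grid):
        dup = CovariateGrid(pc_grid.n_rows, pc_grid.n_cols, 1.0,
                            ("a", "b"),
                            np.column_stack([pc_grid.values[:, 0]] * 2))
        rng = np.random.default_rng(1)
        pat = PointPattern(rng.random((50, 2)) * [50, 25], Window(50, 25))
        with pytest.raises(CollinearityError):
            fit_ippp(pat, dup, [0, 1])

    def test_score_zero_at_optimum(self, study_pattern, pc_grid):
        fm = fit_ippp(study_pattern, pc_grid, [0, 1, 2, 3])
        cells = aggregate(study_pattern, pc_grid)
        X = np.column_stack([np.ones(1250), pc_grid.values[:, :4]])
        mu = np.exp(X @ fm.theta)
        grad = X.T @ (cells.counts - mu)
        assert np.max(np.abs(grad)) <= 1e-6


class TestFitPoissonCounts:
    def test_intercept_only_closed_form(self, pc_grid):
        counts = np.zeros(1250, dtype=int)
        counts[:100] = 1
        cells = CellData(25, 50, 1.0, counts)
        fm = fit_poisson_counts(cells, pc_grid, [])
        assert np.isclose(fm.theta[0], np.log(0.08), atol=1e-8)

    def test_all_zero_counts_rejected(self, pc_grid):
        with pytest.raises(DegenerateDataError):
            fit_poisson_counts(CellData(25, 50, 1.0, np.zeros(1250, int)),
                               pc_grid, [])

    def test_loglik_offset_from_ippp(self, study_pattern, pc_grid):
        # with unit cells: count loglik = pattern loglik - sum ln(y_c!)
        fm_pat = fit_ippp(study_pattern, pc_grid, [0, 1])
        cells = aggregate(study_pattern, pc_grid)
        fm_cnt = fit_poisson_counts(cells, pc_grid, [0, 1])
        offset = gammaln(cells.counts + 1.0).sum()
        assert np.allclose(fm_pat.theta, fm_cnt.theta, atol=1e-8)
        assert np.isclose(fm_cnt.loglik, fm_pat.loglik - offset, atol=1e-6)

    def test_matches_bruteforce_on_toy_grid(self):
        # 3-cell grid, 1 feature: grid-search the likelihood directly
        grid = CovariateGrid(1, 3, 1.0, ("s",),
                             np.array([[-1.0], [0.0], [1.0]]))
        cells = CellData(1, 3, 1.0, np.array([2, 1, 4]))
        fm = fit_poisson_counts(cells, grid, [0])
        b0 = np.linspace(-2, 2, 401)
        b1 = np.linspace(-2, 2, 401)
        B0, B1 = np.meshgrid(b0, b1)
        s = grid.values[:, 0]
        y = cells.counts
        ll = sum(y[c] * (B0 + B1 * s[c]) - np.exp(B0 + B1 * s[c])
                 for c in range(3))
        k = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(fm.theta[0] - B0[k]) < 1e-2  # grid resolution
        assert abs(fm.theta[1] - B1[k]) < 1e-2
        # refine: analytic score is zero at the returned optimum
        mu = np.exp(fm.theta[0] + fm.theta[1] * s)
        assert np.allclose([np.sum(y - mu), np.sum((y - mu) * s)], 0,
                           atol=1e-6)

    def test_matches_statsmodels(self, study_pattern, pc_grid):
        sm = pytest.importorskip("statsmodels.api")
        cells = aggregate(study_pattern, pc_grid)
        fm = fit_poisson_counts(cells, pc_grid, [0, 1, 2])
        X = np.column_stack([np.ones(1250), pc_grid.values[:, :3]])
        ref = sm.GLM(cells.counts, X, family=sm.families.Poisson()).fit()
        assert np.allclose(fm.theta, ref.params, atol=1e-6)
        assert np.isclose(fm.loglik, ref.llf, atol=1e-6)


class TestFitNegbin:
    def test_residual_df(self, study_pattern, pc_grid):
        cells = aggregate(study_pattern, pc_grid)
        fm = fit_negbin_counts(cells, pc_grid, list(range(8)))
        assert fm.residual_df == 1250 - 9 == 1241

    def test_dispersion_near_one_for_poisson_data(self, pc_grid):
        theta0 = np.concatenate([[-3.0], 1.0 / pc_grid.sigmas[:2]])
        lam = intensity_surface(pc_grid, [0, 1], theta0)
        disps = []
        for s in range(10):
            cells = aggregate(simulate_ippp(lam, pc_grid, seed=200 + s),
                              pc_grid)
            disps.append(fit_negbin_counts(cells, pc_grid, [0, 1]).dispersion)
        assert abs(np.mean(disps) - 1.0) < 0.15

    def test_detects_gamma_mixing_overdispersion(self, pc_grid):
        rng = np.random.default_rng(77)
        lam = np.full(1250, 0.5) * rng.gamma(2.0, 0.5, 1250)
        counts = rng.poisson(lam)
        cells = CellData(25, 50, 1.0, counts)
        fm = fit_negbin_counts(cells, pc_grid, [])
        po = fit_poisson_counts(cells, pc_grid, [])
        assert fm.dispersion > 1.05
        assert fm.loglik > po.loglik

    def test_matches_statsmodels_ml(self, pc_grid):
        smd = pytest.importorskip("statsmodels.discrete.discrete_model")
        rng = np.random.default_rng(5)
        lam = np.exp(-1.0 + 0.5 * pc_grid.values[:, 0]) \
            * rng.gamma(4.0, 0.25, 1250)
        cells = CellData(25, 50, 1.0, rng.poisson(lam))
        fm = fit_negbin_counts(cells, pc_grid, [0])
        X = np.column_stack([np.ones(1250), pc_grid.values[:, 0]])
        ref = smd.NegativeBinomial(cells.counts, X).fit(disp=0)
        assert np.allclose(fm.theta, ref.params[:2], atol=1e-3)
        assert np.isclose(fm.alpha, ref.params[2], rtol=0.05)
        assert np.isclose(fm.loglik, ref.llf, atol=0.01)


class TestFitLogistic:
    def test_intercept_only_closed_form(self, pc_grid):
        counts = np.zeros(1250, dtype=int)
        counts[:250] = 1
        cells = CellData(25, 50, 1.0, counts)
        fm = fit_logistic_occupancy(cells, pc_grid, [])
        assert np.isclose(fm.theta[0], np.log(0.25), atol=1e-8)
        assert np.isclose(fm.fisher[0, 0], 1250 * 0.2 * 0.8, atol=1e-6)

    def test_constant_occupancy_rejected(self, pc_grid):
        with pytest.raises(DegenerateDataError):
            fit_logistic_occupancy(CellData(25, 50, 1.0, np.ones(1250, int)),
                                   pc_grid, [])

    def test_parameter_recovery_within_3se(self, pc_grid):
        beta0 = np.array([-1.0, 1.0, -0.8])
        eta = beta0[0] + pc_grid.values[:, :2] / pc_grid.sigmas[:2] \
            @ beta0[1:]
        p = 1 / (1 + np.exp(-eta))
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            cells = CellData(25, 50, 1.0, (rng.random(1250) < p).astype(int))
            g2 = CovariateGrid(25, 50, 1.0, ("a", "b"),
                               pc_grid.values[:, :2] / pc_grid.sigmas[:2])
            fm = fit_logistic_occupancy(cells, g2, [0, 1])
            se = np.sqrt(np.diag(np.linalg.inv(fm.fisher)))
            hits += np.all(np.abs(fm.theta - beta0) < 3 * se)
        assert hits >= 18

    def test_matches_statsmodels(self, study_pattern, pc_grid):
        sm = pytest.importorskip("statsmodels.api")
        cells = aggregate(study_pattern, pc_grid)
        fm = fit_logistic_occupancy(cells, pc_grid, [0, 1])
        X = np.column_stack([np.ones(1250), pc_grid.values[:, :2]])
        ref = sm.Logit(cells.occupancy, X).fit(disp=0)
        assert np.allclose(fm.theta, ref.params, atol=1e-6)
        assert np.isclose(fm.loglik, ref.llf, atol=1e-8)


class TestFitHardcore:
    def test_radius_is_bruteforce_min_distance(self, study_pattern, pc_grid):
        pat = thin(study_pattern, 0.3, seed=0)
        fm = fit_hardcore(pat, pc_grid, [0], n_profile=11)
        pts = pat.points
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert fm.radius == d.min()
        assert fm.extra_prior_mean == pytest.approx(1250 / pat.n)

    def test_two_point_pattern(self, pc_grid):
        pat = PointPattern(np.array([[1.0, 1.0], [1.0, 3.0]]), Window(50, 25))
        fm = fit_hardcore(pat, pc_grid, [], n_profile=5)
        assert fm.radius == 2.0

    def test_single_point_rejected(self, pc_grid):
        pat = PointPattern(np.array([[1.0, 1.0]]), Window(50, 25))
        with pytest.raises(InsufficientDataError):
            fit_hardcore(pat, pc_grid, [])

    def test_r_profile_window_sensitivity(self, study_pattern, pc_grid):
        # the radius information entry comes from a smoothed profile; the
        # coefficient estimates and message must not depend on its grid
        pat = thin(study_pattern, 0.5, seed=1)
        a = fit_hardcore(pat, pc_grid, [0, 1], n_profile=11)
        b = fit_hardcore(pat, pc_grid, [0, 1], n_profile=41)
        assert np.allclose(a.theta, b.theta, atol=1e-10)
        assert a.radius == b.radius
        assert a.fisher[-1, -1] > 0 and b.fisher[-1, -1] > 0
        from mmlsdm.mml import message_length

        ia, ib = message_length(a, 8).total, message_length(b, 8).total
        assert np.isfinite(ia) and np.isfinite(ib)
        assert abs(ia - ib) < 2.0  # only the r-precision term may move

    def test_agrees_with_ippp_on_poisson_pattern(self, pc_grid):
        # pure IPPP data: pseudolikelihood trend estimates track the MLE
        theta0 = np.concatenate([[-3.0], 1.0 / pc_grid.sigmas[:2]])
        lam = intensity_surface(pc_grid, [0, 1], theta0)
        deviations = []
        for s in range(5):
            pat = simulate_ippp(lam, pc_grid, seed=400 + s)
            hc = fit_hardcore(pat, pc_grid, [0, 1], n_profile=11)
            ip = fit_ippp(pat, pc_grid, [0, 1])
            se = np.sqrt(np.diag(np.linalg.inv(ip.fisher)))
            deviations.append(np.abs(hc.theta - ip.theta) / se)
        assert np.max(deviations) < 3.0


class TestInvariants:
    @pytest.mark.parametrize("family,subset", [
        ("ippp", [0, 1, 2]),
        ("poisson_count", [0, 3]),
        ("negbin_count", [1, 2]),
        ("logistic_occupancy", [0, 1]),
        ("hardcore", [0]),
    ])
    def test_fisher_symmetric_positive_definite(self, family, subset,
                                                study_pattern, pc_grid):
        data = study_pattern if family in ("ippp", "hardcore") \
            else aggregate(study_pattern, pc_grid)
        kw = {"n_profile": 11} if family == "hardcore" else {}
        fm = fit_family(family, data, pc_grid, subset, **kw)
        F = fm.fisher
        assert np.allclose(F, F.T, atol=1e-8)
        assert np.linalg.eigvalsh(F).min() > 0
        assert np.isfinite(fm.loglik)

    @pytest.mark.parametrize("family", ["ippp", "poisson_count",
                                        "logistic_occupancy"])
    def test_nesting_monotonicity(self, family, study_pattern, pc_grid):
        data = study_pattern if family == "ippp" \
            else aggregate(study_pattern, pc_grid)
        lls = [fit_family(family, data, pc_grid, list(range(k))).loglik
               for k in range(5)]
        assert np.all(np.diff(lls) >= -1e-6)
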