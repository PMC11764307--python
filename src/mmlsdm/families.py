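"""Maximum-likelihood fits for the candidate model families.

Five families share one interface: the inhomogeneous Poisson point process
(IPPP) and the hardcore process consume point patterns; Poisson and
negative-binomial (NB2) regressions consume per-cell counts; logistic
regression consumes per-cell occupancy.  Every fit returns the coefficient
vector (intercept first), the maximized (pseudo)log-likelihood in nats, and
the expected Fisher information over the continuous parameters, which the
message-length layer turns into a coding cost.

Solvers are Fisher-scoring Newton iterations written directly in numpy:
subset-selection experiments evaluate every candidate subset, so each fit
must cost well under a millisecond on a 1250-cell grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .covariates import CovariateGrid
from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateDataError,
    DispersionError,
    GeometryError,
    InsufficientDataError,
    InvalidArgumentError,
    SeparationError,
)
from .pointprocess import CellData, PointPattern, aggregate, min_pairwise_distance

__all__ = [
    "FAMILIES",
    "DATA_VIEWS",
    "FittedModel",
    "fit_ippp",
    "fit_poisson_counts",
    "fit_negbin_counts",
    "fit_logistic_occupancy",
    "fit_hardcore",
    "fit_family",
]

FAMILIES = ("ippp", "poisson_count", "negbin_count", "logistic_occupancy",
            "hardcore")

#: which data representation each family consumes
DATA_VIEWS = {
    "ippp": "pattern",
    "hardcore": "pattern",
    "poisson_count": "counts",
    "negbin_count": "counts",
    "logistic_occupancy": "occupancy",
}

_MAX_ITER = 100
_GRAD_TOL = 1e-8
_MIN_ALPHA = 1e-8  # NB2 size-inverse lower bound (Poisson limit)


@dataclass(frozen=True)
class FittedModel:
    """A fitted candidate model.

    ``theta`` holds the trend coefficients, intercept first.  ``dispersion``
    is the NB2 dispersion statistic (Pearson chi-square over residual df),
    ``radius`` the hardcore exclusion radius; at most one is set.
    ``fisher`` is the expected information over all continuous parameters
    in order (theta..., extra), and ``extra_prior_mean`` the mean of the
    exponential prior used for the extra parameter's coding cost.
    """

    family: str
    subset: tuple
    theta: np.ndarray
    loglik: float
    fisher: np.ndarray
    n_points: int
    n_cells: int
    dispersion: float | None = None
    radius: float | None = None
    extra_prior_mean: float | None = None
    residual_df: int | None = None
    converged: bool = True
    n_iter: int = 0
    alpha: float = field(default=0.0)  # NB2 size-inverse used in loglik

    @property
    def data_view(self) -> str:
        return DATA_VIEWS[self.family]

    @property
    def n_params(self) -> int:
        """Number of free continuous parameters (for AIC/AICc/BIC)."""
        extra = int(self.dispersion is not None or self.radius is not None)
        return len(self.theta) + extra

    def to_json(self) -> str:
        d = {
            "family": self.family,
            "subset": list(self.subset),
            "theta": [float(v) for v in self.theta],
            "loglik": float(self.loglik),
            "fisher": [float(v) for v in np.asarray(self.fisher).ravel()],
            "n_points": self.n_points,
            "n_cells": self.n_cells,
            "converged": self.converged,
            "iterations": self.n_iter,
        }
        if self.dispersion is not None:
            d["dispersion"] = float(self.dispersion)
        if self.radius is not None:
            d["radius"] = float(self.radius)
        return json.dumps(d)


# -- shared machinery --------------------------------------------------------

def _design(grid: CovariateGrid, subset) -> np.ndarray:
    subset = list(subset)
    X = np.empty((grid.n_cells, len(subset) + 1))
    X[:, 0] = 1.0
    if subset:
        X[:, 1:] = grid.values[:, subset]
    return X


def _check_rank(X: np.ndarray, subset) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
    if bad.size:
        cols = [("intercept" if j == 0 else f"feature {list(subset)[j - 1]}")
                for j in bad]
        raise CollinearityError(
            f"rank-deficient design; dependent columns: {', '.join(cols)}",
            columns=list(bad))


def _poisson_newton(X, y, exposure, beta0=None):
    """Maximize sum(y*eta) - sum(exposure*exp(eta)) by Fisher scoring.

    Handles zero exposure (blocked quadrature cells keep their linear term).
    Returns (beta, mu, iterations).
    """
    total_e = exposure.sum()
    if beta0 is None:
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.sum(), 0.5) / total_e)
    else:
        beta = beta0.copy()

    def obj(b):
        eta = X @ b
        return y @ eta - exposure @ np.exp(np.clip(eta, -700, 700))

    f = obj(beta)
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -700, 700)
        mu = exposure * np.exp(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) <= _GRAD_TOL:
            return beta, mu, it
        H = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in Newton step") from exc
        # step halving on likelihood decrease
        t = 1.0
        for _ in range(40):
            f_new = obj(beta + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        f = f_new
    eta = np.clip(X @ beta, -700, 700)
    mu = exposure * np.exp(eta)
    if np.max(np.abs(X.T @ (y - mu))) <= 1e-6 * max(1.0, y.sum()):
        return beta, mu, _MAX_ITER  # flat-likelihood plateau, accept
    raise ConvergenceError("Poisson scoring failed to converge")


# -- point-process families --------------------------------------------------

def fit_ippp(pattern: PointPattern, grid: CovariateGrid, subset,
             cell_mask=None) -> FittedModel:
    """IPPP with log-linear intensity, fitted on the gridded discretization.

    Maximizes l(theta) = sum_points ln lambda(x_i) - sum_c lambda_c a_c.
    With piecewise-constant covariates this is exactly Poisson regression of
    per-cell counts with offset ln(cell area) (the one-quadrature-point-per
    -cell Berman-Turner device).  Expected information:
    F = sum_c s_c s_c' lambda_c a_c.

    ``cell_mask`` (boolean per cell) restricts the fit to a sub-region:
    counts and the intensity integral outside the mask are ignored (used by
    block cross-validation to train on part of the window).
    """
    if pattern.n == 0:
        raise DegenerateDataError("cannot fit an IPPP to an empty pattern")
    cells = aggregate(pattern, grid)
    X = _design(grid, subset)
    _check_rank(X, subset)
    y = cells.counts.astype(float)
    exposure = np.full(grid.n_cells, grid.cell_area)
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        y = np.where(cell_mask, y, 0.0)
        exposure = np.where(cell_mask, exposure, 0.0)
        if y.sum() == 0:
            raise DegenerateDataError("no points inside the cell mask")
    beta, mu, it = _poisson_newton(X, y, exposure)
    lam = np.exp(np.clip(X @ beta, -700, 700))
    nz = y > 0
    loglik = float(y[nz] @ np.log(lam[nz]) - mu.sum())
    fisher = X.T @ (X * mu[:, None])
    return FittedModel("ippp", tuple(subset), beta, loglik, fisher,
                       int(y.sum()), grid.n_cells, n_iter=it)


def fit_hardcore(pattern: PointPattern, grid: CovariateGrid, subset, *,
                 n_profile: int = 41, sqrt_mu: bool = False) -> FittedModel:
    """Hardcore process by maximum pseudolikelihood.

    The interaction radius is estimated by its ML value, the minimum
    pairwise distance r_hat.  Trend coefficients maximize the Berman-Turner
    discretized log pseudolikelihood in which a quadrature cell contributes
    zero conditional intensity when its center lies within r_hat of a data
    point outside that cell.  The information entry for r comes from the
    curvature of a quadratic fit to the pseudolikelihood profiled over an
    ``n_profile``-point geometric grid of radii in [r_hat/2, r_hat]; the
    hard constraint makes the profile non-smooth, so the curvature is
    floored at the prior's squared inverse width (the statement precision
    never exceeds the prior scale).

    The exponential prior mean for r is |A|/n (``sqrt_mu=True`` uses
    sqrt(|A|/n), the side of the per-point square).
    """
    if pattern.n < 2:
        raise InsufficientDataError("hardcore fit needs at least 2 points")
    r_hat = min_pairwise_distance(pattern)
    cells = aggregate(pattern, grid)
    y = cells.counts.astype(float)
    X = _design(grid, subset)
    _check_rank(X, subset)

    # distance from each cell center to the nearest point NOT in that cell
    centers = grid.cell_centers()
    pts = pattern.points
    pt_cell = (np.minimum((pts[:, 1] // grid.cell_size).astype(int),
                          grid.n_rows - 1) * grid.n_cols
               + np.minimum((pts[:, 0] // grid.cell_size).astype(int),
                            grid.n_cols - 1))
    d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    d2[np.arange(grid.n_cells)[:, None] == pt_cell[None, :]] = np.inf
    dmin_other = np.sqrt(d2.min(axis=1))

    def fit_at(r, beta0=None):
        exposure = np.where(dmin_other >= r, grid.cell_area, 0.0)
        beta, mu, it = _poisson_newton(X, y, exposure, beta0)
        lam = np.exp(np.clip(X @ beta, -700, 700))
        nz = y > 0
        logpl = float(y[nz] @ np.log(lam[nz]) - mu.sum())
        return beta, lam, mu, logpl, it

    beta, lam, mu, logpl, it = fit_at(r_hat)
    coef_fisher = X.T @ (X * mu[:, None])

    # profile curvature for the r information entry
    radii = np.geomspace(0.5 * r_hat, r_hat, n_profile)
    profile = np.empty(n_profile)
    b = beta
    for i, r in enumerate(radii[::-1]):
        b, _, _, profile[n_profile - 1 - i], _ = fit_at(r, b)
    quad = np.polyfit(radii, profile, 2)
    mu_prior = grid.width * grid.height / pattern.n
    if sqrt_mu:
        mu_prior = np.sqrt(mu_prior)
    # same prior-scale floor as the NB dispersion entry: a flat profile
    # must not shorten the message via a vanishing precision term
    r_entry = max(-2.0 * quad[0], 1.0 / mu_prior ** 2)

    fisher = block_diag(coef_fisher, [[r_entry]])
    return FittedModel("hardcore", tuple(subset), beta, logpl, fisher,
                       pattern.n, grid.n_cells, radius=float(r_hat),
                       extra_prior_mean=float(mu_prior), n_iter=it)


# -- count and occupancy families --------------------------------------------

def fit_poisson_counts(cells: CellData, grid: CovariateGrid,
                       subset) -> FittedModel:
    """Poisson GLM on per-cell counts with log link and offset ln(area)."""
    _check_cells(cells, grid)
    y = cells.counts.astype(float)
    if y.sum() == 0:
        raise DegenerateDataError("all counts are zero")
    X = _design(grid, subset)
    _check_rank(X, subset)
    exposure = np.full(grid.n_cells, grid.cell_area)
    beta, mu, it = _poisson_newton(X, y, exposure)
    loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    fisher = X.T @ (X * mu[:, None])
    return FittedModel("poisson_count", tuple(subset), beta, loglik, fisher,
                       int(y.sum()), grid.n_cells, n_iter=it)


def _nb2_loglik(y, mu, alpha):
    """NB2 log-likelihood with variance mu + alpha*mu^2 (size 1/alpha)."""
    inv = 1.0 / alpha
    return float(np.sum(gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
                        + y * np.log(alpha * mu / (1 + alpha * mu))
                        - inv * np.log1p(alpha * mu)))


def fit_negbin_counts(cells: CellData, grid: CovariateGrid, subset, *,
                      dispersion_method: str = "pearson") -> FittedModel:
    """NB2 regression on per-cell counts by maximum likelihood.

    Coefficients and the size parameter come from NB2 maximum likelihood
    (alternating Fisher scoring for the coefficients with a one
    -dimensional ML update of the size); the reported log-likelihood is
    the ML log-likelihood, as produced by standard NB GLM software.

    The *reported dispersion statistic* — the quantity that carries the
    exponential prior in the message length — is the Pearson chi-square
    over the residual degrees of freedom,

        theta_disp = sum_c (y_c - mu_c)^2 / mu_c  /  (n - p),

    a quasi-likelihood variance-inflation estimate (~1 for equidispersed
    data).  For its coding curvature it is mapped onto the NB2 size
    -inverse through the variance identity mu + alpha*mu^2 =
    theta_disp * mu taken at the mean fitted value, alpha(t) =
    (t - 1)/mean(mu) clamped at the Poisson limit.
    ``dispersion_method='pearson_plugin'`` additionally evaluates the
    reported log-likelihood at that mapped size instead of the ML size;
    ``'ml'`` reports the ML size's implied inflation 1 + alpha*mean(mu)
    as the dispersion.

    The information matrix is block diagonal: coefficients
    sum_c s_c s_c' mu_c/(1 + alpha*mu_c), plus a dispersion entry from the
    negative second finite difference of the log-likelihood in theta_disp,
    floored at the prior's squared inverse width when the curvature at
    the reported point vanishes (at the equidispersion boundary the
    mapped size clamps and the likelihood is locally flat).  The
    exponential prior mean for theta_disp is the mean of the count data.
    """
    if dispersion_method not in ("pearson", "pearson_plugin", "ml"):
        raise InvalidArgumentError(
            "dispersion_method must be pearson, pearson_plugin or ml")
    _check_cells(cells, grid)
    y = cells.counts.astype(float)
    if y.sum() == 0:
        raise DegenerateDataError("all counts are zero")
    X = _design(grid, subset)
    _check_rank(X, subset)
    exposure = np.full(grid.n_cells, grid.cell_area)

    beta, mu, it = _poisson_newton(X, y, exposure)
    alpha = _MIN_ALPHA
    for _ in range(3):
        res = minimize_scalar(
            lambda t: -_nb2_loglik(y, mu, np.exp(t)),
            bounds=(np.log(_MIN_ALPHA), np.log(1e4)), method="bounded",
            options={"xatol": 1e-8})
        alpha_new = float(np.exp(res.x))
        beta, mu = _nb_scoring(X, y, exposure, alpha_new, beta)
        if abs(np.log(alpha_new) - np.log(alpha)) < 1e-6:
            alpha = alpha_new
            break
        alpha = alpha_new

    p = len(subset) + 1
    df = grid.n_cells - p
    pearson = float(((y - mu) ** 2 / mu).sum())
    theta_disp = pearson / df
    if theta_disp <= 0:
        raise DispersionError(f"non-positive dispersion {theta_disp}")
    mean_mu = float(mu.mean())

    def alpha_of(t):
        return max((t - 1.0) / mean_mu, _MIN_ALPHA)

    alpha_rep = max(alpha, _MIN_ALPHA)
    if dispersion_method == "pearson_plugin":
        alpha_rep = alpha_of(theta_disp)
    elif dispersion_method == "ml":
        theta_disp = 1.0 + alpha_rep * mean_mu
    loglik = _nb2_loglik(y, mu, alpha_rep)

    coef_fisher = X.T @ (X * (mu / (1 + alpha_rep * mu))[:, None])
    h = 1e-4 * theta_disp
    f = [_nb2_loglik(y, mu, alpha_of(theta_disp + d)) for d in (-h, 0.0, h)]
    curv = -(f[0] - 2 * f[1] + f[2]) / h ** 2
    # when the data carry no curvature (equidispersed boundary), the
    # statement precision is bounded by the prior scale: floor at the
    # prior's squared inverse width so a useless parameter never
    # *shortens* the message through a vanishing half-log-determinant
    mu_prior = float(y.mean())
    disp_entry = max(curv, 1.0 / mu_prior ** 2)
    fisher = block_diag(coef_fisher, [[disp_entry]])
    return FittedModel("negbin_count", tuple(subset), beta, loglik, fisher,
                       int(y.sum()), grid.n_cells,
                       dispersion=float(theta_disp),
                       extra_prior_mean=float(y.mean()),
                       residual_df=df, n_iter=it, alpha=float(alpha_rep))


def _nb_scoring(X, y, exposure, alpha, beta):
    """Fisher scoring for NB2 coefficients at fixed size-inverse alpha."""
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta, -700, 700)
        mu = exposure * np.exp(eta)
        grad = X.T @ ((y - mu) / (1 + alpha * mu))
        if np.max(np.abs(grad)) <= _GRAD_TOL:
            break
        W = mu / (1 + alpha * mu)
        H = X.T @ (X * W[:, None])
        beta = beta + np.linalg.solve(H, grad)
    eta = np.clip(X @ beta, -700, 700)
    return beta, exposure * np.exp(eta)


def fit_logistic_occupancy(cells: CellData, grid: CovariateGrid,
                           subset) -> FittedModel:
    """Bernoulli ML with logit link on per-cell occupancy.

    F = sum_c s_c s_c' p_c (1 - p_c).
    """
    _check_cells(cells, grid)
    z = cells.occupancy.astype(float)
    if z.min() == z.max():
        raise DegenerateDataError("occupancy is constant (all 0 or all 1)")
    X = _design(grid, subset)
    _check_rank(X, subset)
    pbar = z.mean()
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(pbar / (1 - pbar))

    def obj(b):
        eta = X @ b
        return float(z @ eta - np.logaddexp(0.0, eta).sum())

    f = obj(beta)
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (z - p)
        if np.max(np.abs(grad)) <= _GRAD_TOL:
            break
        w = np.maximum(p * (1 - p), 1e-12)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular Hessian: separation") from exc
        t = 1.0
        for _ in range(40):
            f_new = obj(beta + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        f = f_new
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError("complete separation: diverging coefficients")
    else:
        raise ConvergenceError("logistic scoring failed to converge")
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    loglik = float(z @ np.log(p) + (1 - z) @ np.log1p(-p))
    fisher = X.T @ (X * (p * (1 - p))[:, None])
    return FittedModel("logistic_occupancy", tuple(subset), beta, loglik,
                       fisher, int(z.sum()), grid.n_cells, n_iter=it)


def _check_cells(cells: CellData, grid: CovariateGrid) -> None:
    if (cells.n_rows, cells.n_cols) != (grid.n_rows, grid.n_cols):
        raise GeometryError("cell data shape does not match grid")


_FITTERS = {
    "ippp": fit_ippp,
    "poisson_count": fit_poisson_counts,
    "negbin_count": fit_negbin_counts,
    "logistic_occupancy": fit_logistic_occupancy,
    "hardcore": fit_hardcore,
}


def fit_family(family: str, data, grid: CovariateGrid, subset,
               **kwargs) -> FittedModel:
    """Dispatch to the family's fitter; ``data`` must match its view."""
    if family not in _FITTERS:
        raise InvalidArgumentError(f"unknown family {family!r}")
    view = DATA_VIEWS[family]
    if view == "pattern" and not isinstance(data, PointPattern):
        raise InvalidArgumentError(f"{family} requires a PointPattern")
    if view in ("counts", "occupancy") and not isinstance(data, CellData):
        raise InvalidArgumentError(f"{family} requires CellData")
    return _FITTERS[family](data, grid, subset, **kwargs)
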