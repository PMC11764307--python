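"""Point-pattern simulation and aggregation.

Simulators for the generative side of the study: inhomogeneous Poisson
point processes with a piecewise-constant log-linear intensity, independent
thinning, and a hardcore process obtained by iterative random removal of
violating pairs from a Poisson parent.  Patterns aggregate to per-cell
counts and binary occupancy.

Cells are half-open squares [x0, x0+h) x [y0, y0+h), so aggregation is a
true partition of the window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .covariates import CovariateGrid
from .errors import GeometryError, InvalidArgumentError

__all__ = [
    "Window",
    "PointPattern",
    "CellData",
    "intensity_surface",
    "simulate_ippp",
    "thin",
    "simulate_hardcore",
    "aggregate",
    "read_pattern_csv",
    "write_pattern_csv",
    "read_celldata_csv",
    "write_celldata_csv",
]

_GEOM_TOL = 1e-9


@dataclass(frozen=True)
class Window:
    """Rectangular observation window [0, width) x [0, height)."""

    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise InvalidArgumentError("window sides must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class PointPattern:
    """A finite point pattern inside a rectangular window."""

    points: np.ndarray  # (n, 2)
    window: Window

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 0].max() >= self.window.width
            or pts[:, 1].min() < 0 or pts[:, 1].max() >= self.window.height
        ):
            raise InvalidArgumentError("points must lie inside the window")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class CellData:
    """Per-cell counts and occupancy on a lattice geometry."""

    n_rows: int
    n_cols: int
    cell_size: float
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (self.n_rows * self.n_cols,):
            raise InvalidArgumentError("counts must be a flat per-cell vector")
        if (counts < 0).any():
            raise InvalidArgumentError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def occupancy(self) -> np.ndarray:
        return (self.counts > 0).astype(int)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def intensity_surface(grid: CovariateGrid, subset, theta) -> np.ndarray:
    """Per-cell intensity exp(theta_1 + sum_j theta_{j+1} s_j(c)).

    ``theta`` has a leading intercept followed by one coefficient per
    feature index in ``subset``; covariates are piecewise constant per cell.
    """
    theta = np.asarray(theta, dtype=float)
    subset = list(subset)
    if theta.shape != (len(subset) + 1,):
        raise InvalidArgumentError(
            f"theta must have length {len(subset) + 1} (intercept first)")
    if not np.all(np.isfinite(theta)):
        raise InvalidArgumentError("coefficients must be finite")
    log_lam = np.full(grid.n_cells, theta[0])
    if subset:
        log_lam = log_lam + grid.values[:, subset] @ theta[1:]
    return np.exp(log_lam)


def _window_of(grid: CovariateGrid) -> Window:
    return Window(grid.width, grid.height)


def simulate_ippp(intensity, grid: CovariateGrid, seed=None) -> PointPattern:
    """Exact IPPP simulation on a gridded intensity.

    Per cell, a Poisson(lambda_c * cell_area) count is drawn and that many
    points are placed uniformly in the cell, which is exact because the
    intensity is piecewise constant.  ``seed`` may be an int or a Generator.
    """
    lam = np.asarray(intensity, dtype=float)
    if lam.shape != (grid.n_cells,):
        raise InvalidArgumentError("intensity must be per-cell")
    if not np.all(np.isfinite(lam)) or (lam < 0).any():
        raise InvalidArgumentError("intensities must be finite and >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    counts = rng.poisson(lam * grid.cell_area)
    total = int(counts.sum())
    cells = np.repeat(np.arange(grid.n_cells), counts)
    rows, cols = np.divmod(cells, grid.n_cols)
    u = rng.random((total, 2))
    x = (cols + u[:, 0]) * grid.cell_size
    y = (rows + u[:, 1]) * grid.cell_size
    return PointPattern(np.column_stack([x, y]), _window_of(grid))


def thin(pattern: PointPattern, p: float, seed=None) -> PointPattern:
    """Independent thinning: each point retained with probability ``p``.

    Thinning an IPPP with retention p yields an IPPP with intensity p*lambda.
    """
    if not 0 <= p <= 1:
        raise InvalidArgumentError("retention probability must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if p == 1:
        return pattern
    keep = rng.random(pattern.n) < p
    return PointPattern(pattern.points[keep], pattern.window)


def simulate_hardcore(intensity, grid: CovariateGrid, r: float,
                      seed=None) -> PointPattern:
    """Hardcore process by iterative removal from a Poisson parent.

    A parent IPPP is generated, then while any pair of points lies at
    distance < r the closest violating pair (ties broken lexicographically
    by point index) is found and one of its two members is deleted
    uniformly at random.  The result has minimum pairwise distance >= r;
    ``r = 0`` returns the parent unchanged (identical to
    :func:`simulate_ippp` under the same seed).
    """
    if r < 0:
        raise InvalidArgumentError("exclusion radius must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    parent = simulate_ippp(intensity, grid, rng)
    if r == 0 or parent.n < 2:
        return parent
    pts = parent.points
    alive = np.ones(len(pts), dtype=bool)
    while True:
        idx = np.flatnonzero(alive)
        if idx.size < 2:
            break
        sub = pts[idx]
        diff = sub[:, None, :] - sub[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(idx.size, k=1)
        d = dist[iu]
        violating = d < r
        if not violating.any():
            break
        # first violating pair in (distance asc, then lexicographic) order
        dv = d[violating]
        ii = iu[0][violating]
        jj = iu[1][violating]
        order = np.lexsort((jj, ii, dv))
        k = order[0]
        victim = ii[k] if rng.integers(2) == 0 else jj[k]
        alive[idx[victim]] = False
    return PointPattern(pts[alive], parent.window)


def aggregate(pattern: PointPattern, grid: CovariateGrid) -> CellData:
    """Count points per half-open grid cell; occupancy = count > 0."""
    w = pattern.window
    if (abs(w.width - grid.width) > _GEOM_TOL
            or abs(w.height - grid.height) > _GEOM_TOL):
        raise GeometryError(
            f"pattern window {w.width}x{w.height} does not match grid "
            f"extent {grid.width}x{grid.height}")
    cols = np.floor(pattern.points[:, 0] / grid.cell_size).astype(int)
    rows = np.floor(pattern.points[:, 1] / grid.cell_size).astype(int)
    cols = np.minimum(cols, grid.n_cols - 1)
    rows = np.minimum(rows, grid.n_rows - 1)
    counts = np.bincount(rows * grid.n_cols + cols, minlength=grid.n_cells)
    return CellData(grid.n_rows, grid.n_cols, grid.cell_size, counts)


def min_pairwise_distance(pattern: PointPattern) -> float:
    """Minimum inter-point distance (inf for patterns with < 2 points)."""
    if pattern.n < 2:
        return float("inf")
    return float(pdist(pattern.points).min())


# -- CSV / JSON interface ----------------------------------------------------

def write_pattern_csv(pattern: PointPattern, path, sidecar=None) -> None:
    """Write `x,y` CSV; window goes to a JSON sidecar (default `path`.json)."""
    df = pd.DataFrame(pattern.points, columns=["x", "y"])
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = sidecar or f"{path}.json"
    with open(sidecar, "w") as fh:
        json.dump({"width": pattern.window.width,
                   "height": pattern.window.height}, fh)


def read_pattern_csv(path, sidecar=None) -> PointPattern:
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = sidecar or f"{path}.json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    window = Window(meta["width"], meta["height"])
    return PointPattern(df[["x", "y"]].to_numpy(dtype=float), window)


def write_celldata_csv(cells: CellData, path) -> None:
    rows, cols = np.divmod(np.arange(cells.n_cells), cells.n_cols)
    pd.DataFrame({"row": rows, "col": cols, "count": cells.counts,
                  "occupancy": cells.occupancy}).to_csv(path, index=False)


def read_celldata_csv(path, cell_size: float = 1.0) -> CellData:
    df = pd.read_csv(path)
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    order = np.argsort(df["row"].to_numpy() * n_cols + df["col"].to_numpy())
    counts = df["count"].to_numpy()[order]
    return CellData(n_rows, n_cols, cell_size, counts)
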