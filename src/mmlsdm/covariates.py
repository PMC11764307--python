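"""Synthetic spatial covariate fields.

Gridded environmental covariates for species distribution modeling: smooth
random fields stand in for soil-chemistry maps, which are standardized and
rotated to principal-component score fields so that candidate features are
mutually uncorrelated.  Component standard deviations are retained because
log-linear intensity generators weight each component by the reciprocal of
its standard deviation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateCovariateError, InvalidArgumentError

__all__ = [
    "CovariateGrid",
    "generate_raw_fields",
    "standardize",
    "pca_components",
    "read_grid_csv",
    "write_grid_csv",
]


@dataclass(frozen=True)
class CovariateGrid:
    """Rectangular lattice of cells, each carrying a covariate vector.

    Cells are indexed row-major: cell ``i`` is at row ``i // n_cols``,
    column ``i % n_cols``.  Column index maps to the x axis, row index to
    the y axis, each cell a ``cell_size`` square.

    Attributes
    ----------
    n_rows, n_cols : int
        Lattice shape.
    cell_size : float
        Side length of a cell (dimensionless units; default 1).
    names : tuple of str
        Covariate labels, one per column of ``values``.
    values : ndarray, shape (n_cells, n_fields)
        One covariate vector per cell.
    sigmas : ndarray or None
        Per-covariate sample standard deviations recorded by
        :func:`pca_components` (``None`` otherwise).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    names: tuple
    values: np.ndarray
    sigmas: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be positive")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != self.n_rows * self.n_cols:
            raise InvalidArgumentError(
                f"values must have shape (n_cells, n_fields) with "
                f"n_cells={self.n_rows * self.n_cols}, got {vals.shape}"
            )
        if vals.shape[1] != len(self.names):
            raise InvalidArgumentError("one name per covariate required")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_fields(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center (x, y) coordinates."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = (cols + 0.5) * self.cell_size
        y = (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])


def generate_raw_fields(n_rows: int, n_cols: int, n_fields: int,
                        smoothness: float, seed: int) -> CovariateGrid:
    """Spatially autocorrelated random fields on a lattice.

    Per-cell Gaussian white noise convolved with an isotropic Gaussian
    kernel of length-scale ``smoothness`` (in cells); ``smoothness=0``
    returns the raw white noise.  Deterministic given ``seed``.
    """
    if n_rows < 1 or n_cols < 1 or n_fields < 1:
        raise InvalidArgumentError("n_rows, n_cols and n_fields must be >= 1")
    if smoothness < 0:
        raise InvalidArgumentError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_fields, n_rows, n_cols))
    if smoothness > 0:
        noise = np.stack([
            ndimage.gaussian_filter(f, sigma=smoothness, mode="reflect")
            for f in noise
        ])
    values = noise.reshape(n_fields, -1).T
    names = tuple(f"f{i + 1}" for i in range(n_fields))
    return CovariateGrid(n_rows, n_cols, 1.0, names, values)


def standardize(grid: CovariateGrid) -> CovariateGrid:
    """Rescale every covariate to sample mean 0 and variance 1 (n-1
    denominator).

    Raises
    ------
    DegenerateCovariateError
        If any covariate is constant over cells; the message names it.
    """
    vals = grid.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(grid.names[i] for i in bad)
        raise DegenerateCovariateError(
            f"constant covariate(s) cannot be standardized: {names}")
    return replace(grid, values=(vals - mean) / sd, sigmas=None)


def pca_components(grid: CovariateGrid, n_components: int) -> CovariateGrid:
    """Principal-component score fields, ordered by decreasing variance.

    Eigendecomposition of the sample covariance (n-1 denominator) of the
    covariate columns.  Each loading vector is sign-flipped so its
    largest-magnitude entry is positive, removing the eigenvector sign
    ambiguity.  The returned grid's ``sigmas`` holds each component's
    sample standard deviation, needed for 1/sigma_i intensity weights.
    """
    if n_components < 1 or n_components > grid.n_fields:
        raise InvalidArgumentError(
            f"n_components must be in [1, {grid.n_fields}], got {n_components}")
    centered = grid.values - grid.values.mean(axis=0)
    cov = centered.T @ centered / (grid.n_cells - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_components]
    loadings = eigvec[:, order]
    # sign convention: largest-|loading| entry positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = centered @ loadings
    sigmas = scores.std(axis=0, ddof=1)
    names = tuple(f"PC{i + 1}" for i in range(n_components))
    return replace(grid, names=names, values=scores, sigmas=sigmas)


# -- CSV interface -----------------------------------------------------------
# columns: row,col,<name1>,... ; 0-based indices, row-major order; floats at
# 17 significant digits so values round-trip bit-exactly.

def write_grid_csv(grid: CovariateGrid, path) -> None:
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    df = pd.DataFrame({"row": rows, "col": cols})
    for j, name in enumerate(grid.names):
        df[name] = grid.values[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_grid_csv(path, cell_size: float = 1.0) -> CovariateGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["row", "col"]:
        raise InvalidArgumentError("grid CSV must start with row,col columns")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    if len(df) != n_rows * n_cols:
        raise InvalidArgumentError("grid CSV does not cover a full lattice")
    order = np.argsort(df["row"].to_numpy() * n_cols + df["col"].to_numpy())
    names = tuple(df.columns[2:])
    values = df.iloc[order, 2:].to_numpy(dtype=float)
    return CovariateGrid(n_rows, n_cols, cell_size, names, values)
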