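"""Thin-plate-spline interpolation of station indices over a DEM.

Station index values are interpolated with a 2-D thin-plate spline in
planar map coordinates, kernel U(r) = r^2 ln r with U(0) = 0, plus an
affine trend a0 + ax*x + ay*y + az*elev in which the DEM elevation acts
as a linear covariate.  At smoothing 0 the spline interpolates the
stations exactly; positive smoothing trades station fidelity for a
flatter surface.  Rasters travel as ESRI ASCII grids (the plain-text
dialect with ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value
headers); scenario comparison is cellwise differencing, and changes are
profiled against altitude in equal-width elevation bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "StationSample",
    "TPSModel",
    "fit_tps",
    "predict_grid",
    "grid_difference",
    "sample_points",
    "altitude_profile",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class Grid:
    """A row-major raster; the first row is the northernmost."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.ncols == other.ncols and self.nrows == other.nrows
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def mask(self) -> np.ndarray:
        """True where the cell holds a legitimate value."""
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, matching values' shape."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(self.ncols, self.nrows, self.xllcorner, self.yllcorner,
                    self.cellsize, self.nodata, np.array(values, dtype=float))


@dataclass(frozen=True)
class StationSample:
    """One station observation: planar coordinates, elevation, value."""

    x: float
    y: float
    elev: float
    value: float

    def __post_init__(self):
        for v in (self.x, self.y, self.elev, self.value):
            if not np.isfinite(v):
                raise ValueError("station samples must be finite")


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 ln r, with U(0) = 0 by continuity."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r * r * np.log(r)
    return np.where(r > 0.0, u, 0.0)


@dataclass
class TPSModel:
    """Fitted thin-plate spline with a linear elevation covariate."""

    a0: float
    ax: float
    ay: float
    az: float
    weights: np.ndarray       # kernel weight per station
    station_xy: np.ndarray    # (n, 2)

    def predict(self, x, y, elev):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        elev = np.asarray(elev, dtype=float)
        trend = self.a0 + self.ax * x + self.ay * y + self.az * elev
        dx = x[..., None] - self.station_xy[:, 0]
        dy = y[..., None] - self.station_xy[:, 1]
        u = _tps_kernel(np.hypot(dx, dy))
        out = trend + u @ self.weights
        return float(out) if out.ndim == 0 else out


def fit_tps(samples: Sequence[StationSample], smoothing: float = 0.0) -> TPSModel:
    """Fit the spline to >= 4 stations.

    Solves the standard augmented TPS system: kernel matrix plus the
    side conditions that the weights are orthogonal to the trend basis
    (sum w = sum w*x = sum w*y = sum w*elev = 0).  ``smoothing`` >= 0 is
    added to the kernel diagonal; 0 gives exact interpolation.
    Duplicate or collinear station layouts make the system singular and
    raise a ValueError naming the problem.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 stations to fit the spline")
    xy = np.array([[s.x, s.y] for s in samples], dtype=float)
    z = np.array([s.elev for s in samples], dtype=float)
    v = np.array([s.value for s in samples], dtype=float)

    d = np.hypot(xy[:, 0:1] - xy[:, 0], xy[:, 1:2] - xy[:, 1])
    if np.any(d[~np.eye(n, dtype=bool)] == 0.0):
        raise ValueError("duplicate station coordinates make the spline singular")

    K = _tps_kernel(d) + smoothing * np.eye(n)
    P = np.column_stack([np.ones(n), xy[:, 0], xy[:, 1], z])
    if np.linalg.matrix_rank(P, tol=1e-8 * max(1.0, np.abs(P).max())) < 4:
        raise ValueError(
            "station layout is collinear (trend basis rank-deficient); "
            "spread stations in x, y and elevation"
        )
    m = n + 4
    A = np.zeros((m, m))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.concatenate([v, np.zeros(4)])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular spline system: {e}") from e
    w = sol[:n]
    a0, ax, ay, az = sol[n:]
    return TPSModel(float(a0), float(ax), float(ay), float(az), w, xy)


def predict_grid(model: TPSModel, dem: Grid) -> Grid:
    """Evaluate the spline at every DEM cell centre.

    The DEM supplies both the evaluation coordinates and the elevation
    covariate; nodata cells propagate to the output.
    """
    gx, gy = dem.cell_centers()
    valid = dem.mask()
    out = np.full(dem.values.shape, dem.nodata, dtype=float)
    out[valid] = model.predict(gx[valid], gy[valid], dem.values[valid])
    return dem.copy_with(out)


def grid_difference(future: Grid, current: Grid) -> Grid:
    """Cellwise future - current; nodata in either operand propagates."""
    if not future.same_geometry(current):
        raise ValueError("grid geometries do not match")
    valid = future.mask() & current.mask()
    out = np.full(future.values.shape, future.nodata, dtype=float)
    out[valid] = future.values[valid] - current.values[valid]
    return future.copy_with(out)


def sample_points(g: Grid, pts) -> list:
    """Nearest-cell values at planar points (cell-centre convention).

    A point on a cell corner is resolved by round-half-up in both axes
    (the cell to the east/north wins).  Out-of-bounds points yield None
    in the result rather than failing the whole call; nodata passes
    through as the grid's nodata value.
    """
    out = []
    for x, y in pts:
        u = (x - g.xllcorner) / g.cellsize
        vv = (y - g.yllcorner) / g.cellsize
        col = int(np.floor(u))
        row_from_bottom = int(np.floor(vv))
        if not (0 <= col < g.ncols and 0 <= row_from_bottom < g.nrows):
            out.append(None)
            continue
        row = g.nrows - 1 - row_from_bottom
        out.append(float(g.values[row, col]))
    return out


def altitude_profile(change: Grid, dem: Grid, n_bins: int) -> pd.DataFrame:
    """Mean change per equal-width elevation bin.

    Cells valid in both grids are partitioned by DEM elevation into
    ``n_bins`` equal-width bins spanning [min, max]; the result has one
    row per bin (bin_mid_alt_m, mean_change, n_cells), with NaN means
    for empty bins.
    """
    if not change.same_geometry(dem):
        raise ValueError("grid geometries do not match")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    valid = change.mask() & dem.mask()
    if not np.any(valid):
        raise ValueError("no valid cells to profile")
    elev = dem.values[valid]
    delta = change.values[valid]
    lo, hi = float(elev.min()), float(elev.max())
    if hi == lo:
        hi = lo + 1.0  # single-elevation degenerate case: one bin
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(elev, edges) - 1, 0, n_bins - 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(delta[sel].mean())
    return pd.DataFrame(
        {"bin_mid_alt_m": mids, "mean_change": means, "n_cells": counts}
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid (header keywords case-insensitive)."""
    header = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _HEADER_KEYS and len(parts) == 2 and not data_lines:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS[:5] if k not in header]
    if missing:
        raise ValueError(f"ASCII grid missing header keys: {missing}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    return Grid(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
        values=values,
    )


def write_ascii_grid(g: Grid, path, precision: int = 6) -> None:
    """Write an ESRI ASCII grid (lower-case headers, 6 significant digits)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xllcorner:.{precision}g}\n")
        fh.write(f"yllcorner {g.yllcorner:.{precision}g}\n")
        fh.write(f"cellsize {g.cellsize:.{precision}g}\n")
        fh.write(f"nodata_value {g.nodata:.{precision}g}\n")
        for row in g.values:
            fh.write(" ".join(f"{v:.{precision}g}" for v in row) + "\n")
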