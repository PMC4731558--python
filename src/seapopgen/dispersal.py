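"""Lagrangian larval dispersal on gridded velocity fields.

Virtual larvae are released from habitat cells of each locality, advected
through a time-varying 2-D velocity field (representing the surface mixed
layer in which barnacle larvae drift) with a 4th-order Runge-Kutta tracker,
and scored by the locality containing their end position after a pelagic
larval duration (PLD) drawn uniformly per particle.  Endpoint counts reduce
to a row-substochastic connectivity matrix; matrix powers give stepping-stone
multi-generation connectivity, and min-symmetrization makes the (generally
asymmetric) transport comparable with symmetric genetic distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .io import MatrixTable


class DispersalSpecError(ValueError):
    """Invalid release or locality specification (land release, overlap...)."""


Cell = tuple[int, int]  # (iy, ix)

#: connectivity matrices reuse the labeled-matrix container
ConnectivityMatrix = MatrixTable


@dataclass
class VelocityField:
    """Gridded surface velocities u,v(t,y,x) with land mask and depth.

    ``x``/``y`` are cell-centre coordinates in km, ``times`` in hours with a
    uniform step, velocities in m/s, ``depth`` in metres, and ``mask`` is
    True on land.  Velocities are zero on land cells.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        nt, ny, nx = self.u.shape
        assert self.v.shape == (nt, ny, nx)
        assert self.mask.shape == (ny, nx) and self.depth.shape == (ny, nx)
        assert len(self.x) == nx and len(self.y) == ny and len(self.times) == nt
        if nt > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0]):
                raise DispersalSpecError("field time step is not uniform")
        if np.any(self.u[:, self.mask] != 0) or np.any(self.v[:, self.mask] != 0):
            raise DispersalSpecError("nonzero velocity on land cells")

    @property
    def spacing(self) -> tuple[float, float]:
        dx = float(self.x[1] - self.x[0]) if len(self.x) > 1 else 1.0
        dy = float(self.y[1] - self.y[0]) if len(self.y) > 1 else 1.0
        return dy, dx

    def cell_of(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dy, dx = self.spacing
        ix = np.floor((xs - (self.x[0] - dx / 2)) / dx).astype(int)
        iy = np.floor((ys - (self.y[0] - dy / 2)) / dy).astype(int)
        return (
            np.clip(iy, 0, len(self.y) - 1),
            np.clip(ix, 0, len(self.x) - 1),
        )

    def is_land(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        iy, ix = self.cell_of(np.asarray(xs), np.asarray(ys))
        return self.mask[iy, ix]

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "y", "x"), self.u),
                "v": (("time", "y", "x"), self.v),
                "mask": (("y", "x"), self.mask.astype(np.int8)),
                "depth": (("y", "x"), self.depth),
            },
            coords={"time": self.times, "y": self.y, "x": self.x},
            attrs={"units_uv": "m s-1", "units_xy": "km", "units_time": "h"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityField":
        return cls(
            x=ds["x"].values.astype(float),
            y=ds["y"].values.astype(float),
            times=ds["time"].values.astype(float),
            u=ds["u"].values.astype(float),
            v=ds["v"].values.astype(float),
            mask=ds["mask"].values.astype(bool),
            depth=ds["depth"].values.astype(float),
        )

    def save(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(str(path), engine="scipy")

    @classmethod
    def load(cls, path: str | Path) -> "VelocityField":
        with xr.open_dataset(str(path), engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    # -- interpolation -----------------------------------------------------

    def _slice_interp(self, uv: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of one (ny, nx) slice at km positions."""
        dy, dx = self.spacing
        fx = np.clip((xs - self.x[0]) / dx, 0.0, len(self.x) - 1.0)
        fy = np.clip((ys - self.y[0]) / dy, 0.0, len(self.y) - 1.0)
        ix0 = np.clip(np.floor(fx).astype(int), 0, len(self.x) - 2) if len(self.x) > 1 else np.zeros_like(fx, dtype=int)
        iy0 = np.clip(np.floor(fy).astype(int), 0, len(self.y) - 2) if len(self.y) > 1 else np.zeros_like(fy, dtype=int)
        tx = fx - ix0
        ty = fy - iy0
        ix1 = np.minimum(ix0 + 1, len(self.x) - 1)
        iy1 = np.minimum(iy0 + 1, len(self.y) - 1)
        return (
            uv[iy0, ix0] * (1 - tx) * (1 - ty)
            + uv[iy0, ix1] * tx * (1 - ty)
            + uv[iy1, ix0] * (1 - tx) * ty
            + uv[iy1, ix1] * tx * ty
        )

    def velocity(self, xs: np.ndarray, ys: np.ndarray, t_hours: float) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) in km/h at positions, bilinear in space, linear in time."""
        times = self.times
        if len(times) == 1:
            k0 = k1 = 0
            w = 0.0
        else:
            step = times[1] - times[0]
            f = np.clip((t_hours - times[0]) / step, 0.0, len(times) - 1.0)
            k0 = int(np.floor(f))
            k0 = min(k0, len(times) - 2)
            k1 = k0 + 1
            w = f - k0
        u = (1 - w) * self._slice_interp(self.u[k0], xs, ys) + w * self._slice_interp(self.u[k1], xs, ys)
        v = (1 - w) * self._slice_interp(self.v[k0], xs, ys) + w * self._slice_interp(self.v[k1], xs, ys)
        return u * 3.6, v * 3.6  # m/s -> km/h


@dataclass
class ReleaseSpec:
    """Release schedule for virtual larvae.

    Defaults follow the study design: 47,040 particles per locality spread
    over 10 habitat cells, spawning June-August over 8 years, PLD uniform in
    20-30 days, 15-minute tracking step.
    """

    localities: dict[str, list[Cell]]
    particles_per_locality: int = 47040
    spawning_window: tuple[int, int] = (152, 243)  # days of year, Jun 1 - Aug 31
    years: int = 8
    pld_days: tuple[float, float] = (20.0, 30.0)
    dt_minutes: float = 15.0
    releases_per_window: int = 8
    year_length_days: float = 365.0
    #: horizontal sub-grid-scale eddy diffusivity (m^2/s); 0 = pure advection
    diffusivity: float = 0.0

    def __post_init__(self) -> None:
        if self.pld_days[0] > self.pld_days[1]:
            raise DispersalSpecError("PLD lower bound exceeds upper bound")
        if self.particles_per_locality < 1:
            raise DispersalSpecError("need at least one particle per locality")
        all_cells = [c for cells in self.localities.values() for c in cells]
        if len(all_cells) != len(set(all_cells)):
            raise DispersalSpecError("localities overlap in habitat cells")

    def release_times_hours(self) -> np.ndarray:
        """Evenly spaced release times (hours from field start) per year.

        The field's time origin is aligned with the start of the spawning
        window of the first year; successive years are ``year_length_days``
        apart (compressible for compact synthetic fields).
        """
        d0, d1 = self.spawning_window
        days = np.linspace(0.0, d1 - d0, self.releases_per_window)
        out = []
        for year in range(self.years):
            out.extend(year * self.year_length_days * 24.0 + days * 24.0)
        return np.asarray(out)


def advect(field: VelocityField, spec: ReleaseSpec, seed: int) -> pd.DataFrame:
    """Track all particles and return their release and end positions.

    Returns a DataFrame with columns ``locality, year, x0, y0, x, y, pld_days``.
    Positions are km; each particle's endpoint is its position at
    ``release_time + PLD`` with free-slip handling of land encounters.
    """
    rng = np.random.default_rng(seed)
    dy, dx = field.spacing
    for name, cells in spec.localities.items():
        for iy, ix in cells:
            if field.mask[iy, ix]:
                raise DispersalSpecError(f"locality {name} releases on land cell {(iy, ix)}")

    release_times = spec.release_times_hours()
    n_rel_per_year = spec.releases_per_window
    horizon_needed = release_times.max() + spec.pld_days[1] * 24.0
    if field.times[-1] < horizon_needed:
        raise DispersalSpecError(
            f"field spans {field.times[-1]:.0f} h but release schedule needs {horizon_needed:.0f} h"
        )

    dt_h = spec.dt_minutes / 60.0
    records: list[pd.DataFrame] = []
    for name, cells in spec.localities.items():
        n = spec.particles_per_locality
        # cycle particles over cells and release times so totals divide evenly
        cell_idx = np.arange(n) % len(cells)
        rel_idx = (np.arange(n) // len(cells)) % len(release_times)
        cy = np.array([c[0] for c in cells])[cell_idx]
        cx = np.array([c[1] for c in cells])[cell_idx]
        x0 = field.x[cx] + (rng.uniform(-0.5, 0.5, n)) * dx
        y0 = field.y[cy] + (rng.uniform(-0.5, 0.5, n)) * dy
        t_rel = release_times[rel_idx]
        pld_h = rng.uniform(spec.pld_days[0], spec.pld_days[1], n) * 24.0
        t_end = t_rel + pld_h

        xs, ys = x0.copy(), y0.copy()
        for rt in np.unique(t_rel):
            sel = t_rel == rt
            xs[sel], ys[sel] = _integrate(
                field, xs[sel], ys[sel], rt, t_end[sel], dt_h,
                diffusivity=spec.diffusivity, rng=rng,
            )
        records.append(
            pd.DataFrame(
                {
                    "locality": name,
                    "year": (rel_idx // n_rel_per_year).astype(int),
                    "x0": x0, "y0": y0, "x": xs, "y": ys,
                    "pld_days": pld_h / 24.0,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def _integrate(
    field: VelocityField,
    xs: np.ndarray,
    ys: np.ndarray,
    t0: float,
    t_end: np.ndarray,
    dt_h: float,
    diffusivity: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 advection of one release cohort up to per-particle end times.

    With a nonzero eddy diffusivity K a random-walk displacement of
    standard deviation sqrt(2 K dt) per axis is added each step
    (sub-grid-scale turbulence unresolved by the stored fields).
    """
    t = t0
    xs, ys = xs.copy(), ys.copy()
    xmin, xmax = field.x[0], field.x[-1]
    ymin, ymax = field.y[0], field.y[-1]
    # km displacement sigma per step from K in m^2/s and dt in hours
    sigma = math.sqrt(2.0 * diffusivity * dt_h * 3600.0) / 1000.0 if diffusivity > 0 else 0.0
    while True:
        active = t_end > t + 1e-9
        if not active.any():
            break
        step = np.minimum(dt_h, t_end[active] - t)
        ax, ay = xs[active], ys[active]
        k1x, k1y = field.velocity(ax, ay, t)
        k2x, k2y = field.velocity(ax + 0.5 * step * k1x, ay + 0.5 * step * k1y, t + dt_h / 2)
        k3x, k3y = field.velocity(ax + 0.5 * step * k2x, ay + 0.5 * step * k2y, t + dt_h / 2)
        k4x, k4y = field.velocity(ax + step * k3x, ay + step * k3y, t + dt_h)
        nx_ = ax + step / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        ny_ = ay + step / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        if sigma > 0 and rng is not None:
            frac = np.sqrt(step / dt_h)
            nx_ = nx_ + sigma * frac * rng.standard_normal(len(ax))
            ny_ = ny_ + sigma * frac * rng.standard_normal(len(ay))
        nx_ = np.clip(nx_, xmin, xmax)
        ny_ = np.clip(ny_, ymin, ymax)
        # free-slip land handling: full step, else slide along one axis
        on_land = field.is_land(nx_, ny_)
        if on_land.any():
            slide_x = field.is_land(nx_, ay)  # keep old y
            keep_x = np.where(slide_x, ax, nx_)
            nx_ = np.where(on_land, keep_x, nx_)
            still = field.is_land(nx_, ny_)
            ny_ = np.where(still & on_land, ay, ny_)
        xs[active], ys[active] = nx_, ny_
        t += dt_h
    return xs, ys


def connectivity(
    endpoints: pd.DataFrame,
    localities: dict[str, list[Cell]],
    field: VelocityField,
    depth_cutoff: float = 100.0,
    per_year: bool = True,
) -> MatrixTable:
    """Reduce endpoints to a row-substochastic connectivity matrix.

    ``C[i, j]`` is the fraction of particles released at locality ``i`` whose
    end position falls in a habitat cell of locality ``j`` (diagonal =
    self-recruitment); particles ending elsewhere are lost.  Locality cells
    must be disjoint and no deeper than ``depth_cutoff`` metres.  With
    ``per_year`` the matrix is computed per release year and averaged.
    """
    names = list(localities)
    all_cells: set[Cell] = set()
    for name, cells in localities.items():
        for c in cells:
            if c in all_cells:
                raise DispersalSpecError(f"cell {c} belongs to two localities")
            all_cells.add(c)
            if field.depth[c] > depth_cutoff:
                raise DispersalSpecError(
                    f"locality {name} cell {c} deeper than {depth_cutoff} m"
                )
    cell_to_loc = {c: k for k, name in enumerate(names) for c in localities[name]}

    def one_matrix(df: pd.DataFrame) -> np.ndarray:
        C = np.zeros((len(names), len(names)))
        iy, ix = field.cell_of(df["x"].to_numpy(), df["y"].to_numpy())
        dest = np.array(
            [cell_to_loc.get((a, b), -1) for a, b in zip(iy, ix)], dtype=int
        )
        src = np.array([names.index(l) for l in df["locality"]], dtype=int)
        for i in range(len(names)):
            sel = src == i
            n_i = sel.sum()
            if n_i == 0:
                continue
            for j in range(len(names)):
                C[i, j] = np.sum(dest[sel] == j) / n_i
        return C

    if per_year and "year" in endpoints and endpoints["year"].nunique() > 1:
        mats = [one_matrix(df) for _, df in endpoints.groupby("year")]
        C = np.mean(mats, axis=0)
    else:
        C = one_matrix(endpoints)
    return MatrixTable(labels=names, values=C)


def multigeneration(C: MatrixTable, generations: int) -> MatrixTable:
    """Stepping-stone connectivity over ``generations`` dispersal events.

    The matrix power sums the transfer probability over every possible
    G-step route between two localities.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    M = np.asarray(C.values)
    if np.any(M < 0) or np.any(M > 1) or np.any(M.sum(axis=1) > 1 + 1e-9):
        raise ValueError("connectivity matrix must be row-substochastic in [0,1]")
    return MatrixTable(labels=list(C.labels), values=np.linalg.matrix_power(M, generations))


def symmetrize_min(M: MatrixTable) -> MatrixTable:
    """Elementwise minimum of M and its transpose; diagonal preserved."""
    V = np.asarray(M.values)
    S = np.minimum(V, V.T)
    np.fill_diagonal(S, np.diag(V))
    return MatrixTable(labels=list(M.labels), values=S, symmetric=True)
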