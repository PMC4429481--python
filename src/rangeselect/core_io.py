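"""Domain types, reference grids, utilization-distribution transforms and I/O.

Everything downstream of this module works in a projected planar CRS with
coordinates in meters and time in seconds since the Unix epoch.  A
:class:`Trajectory` holds one animal's time-ordered relocations; a
:class:`ReferenceGrid` is the fixed-grain raster every estimator of that
animal shares, so that AUC comparisons across estimators are made on an
identical grain and extent; a :class:`UtilizationDistribution` is a
normalized per-cell probability surface whose volume contours define the
home-range isopleths.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

logger = logging.getLogger("rangeselect")

#: GPS duty-cycle classes and the VHF class used throughout the package.
SCHEDULE_CLASSES = ("hourly", "four", "seven", "vhf")

#: Nominal fix interval in seconds for each GPS schedule class.
SCHEDULE_INTERVAL_S = {"hourly": 3600.0, "four": 14400.0, "seven": 25200.0}

GPS = "GPS"
VHF = "VHF"

#: Default reference-grid grain (m); home ranges are rasterized at 100 x 100 m.
DEFAULT_GRAIN = 100.0

#: Default grid buffer = 3 grains per side, so kernel mass loss off-grid is
#: negligible at this grain.
DEFAULT_BUFFER_GRAINS = 3.0

#: Warn when more than this fraction of kernel mass falls off-grid.
OFFGRID_MASS_TOL = 1e-3


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction needs non-collinear points."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """One animal's time-ordered relocations.

    Parameters
    ----------
    animal_id
        Identifier of the animal.
    t
        Fix times, seconds since epoch, strictly increasing.
    x, y
        Projected planar coordinates in meters.
    err_sd
        Optional per-fix location-error SD in meters (e.g. 34 m for GPS,
        124 m for aerial VHF).
    schedule_class
        One of ``hourly``/``four``/``seven``/``vhf``.
    technology
        ``"GPS"`` or ``"VHF"``.
    """

    animal_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    err_sd: np.ndarray | None = None
    schedule_class: str = "hourly"
    technology: str = GPS

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 1:
            raise ValueError("trajectory needs at least one fix")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"timestamps of animal {self.animal_id!r} not strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.err_sd is not None:
            self.err_sd = np.asarray(self.err_sd, dtype=float)
            if self.err_sd.size != self.t.size:
                raise ValueError("err_sd must match number of fixes")
            if np.any(self.err_sd < 0):
                raise ValueError("err_sd must be >= 0")
        if self.schedule_class not in SCHEDULE_CLASSES:
            raise ValueError(f"unknown schedule_class {self.schedule_class!r}")
        if self.technology not in (GPS, VHF):
            raise ValueError(f"technology must be GPS or VHF, got {self.technology!r}")

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])

    def error_sd_or(self, default: float) -> np.ndarray:
        """Per-fix error SD, filling missing values with *default*."""
        if self.err_sd is None:
            return np.full(self.n, float(default))
        return self.err_sd


@dataclass(frozen=True)
class ReferenceGrid:
    """Fixed-grain raster extent shared by all estimators of one animal.

    ``(x0, y0)`` is the lower-left corner; cell (row, col) spans
    ``[x0 + col*g, x0 + (col+1)*g) x [y0 + row*g, y0 + (row+1)*g)``
    (half-open, so every in-extent point falls in exactly one cell; points
    exactly on the max edge belong to the last cell). Row 0 is the bottom row.
    """

    x0: float
    y0: float
    grain: float
    ncols: int
    nrows: int

    def __post_init__(self):
        if self.grain <= 0:
            raise ValueError("grain must be > 0")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        return self.grain * self.grain

    @property
    def xmax(self) -> float:
        return self.x0 + self.ncols * self.grain

    @property
    def ymax(self) -> float:
        return self.y0 + self.nrows * self.grain

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (shape nrows x ncols) of cell-center coordinates."""
        cx = self.x0 + (np.arange(self.ncols) + 0.5) * self.grain
        cy = self.y0 + (np.arange(self.nrows) + 0.5) * self.grain
        return np.meshgrid(cx, cy)


@dataclass
class CellScoreField:
    """Per-cell real scores on a reference grid (higher = more intense use)."""

    grid: ReferenceGrid
    score: np.ndarray
    estimator_tag: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != self.grid.shape:
            raise ValueError(
                f"score shape {self.score.shape} != grid shape {self.grid.shape}"
            )
        if np.any(np.isnan(self.score)):
            raise ValueError("scores must not be NaN")


class UtilizationDistribution(CellScoreField):
    """A CellScoreField whose scores are probability mass per cell (sum 1)."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.score < 0) or not np.all(np.isfinite(self.score)):
            raise ValueError("UD masses must be finite and >= 0")
        total = float(self.score.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"UD masses must sum to 1, got {total}")


@dataclass
class IsoplethSet:
    """Nested volume-contour polygons at percent levels.

    ``entries`` is a list of ``(level, region, area_m2)`` with levels strictly
    increasing and regions nested.
    """

    entries: list

    def __post_init__(self):
        levels = [e[0] for e in self.entries]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("isopleth levels must be strictly increasing")

    @property
    def levels(self) -> list[float]:
        return [e[0] for e in self.entries]


# ---------------------------------------------------------------------------
# Readers and dataset filters
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "err_sd": "err_sd",
}


def read_trajectories(path, dialect: dict | None = None) -> list[Trajectory]:
    """Read delimited relocations into one Trajectory per animal.

    The file must have an animal id, an ISO-8601 timestamp and planar x/y in
    a projected meter CRS; a per-fix error-SD column is optional.  *dialect*
    maps the canonical names (``animal_id``/``timestamp``/``x``/``y``/
    ``err_sd``) to the file's column names.  Rows are sorted by time within
    animal; duplicate timestamps within an animal are rejected.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    for key in ("animal_id", "timestamp", "x", "y"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column {cols[key]!r}")
    x = df[cols["x"]].to_numpy(dtype=float)
    y = df[cols["y"]].to_numpy(dtype=float)
    if len(df) and np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        warnings.warn(
            "coordinates look geographic (|x|<=180, |y|<=90 for all rows); "
            "a projected planar CRS in meters is required",
            UserWarning,
            stacklevel=2,
        )
    ts = pd.to_datetime(df[cols["timestamp"]], utc=True, format="ISO8601")
    df = df.assign(
        _t=ts.astype("int64") / 1e9, _x=x, _y=y, _id=df[cols["animal_id"]].astype(str)
    )
    has_err = cols.get("err_sd") in df.columns
    out = []
    for animal, sub in df.groupby("_id", sort=True):
        sub = sub.sort_values("_t", kind="mergesort")
        tvals = sub["_t"].to_numpy()
        dup = np.flatnonzero(np.diff(tvals) == 0)
        if dup.size:
            row = sub.index[dup[0] + 1]
            raise ValueError(
                f"duplicate timestamp for animal {animal!r} at input row {row}"
            )
        err = sub[cols["err_sd"]].to_numpy(dtype=float) if has_err else None
        sched = _guess_schedule(tvals)
        out.append(
            Trajectory(
                animal_id=animal,
                t=tvals,
                x=sub["_x"].to_numpy(),
                y=sub["_y"].to_numpy(),
                err_sd=err,
                schedule_class=sched,
            )
        )
    return out


def _guess_schedule(t: np.ndarray) -> str:
    """Classify a fix series by its median interval (h<=1.5 hourly, <=4.5 four,
    <=14h seven, else vhf)."""
    if t.size < 2:
        return "hourly"
    med = float(np.median(np.diff(t)))
    if med <= 1.5 * 3600:
        return "hourly"
    if med <= 4.5 * 3600:
        return "four"
    if med <= 14.0 * 3600:
        return "seven"
    return "vhf"


def filter_min_annual(traj: Trajectory, threshold: int = 50) -> list[Trajectory]:
    """Split a trajectory by calendar year, keeping years with > *threshold* fixes.

    The annual home-range criterion is strict: a year with exactly *threshold*
    locations is dropped.  Calendar years run 1 January to 31 December (UTC).
    Returns one Trajectory per retained year.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if traj.n == 0:
        return []
    years = pd.to_datetime(traj.t, unit="s", utc=True).year.to_numpy()
    out = []
    for year in np.unique(years):
        mask = years == year
        if int(mask.sum()) > threshold:
            out.append(
                Trajectory(
                    animal_id=traj.animal_id,
                    t=traj.t[mask],
                    x=traj.x[mask],
                    y=traj.y[mask],
                    err_sd=None if traj.err_sd is None else traj.err_sd[mask],
                    schedule_class=traj.schedule_class,
                    technology=traj.technology,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reference-grid construction and cell lookup
# ---------------------------------------------------------------------------


def build_reference_grid(
    traj: Trajectory, grain: float = DEFAULT_GRAIN, buffer: float | None = None
) -> ReferenceGrid:
    """Build the fixed-grain grid around a trajectory.

    The lower-left corner is ``(min - buffer)`` snapped *down* to a multiple of
    the grain (deterministic extent), and the column/row counts are the
    smallest covering ``(max + buffer)``.  Buffer defaults to 3 grains per
    side.  The same grid is reused for every estimator of the same animal.
    """
    if grain <= 0:
        raise ValueError("grain must be > 0")
    if buffer is None:
        buffer = DEFAULT_BUFFER_GRAINS * grain
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    x0 = math.floor((traj.x.min() - buffer) / grain) * grain
    y0 = math.floor((traj.y.min() - buffer) / grain) * grain
    ncols = max(1, math.ceil((traj.x.max() + buffer - x0) / grain))
    nrows = max(1, math.ceil((traj.y.max() + buffer - y0) / grain))
    return ReferenceGrid(x0=x0, y0=y0, grain=grain, ncols=ncols, nrows=nrows)


def point_to_cell(grid: ReferenceGrid, x: float, y: float):
    """Map a point to its (row, col) under the half-open cell convention.

    Returns ``None`` for points outside the grid extent; points exactly on the
    max edge are assigned to the last cell.
    """
    g = grid.grain
    col = math.floor((x - grid.x0) / g)
    row = math.floor((y - grid.y0) / g)
    if x == grid.xmax:
        col = grid.ncols - 1
    if y == grid.ymax:
        row = grid.nrows - 1
    if 0 <= col < grid.ncols and 0 <= row < grid.nrows:
        return (row, col)
    return None


def points_to_cells(grid: ReferenceGrid, x: np.ndarray, y: np.ndarray):
    """Vectorized point_to_cell: returns (rows, cols, inside_mask)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - grid.x0) / grid.grain).astype(int)
    row = np.floor((y - grid.y0) / grid.grain).astype(int)
    col[x == grid.xmax] = grid.ncols - 1
    row[y == grid.ymax] = grid.nrows - 1
    inside = (col >= 0) & (col < grid.ncols) & (row >= 0) & (row < grid.nrows)
    return row, col, inside


# ---------------------------------------------------------------------------
# UD transforms: normalization, volume contours, isopleths
# ---------------------------------------------------------------------------


def normalize_to_ud(field: CellScoreField) -> UtilizationDistribution:
    """Normalize a nonnegative score field to a utilization distribution."""
    score = np.asarray(field.score, dtype=float)
    if np.any(score < 0):
        raise ValueError("cannot normalize a field with negative scores")
    total = score.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cannot normalize an all-zero score field")
    return UtilizationDistribution(
        grid=field.grid,
        score=score / total,
        estimator_tag=field.estimator_tag,
        params=dict(field.params),
    )


def volume_contour_levels(ud: UtilizationDistribution) -> CellScoreField:
    """Per-cell volume-contour level in percent.

    A cell's level is 100 x (total mass of all cells with mass >= this
    cell's mass); cells with tied mass are grouped before accumulating, so
    ties share a single level.  Low levels mark the UD core: the L% isopleth
    is the set of cells with level <= L.
    """
    mass = ud.score.ravel()
    order = np.argsort(-mass, kind="mergesort")
    sorted_mass = mass[order]
    csum = np.cumsum(sorted_mass)
    # assign each tie group the cumulative mass at the *end* of the group
    levels_sorted = np.empty_like(sorted_mass)
    i = 0
    n = sorted_mass.size
    while i < n:
        j = i
        while j + 1 < n and sorted_mass[j + 1] == sorted_mass[i]:
            j += 1
        levels_sorted[i : j + 1] = csum[j]
        i = j + 1
    levels = np.empty_like(mass)
    levels[order] = 100.0 * levels_sorted
    return CellScoreField(
        grid=ud.grid,
        score=levels.reshape(ud.grid.shape),
        estimator_tag=ud.estimator_tag,
        params={"transform": "volume_contour_levels", **ud.params},
    )


def extract_isopleths(ud: UtilizationDistribution, levels) -> IsoplethSet:
    """Extract nested isopleth polygons at the given percent levels.

    The region at level L is the union of positive-mass cells whose
    volume-contour level is <= L, polygonized along cell edges; its area is
    the cell count times the cell area.
    """
    levels = sorted(float(v) for v in levels)
    for lv in levels:
        if not (0.0 < lv <= 100.0):
            raise ValueError(f"isopleth level {lv} outside (0, 100]")
    vcl = volume_contour_levels(ud).score
    positive = ud.score > 0
    g = ud.grid
    entries = []
    for lv in levels:
        mask = positive & (vcl <= lv + 1e-9)
        rows, cols = np.nonzero(mask)
        cells = [
            box(
                g.x0 + c * g.grain,
                g.y0 + r * g.grain,
                g.x0 + (c + 1) * g.grain,
                g.y0 + (r + 1) * g.grain,
            )
            for r, c in zip(rows, cols)
        ]
        region = unary_union(cells) if cells else shapely.Polygon()
        entries.append((lv, region, float(rows.size) * g.cell_area))
    return IsoplethSet(entries=entries)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_field_ascii(field: CellScoreField, path) -> None:
    """Write a score field as an ESRI ASCII grid (text raster)."""
    g = field.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {float(g.x0)!r}\n")
        fh.write(f"yllcorner {float(g.y0)!r}\n")
        fh.write(f"cellsize {float(g.grain)!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in field.score[::-1]:  # ASCII grids store the top row first
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_field_ascii(path) -> CellScoreField:
    """Read an ESRI ASCII grid written by :func:`write_field_ascii`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    grid = ReferenceGrid(
        x0=float(header["xllcorner"]),
        y0=float(header["yllcorner"]),
        grain=float(header["cellsize"]),
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    return CellScoreField(grid=grid, score=data)


def write_isopleths_geojson(isoset: IsoplethSet, path) -> None:
    """Write isopleths as a GeoJSON FeatureCollection with a level attribute."""
    features = []
    for level, region, area in isoset.entries:
        features.append(
            {
                "type": "Feature",
                "properties": {"level": level, "area_m2": area},
                "geometry": mapping(region),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_table_csv(df: pd.DataFrame, path, columns=None) -> None:
    """Write a results table as CSV with a declared column order."""
    if columns is not None:
        df = df.loc[:, list(columns)]
    df.to_csv(path, index=False)
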