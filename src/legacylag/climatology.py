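"""Sliding-window climatologies and the joint climate PCA.

Historical climate enters the models as decadal means ("climatologies")
of each monthly variable, computed over 10-year windows that overlap by
5 years, plus a 1-year contemporary climatology from the collection
year. A single PCA is fitted jointly over all (location, window)
observations; the projections onto the first three components are the
"climate variables" that compete during model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import (IncompleteCoverageError, OutOfExtentError,
                         ZeroVarianceError)
from .synthetic import RESOLUTION

#: Final years of the default decadal windows.
DEFAULT_WINDOW_ENDS = (2009, 2004, 1999, 1994, 1989, 1984, 1979, 1974,
                       1969, 1964, 1959)

CONTEMPORARY_ID = "contemporary"


@dataclass(frozen=True)
class Window:
    id: str
    start: pd.Timestamp
    end: pd.Timestamp
    contemporary: bool = False

    @property
    def n_months(self) -> int:
        return ((self.end.year - self.start.year) * 12
                + self.end.month - self.start.month + 1)

    @property
    def start_year(self) -> int:
        return int(self.start.year)


@dataclass(frozen=True)
class WindowSchedule:
    """An ordered set of climatology windows, oldest first, the 1-year
    contemporary window last."""

    windows: tuple[Window, ...]
    length_months: int = 120

    def __post_init__(self) -> None:
        ids = [w.id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate window ids")
        for w in self.windows:
            expected = 12 if w.contemporary else self.length_months
            if w.n_months != expected:
                raise ValueError(
                    f"window {w.id!r} spans {w.n_months} months, "
                    f"expected {expected}")

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    @property
    def historical_ids(self) -> list[str]:
        return [w.id for w in self.windows if not w.contemporary]

    @property
    def contemporary_id(self) -> str:
        for w in self.windows:
            if w.contemporary:
                return w.id
        raise ValueError("schedule has no contemporary window")

    @property
    def most_recent_historical_id(self) -> str:
        hist = [w for w in self.windows if not w.contemporary]
        return max(hist, key=lambda w: w.end).id

    def window(self, window_id: str) -> Window:
        for w in self.windows:
            if w.id == window_id:
                return w
        raise KeyError(window_id)


def default_window_schedule(collection_year: int = 2011,
                            window_ends: tuple[int, ...] = DEFAULT_WINDOW_ENDS,
                            length_months: int = 120) -> WindowSchedule:
    """The default schedule: decadal windows ending Dec 31 of
    2009, 2004, ..., 1959 (oldest first in the result) plus the 1-year
    contemporary window covering the collection year.

    ``length_months`` = 240 gives the 20-year variant over the same end
    years.
    """
    years = length_months // 12
    hist = []
    for end_year in sorted(window_ends):
        start_year = end_year - years + 1
        hist.append(Window(
            id=f"{start_year}-{end_year}",
            start=pd.Timestamp(f"{start_year}-01-01"),
            end=pd.Timestamp(f"{end_year}-12-31"),
        ))
    contemporary = Window(
        id=CONTEMPORARY_ID,
        start=pd.Timestamp(f"{collection_year}-01-01"),
        end=pd.Timestamp(f"{collection_year}-12-31"),
        contemporary=True,
    )
    return WindowSchedule(tuple(hist) + (contemporary,),
                          length_months=length_months)


def _nearest_index(centers: np.ndarray, value: float) -> int:
    # ties broken toward the lower index (np.argmin keeps the first min)
    return int(np.argmin(np.abs(centers - value)))


def _check_extent(centers: np.ndarray, value: float, axis: str) -> None:
    if value < centers[0] - RESOLUTION / 2 or value > centers[-1] + RESOLUTION / 2:
        raise OutOfExtentError(
            f"{axis}={value} outside grid extent "
            f"[{centers[0] - RESOLUTION / 2}, {centers[-1] + RESOLUTION / 2}]")


def extract_at_locations(grid: xr.Dataset,
                         designs: pd.DataFrame) -> pd.DataFrame:
    """Extract the monthly series of the 0.5-degree cell nearest each
    sampling location.

    One series per *location* (site): replicate plots of a site share a
    cell, so the site is the climatic unit. Returns a DataFrame indexed
    by (location, time) with one column per climate variable.
    """
    lats = np.asarray(grid["lat"].values)
    lons = np.asarray(grid["lon"].values)
    variables = list(grid.data_vars)

    site_cell: dict[str, tuple[int, int]] = {}
    for sample_id, row in designs.iterrows():
        _check_extent(lats, row["lat"], "lat")
        _check_extent(lons, row["lon"], "lon")
        cell = (_nearest_index(lats, row["lat"]),
                _nearest_index(lons, row["lon"]))
        prev = site_cell.setdefault(row["site_id"], cell)
        if prev != cell:
            raise ValueError(
                f"plots of site {row['site_id']!r} map to different grid "
                f"cells {prev} and {cell}")

    time = pd.DatetimeIndex(grid["time"].values)
    frames = []
    for site_id, (i, j) in site_cell.items():
        data = {v: np.asarray(grid[v].values)[:, i, j] for v in variables}
        frame = pd.DataFrame(data, index=time)
        frame.insert(0, "location", site_id)
        frames.append(frame)
    out = pd.concat(frames)
    out.index.name = "time"
    out = out.set_index("location", append=True).reorder_levels(
        ["location", "time"]).sort_index()
    return out


def cells_to_series(grid: xr.Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treat every grid cell as a location (for map projection).

    Returns (series, cells) where ``series`` has the same layout as
    :func:`extract_at_locations` and ``cells`` maps location id ->
    (lat, lon, ilat, ilon).
    """
    lats = np.asarray(grid["lat"].values)
    lons = np.asarray(grid["lon"].values)
    variables = list(grid.data_vars)
    time = pd.DatetimeIndex(grid["time"].values)

    frames = []
    cell_rows = []
    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            loc = f"cell_{i:03d}_{j:03d}"
            data = {v: np.asarray(grid[v].values)[:, i, j] for v in variables}
            frame = pd.DataFrame(data, index=time)
            frame.insert(0, "location", loc)
            frames.append(frame)
            cell_rows.append({"location": loc, "lat": float(lat),
                              "lon": float(lon), "ilat": i, "ilon": j})
    series = pd.concat(frames)
    series.index.name = "time"
    series = series.set_index("location", append=True).reorder_levels(
        ["location", "time"]).sort_index()
    cells = pd.DataFrame(cell_rows).set_index("location")
    return series, cells


def window_climatology(series: pd.DataFrame,
                       schedule: WindowSchedule) -> pd.DataFrame:
    """Average each location's monthly values over every scheduled window.

    Returns a DataFrame indexed by (location, window) with one column per
    climate variable. A window month missing for any location raises
    :class:`IncompleteCoverageError` — no silent imputation.
    """
    variables = list(series.columns)
    locations = series.index.get_level_values("location").unique()
    times = series.index.get_level_values("time")

    rows = []
    index = []
    for loc in locations:
        sub = series.xs(loc, level="location")
        if sub.isna().any().any():
            raise IncompleteCoverageError(
                f"missing monthly values at location {loc!r}")
        for w in schedule:
            mask = (sub.index >= w.start) & (sub.index <= w.end)
            n = int(mask.sum())
            if n != w.n_months:
                raise IncompleteCoverageError(
                    f"window {w.id!r} at location {loc!r}: {n} of "
                    f"{w.n_months} months covered")
            rows.append(sub.loc[mask].mean().to_numpy())
            index.append((loc, w.id))
    out = pd.DataFrame(
        rows, columns=variables,
        index=pd.MultiIndex.from_tuples(index, names=["location", "window"]))
    return out


@dataclass
class ClimatePCModel:
    """Centering/scaling + loadings of the joint climate PCA.

    Fitted over all (location, window) observations jointly; scaling uses
    the sample standard deviation (n-1). The sign of each loading vector
    is fixed so its largest-magnitude entry is positive, keeping PC
    labels stable across runs.
    """

    variables: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # (n_variables, n_variables), columns = PCs
    variance_fractions: np.ndarray
    n_components: int = 3

    @property
    def component_names(self) -> list[str]:
        return [f"PC{k + 1}" for k in range(self.n_components)]

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        """Project rows of 10 climate variables onto the retained PCs."""
        missing = set(self.variables) - set(values.columns)
        if missing:
            raise ValueError(f"missing climate variables: {sorted(missing)}")
        x = values[self.variables].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        scores = z @ self.loadings[:, :self.n_components]
        return pd.DataFrame(scores, index=values.index,
                            columns=self.component_names)

    def to_json(self) -> str:
        return json.dumps({
            "variables": self.variables,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_components": self.n_components,
        })

    @classmethod
    def from_json(cls, text: str) -> "ClimatePCModel":
        d = json.loads(text)
        return cls(variables=list(d["variables"]),
                   center=np.asarray(d["center"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   loadings=np.asarray(d["loadings"], dtype=float),
                   variance_fractions=np.asarray(d["variance_fractions"],
                                                 dtype=float),
                   n_components=int(d["n_components"]))


def fit_climate_pca(table: pd.DataFrame, n_components: int = 3,
                    ) -> tuple[ClimatePCModel, pd.DataFrame]:
    """Fit the joint PCA over every (location, window) observation.

    Returns the model and the score table (same index as ``table``,
    columns PC1..PCk). Variance fractions are reported for *all*
    components and sum to 1.
    """
    x = table.to_numpy(dtype=float)
    n_obs, n_var = x.shape
    if n_obs < n_components + 1:
        raise ValueError("need at least n_components + 1 observations")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [c for c, s in zip(table.columns, scale) if s == 0]
        raise ZeroVarianceError(f"constant climate variable(s): {bad}")
    z = (x - center) / scale
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    # sign convention: largest-magnitude loading of each component positive
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    variance_fractions = s ** 2 / np.sum(s ** 2)
    model = ClimatePCModel(variables=list(table.columns), center=center,
                           scale=scale, loadings=loadings,
                           variance_fractions=variance_fractions,
                           n_components=n_components)
    scores = model.transform(table)
    return model, scores


def project_onto_pcs(values: pd.DataFrame | pd.Series,
                     model: ClimatePCModel) -> pd.DataFrame:
    """Project new climate-variable vectors onto the fitted components."""
    if isinstance(values, pd.Series):
        values = values.to_frame().T
    return model.transform(values)
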