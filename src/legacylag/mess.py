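"""Geographic projection with MESS extrapolation screening.

Fitted models are evaluated over the full climate grid to map current
and post-equilibration responses. The Multivariate Environmental
Similarity Surface (MESS) quantifies, per cell, how far the cell's
predictor values fall outside the range observed at the training
locations: negative values mean extrapolation, with e.g. -20 meaning
20% of the reference range beyond the observed extreme on the worst
variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .climatology import ClimatePCModel, WindowSchedule, cells_to_series, \
    window_climatology
from .community import inverse_transform
from .equilibration import predict_current, predict_equilibrium
from .exceptions import ZeroVarianceError
from .selection import CandidatePool, SelectedModel, _pool_from_table

DEFAULT_MESS_THRESHOLD = -20.0


@dataclass
class MessSurface:
    """Per-query-point MESS values and their per-variable breakdown."""

    similarities: pd.DataFrame     # (query points x variables)
    mess: pd.Series                # min over variables
    worst_variable: pd.Series      # variable attaining the minimum


def mess(reference: pd.DataFrame | np.ndarray,
         query: pd.DataFrame | np.ndarray,
         variables: list[str] | None = None) -> MessSurface:
    """Multivariate environmental similarity of query points to a
    reference (training) set.

    Per variable, with f = percent of reference values strictly below
    the query value (ties count as not-below) and [min, max] the
    reference range::

        f = 0        ->  100 * (q - min) / (max - min)
        0 < f <= 50  ->  2 * f
        50 < f < 100 ->  2 * (100 - f)
        f = 100      ->  100 * (max - q) / (max - min)

    The MESS value is the minimum over variables; it is positive exactly
    when the point is inside the reference range on every variable and
    100 only at a multivariate median point.
    """
    ref = pd.DataFrame(reference) if not isinstance(reference, pd.DataFrame) \
        else reference
    qry = pd.DataFrame(query) if not isinstance(query, pd.DataFrame) \
        else query
    if variables is not None:
        ref = ref[variables]
        qry = qry[variables]
    if list(ref.columns) != list(qry.columns):
        raise ValueError("reference and query must share predictor columns")

    sims = np.empty((len(qry), ref.shape[1]))
    for k, col in enumerate(ref.columns):
        r = np.sort(ref[col].to_numpy(dtype=float))
        lo, hi = r[0], r[-1]
        if hi == lo:
            raise ZeroVarianceError(f"constant reference column {col!r}")
        q = qry[col].to_numpy(dtype=float)
        f = 100.0 * np.searchsorted(r, q, side="left") / len(r)
        sim = np.where(
            f == 0, 100.0 * (q - lo) / (hi - lo),
            np.where(f <= 50, 2.0 * f,
                     np.where(f < 100, 2.0 * (100.0 - f),
                              100.0 * (hi - q) / (hi - lo))))
        sims[:, k] = sim
    similarities = pd.DataFrame(sims, index=qry.index, columns=ref.columns)
    mess_values = similarities.min(axis=1)
    worst = similarities.idxmin(axis=1)
    return MessSurface(similarities=similarities, mess=mess_values,
                       worst_variable=worst)


def _model_design(model: SelectedModel, pool: CandidatePool,
                  recent_window: str | None,
                  mode: str) -> pd.DataFrame:
    """Predictor values (one column per model term) at every pool sample."""
    cols = {}
    for cand in model.predictors:
        window = cand.window
        if mode == "equilibrium" and window != pool.contemporary_id:
            window = recent_window
        cols[cand.label] = pool.X[:, pool.column(cand.feature, window)]
    return pd.DataFrame(cols, index=pool.sample_ids)


@dataclass
class PredictionSurface:
    """Gridded current/equilibrium predictions with optional MESS layers.

    ``data`` is an xarray.Dataset on (lat, lon) with variables
    ``current``, ``equilibrium``, ``difference`` and, when screened,
    ``mess`` and ``extrapolated``.
    """

    data: xr.Dataset
    cells: pd.DataFrame   # location id -> lat/lon/ilat/ilon


def project_map(model: SelectedModel, grid: xr.Dataset,
                schedule: WindowSchedule, pc_model: ClimatePCModel,
                transform_kind: str,
                recent_window: str | None = None,
                training_pool: CandidatePool | None = None,
                mess_threshold: float | None = None) -> PredictionSurface:
    """Evaluate a fitted model over every grid cell.

    Computes per-cell climatologies for every scheduled window, projects
    them through the stored PC model, evaluates the model in current and
    equilibrium modes and back-transforms. When ``training_pool`` is
    given, a MESS layer is computed against the training locations'
    predictor values, and ``mess_threshold`` additionally flags
    extrapolated cells (values are retained, only marked).
    """
    series, cells = cells_to_series(grid)
    clim = window_climatology(series, schedule)
    scores = pc_model.transform(clim)

    designs = pd.DataFrame({"site_id": cells.index}, index=cells.index)
    pool = _pool_from_table(scores, designs, schedule,
                            list(scores.columns))
    if recent_window is None:
        recent_window = schedule.most_recent_historical_id

    current_t = predict_current(model, pool)
    equil_t = predict_equilibrium(model, pool, recent_window=recent_window)
    current = inverse_transform(current_t, transform_kind)
    equilibrium = inverse_transform(equil_t, transform_kind)

    lats = np.asarray(grid["lat"].values)
    lons = np.asarray(grid["lon"].values)
    shape = (len(lats), len(lons))

    def to_grid(values: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[cells["ilat"].to_numpy(), cells["ilon"].to_numpy()] = values
        return out

    data = xr.Dataset(
        {"current": (("lat", "lon"), to_grid(current)),
         "equilibrium": (("lat", "lon"), to_grid(equilibrium)),
         "difference": (("lat", "lon"), to_grid(equilibrium - current))},
        coords={"lat": lats, "lon": lons},
        attrs={"response": model.response_id, "transform": transform_kind,
               "recent_window": recent_window})

    if training_pool is not None and model.size > 0:
        reference = _model_design(model, training_pool, recent_window,
                                  mode="current")
        query = _model_design(model, pool, recent_window, mode="current")
        surface = mess(reference, query)
        data["mess"] = (("lat", "lon"),
                        to_grid(surface.mess.to_numpy(dtype=float)))
        if mess_threshold is not None:
            data["extrapolated"] = data["mess"] < mess_threshold
            data.attrs["mess_threshold"] = mess_threshold
    return PredictionSurface(data=data, cells=cells)


def mask_by_mess(surface: PredictionSurface, mess_surface: xr.DataArray,
                 threshold: float = DEFAULT_MESS_THRESHOLD,
                 ) -> PredictionSurface:
    """Flag cells whose MESS value falls below ``threshold``.

    Prediction values are retained; a boolean ``extrapolated`` layer
    marks the flagged cells.
    """
    data = surface.data
    if (not np.array_equal(mess_surface["lat"].values, data["lat"].values)
            or not np.array_equal(mess_surface["lon"].values,
                                  data["lon"].values)):
        raise ValueError("MESS grid does not match prediction grid")
    out = data.copy()
    out["mess"] = mess_surface
    out["extrapolated"] = mess_surface < threshold
    out.attrs["mess_threshold"] = threshold
    return PredictionSurface(data=out, cells=surface.cells)
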