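"""Seeded generators for synthetic study inputs.

Produces the three ingredients of a soil-biogeography climate-lag study:
a gridded monthly climate series (0.5-degree cells, ten variables, multi-
decadal trends), a nested sampling design (sites with replicate plots),
and response data — soil properties and OTU count tables — whose taxa are
driven by the climatology of a *known* historical window, so that lag
recovery can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import InfeasibleDesignError, InvalidConfigError

#: Fixed grid resolution in degrees.
RESOLUTION = 0.5

#: The ten monthly climate variables carried through the pipeline
#: (CRU-style short names): daily mean / min / max temperature, diurnal
#: temperature range, precipitation, wet-day frequency, frost-day
#: frequency, vapour pressure, cloud cover, potential evapotranspiration.
CLIMATE_VARIABLES = (
    "tmp", "tmn", "tmx", "dtr", "pre", "wet", "frs", "vap", "cld", "pet",
)

TREND_KINDS = ("none", "linear", "saturating")


@dataclass(frozen=True)
class VariableSpec:
    """Generative recipe for one climate variable.

    Monthly value at cell (lat, lon) and elapsed time t (years since the
    series start, mid-month convention)::

        base + lat_gradient*(lat - lat0) + lon_gradient*(lon - lon0)
             + trend(t) + seasonal_amplitude*cos(2*pi*(month - 6)/12)
             + Normal(0, noise_sd)

    ``trend`` is 0 ("none"), ``slope*t`` ("linear"), or linear until
    ``breakpoint_year`` then flat ("saturating" — a consistent trend
    followed by leveling off).
    """

    base: float
    trend: str = "none"
    slope: float = 0.0  # units per year
    seasonal_amplitude: float = 0.0
    lat_gradient: float = 0.0  # units per degree latitude
    lon_gradient: float = 0.0
    noise_sd: float = 0.0
    breakpoint_year: int | None = None

    def __post_init__(self) -> None:
        if self.trend not in TREND_KINDS:
            raise InvalidConfigError(f"unknown trend kind {self.trend!r}")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not np.isfinite([self.base, self.slope, self.seasonal_amplitude,
                            self.lat_gradient, self.lon_gradient]).all():
            raise InvalidConfigError("non-finite variable parameter")


@dataclass(frozen=True)
class ClimateGenConfig:
    """Configuration of the synthetic monthly climate grid."""

    lat_min: float = 30.0
    lat_max: float = 35.0
    lon_min: float = 85.0
    lon_max: float = 91.0
    start_year: int = 1950
    end_year: int = 2011
    variables: dict[str, VariableSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year + 20:
            raise InvalidConfigError(
                "end_year must be >= start_year + 20 (need at least two "
                "decadal windows plus a contemporary year)")
        if (self.lat_max - self.lat_min < RESOLUTION
                or self.lon_max - self.lon_min < RESOLUTION):
            raise InvalidConfigError("extent smaller than one 0.5-degree cell")
        if not self.variables:
            raise InvalidConfigError("at least one climate variable required")

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / RESOLUTION))
        return self.lat_min + RESOLUTION / 2 + RESOLUTION * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / RESOLUTION))
        return self.lon_min + RESOLUTION / 2 + RESOLUTION * np.arange(n)


def default_climate_config(trend_to_noise: float = 1.0,
                           seed: int = 0,
                           **overrides) -> ClimateGenConfig:
    """Default ten-variable configuration for a high-plateau-like region.

    ``trend_to_noise`` scales every deterministic slope and spatial
    gradient relative to the interannual noise. High values make decadal
    climatologies mutually collinear (the realistic regime: windows share
    the same spatial pattern); low values leave window-specific weather
    noise dominant, so climatologies of different decades are spatially
    well separated and lag attribution is easy. The default of 1.0 is the
    realistic regime; recovery experiments use ~0.3 for the
    well-separated regime.
    """
    r = float(trend_to_noise)
    variables = {
        "tmp": VariableSpec(base=-2.0, trend="linear", slope=0.03 * r,
                            seasonal_amplitude=10.0, lat_gradient=-0.6 * r,
                            lon_gradient=0.1 * r, noise_sd=1.2),
        "tmn": VariableSpec(base=-9.0, trend="linear", slope=0.035 * r,
                            seasonal_amplitude=9.0, lat_gradient=-0.6 * r,
                            lon_gradient=0.1 * r, noise_sd=1.3),
        "tmx": VariableSpec(base=5.0, trend="linear", slope=0.025 * r,
                            seasonal_amplitude=11.0, lat_gradient=-0.6 * r,
                            lon_gradient=0.1 * r, noise_sd=1.2),
        "dtr": VariableSpec(base=14.0, trend="linear", slope=-0.01 * r,
                            seasonal_amplitude=2.0, lat_gradient=0.2 * r,
                            noise_sd=0.8),
        "pre": VariableSpec(base=40.0, trend="saturating", slope=0.15 * r,
                            breakpoint_year=1990, seasonal_amplitude=30.0,
                            lat_gradient=-3.0 * r, lon_gradient=0.8 * r,
                            noise_sd=12.0),
        "wet": VariableSpec(base=8.0, trend="saturating", slope=0.02 * r,
                            breakpoint_year=1990, seasonal_amplitude=5.0,
                            lat_gradient=-0.5 * r, noise_sd=2.0),
        "frs": VariableSpec(base=15.0, trend="linear", slope=-0.04 * r,
                            seasonal_amplitude=12.0, lat_gradient=1.0 * r,
                            noise_sd=2.5),
        "vap": VariableSpec(base=6.0, trend="linear", slope=0.008 * r,
                            seasonal_amplitude=4.0, lat_gradient=-0.4 * r,
                            noise_sd=0.9),
        "cld": VariableSpec(base=45.0, trend="none",
                            seasonal_amplitude=15.0, lat_gradient=-1.0 * r,
                            noise_sd=6.0),
        "pet": VariableSpec(base=2.5, trend="linear", slope=0.004 * r,
                            seasonal_amplitude=1.5, lat_gradient=0.15 * r,
                            noise_sd=0.5),
    }
    return ClimateGenConfig(variables=variables, seed=seed, **overrides)


def _trend_values(spec: VariableSpec, t_years: np.ndarray,
                  start_year: int) -> np.ndarray:
    if spec.trend == "none":
        return np.zeros_like(t_years)
    if spec.trend == "linear":
        return spec.slope * t_years
    # saturating: linear until the breakpoint year, flat afterwards
    if spec.breakpoint_year is None:
        raise InvalidConfigError("saturating trend requires breakpoint_year")
    t_break = spec.breakpoint_year - start_year
    return spec.slope * np.minimum(t_years, t_break)


def generate_climate_grid(config: ClimateGenConfig) -> xr.Dataset:
    """Generate a monthly climate grid as an :class:`xarray.Dataset`.

    Dimensions are (time, lat, lon) with one data variable per climate
    variable. Identical configs (including seed) give bit-identical
    output.
    """
    lats, lons = config.lats, config.lons
    time = pd.date_range(f"{config.start_year}-01-01",
                         f"{config.end_year}-12-01", freq="MS")
    n_months = len(time)
    # mid-month elapsed years so a calendar-year mean of a linear trend
    # advances by exactly `slope` from one year to the next
    t_years = (np.arange(n_months) + 0.5) / 12.0
    month_of_year = np.arange(n_months) % 12
    seasonal_shape = np.cos(2 * np.pi * (month_of_year - 6) / 12.0)

    lat0 = lats.mean()
    lon0 = lons.mean()
    dlat = (lats - lat0)[:, None]
    dlon = (lons - lon0)[None, :]

    rng = np.random.default_rng(config.seed)
    data_vars = {}
    for name in sorted(config.variables):  # fixed order => reproducible draws
        spec = config.variables[name]
        base_field = spec.base + spec.lat_gradient * dlat + spec.lon_gradient * dlon
        series = (_trend_values(spec, t_years, config.start_year)
                  + spec.seasonal_amplitude * seasonal_shape)
        values = base_field[None, :, :] + series[:, None, None]
        if spec.noise_sd > 0:
            values = values + rng.normal(
                0.0, spec.noise_sd, size=(n_months, len(lats), len(lons)))
        else:
            values = np.broadcast_to(values, (n_months, len(lats), len(lons))).copy()
        data_vars[name] = (("time", "lat", "lon"), values)

    ds = xr.Dataset(
        data_vars,
        coords={"time": time, "lat": lats, "lon": lons},
        attrs={"start_year": config.start_year, "end_year": config.end_year,
               "resolution": RESOLUTION},
    )
    return ds


@dataclass(frozen=True)
class SampleDesign:
    """One soil sample: a plot within a site, with coordinates and year."""

    sample_id: str
    site_id: str
    plot: int
    lat: float
    lon: float
    collection_year: int


def generate_sites(grid: xr.Dataset, n_sites: int = 60,
                   plots_per_site: int = 3, seed: int = 0,
                   collection_year: int | None = None) -> pd.DataFrame:
    """Draw a nested sampling design: ``n_sites`` grid cells, each holding
    ``plots_per_site`` plots jittered within the cell (so replicate plots
    of a site always share one 0.5-degree cell).

    Returns a DataFrame with columns sample_id, site_id, plot, lat, lon,
    collection_year. Default 60 sites x 3 plots = 180 samples.
    """
    if n_sites < 1:
        raise InfeasibleDesignError("n_sites must be >= 1")
    if plots_per_site < 1:
        raise InfeasibleDesignError("plots_per_site must be >= 1")
    lats = np.asarray(grid["lat"].values)
    lons = np.asarray(grid["lon"].values)
    n_cells = len(lats) * len(lons)
    if n_sites > n_cells:
        raise InfeasibleDesignError(
            f"cannot place {n_sites} sites on a grid of {n_cells} cells")
    if collection_year is None:
        collection_year = int(grid.attrs["end_year"])

    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cells, size=n_sites, replace=False)
    rows = []
    for s, cell in enumerate(chosen):
        i, j = divmod(int(cell), len(lons))
        site_id = f"site{s:02d}"
        for p in range(plots_per_site):
            # jitter strictly inside the cell: half-width 0.25 deg, keep a
            # margin so nearest-center lookup cannot flip cells
            jit_lat = rng.uniform(-0.2, 0.2)
            jit_lon = rng.uniform(-0.2, 0.2)
            rows.append({
                "sample_id": f"{site_id}p{p + 1}",
                "site_id": site_id,
                "plot": p + 1,
                "lat": float(lats[i] + jit_lat),
                "lon": float(lons[j] + jit_lon),
                "collection_year": collection_year,
            })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_soil_properties(designs: pd.DataFrame,
                             climatologies: pd.DataFrame,
                             lag_window: str,
                             coeffs: dict[str, dict[str, float]],
                             noise_sd: float = 0.0,
                             seed: int = 0,
                             intercepts: dict[str, float] | None = None,
                             ) -> pd.DataFrame:
    """Generate soil properties as linear functions of the climatology of
    one (ground-truth) historical window, plus Gaussian noise.

    ``coeffs`` maps property name -> {climate variable: coefficient}.
    The true window id is recorded in ``result.attrs['true_window']``.
    """
    windows = climatologies.index.get_level_values("window")
    if lag_window not in set(windows):
        raise InvalidConfigError(
            f"lag window {lag_window!r} missing from climatology table")
    if not coeffs:
        raise InvalidConfigError("at least one soil property required")
    intercepts = intercepts or {}
    lagged = climatologies.xs(lag_window, level="window")

    rng = np.random.default_rng(seed)
    out = {}
    for prop, betas in coeffs.items():
        missing = set(betas) - set(lagged.columns)
        if missing:
            raise InvalidConfigError(
                f"soil property {prop!r} references unknown climate "
                f"variables {sorted(missing)}")
        values = np.full(len(designs), float(intercepts.get(prop, 0.0)))
        for var, beta in betas.items():
            values = values + beta * lagged.loc[
                designs["site_id"], var].to_numpy()
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=len(designs))
        out[prop] = values
    table = pd.DataFrame(out, index=designs.index)
    table.attrs["true_window"] = lag_window
    return table


@dataclass(frozen=True)
class TaxonSpec:
    """Ground-truth generative recipe for one taxon.

    ``effects`` is a list of (predictor, window_id, coefficient) where the
    predictor is a climate principal component ("PC1".."PC3", window_id
    names the climatology window) or a soil-property column (window_id
    None). Expected relative abundance per sample is proportional to
    exp(baseline + sum of effects + overdispersion noise).
    """

    taxon_id: str
    baseline: float = 0.0
    effects: tuple[tuple[str, str | None, float], ...] = ()
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        for pred, window, coef in self.effects:
            if not np.isfinite(coef):
                raise InvalidConfigError(
                    f"non-finite coefficient for taxon {self.taxon_id}")
        if self.overdispersion < 0:
            raise InvalidConfigError("overdispersion must be >= 0")

    @property
    def true_windows(self) -> tuple[str, ...]:
        return tuple(w for _, w, _ in self.effects if w is not None)


def generate_otu_table(designs: pd.DataFrame,
                       pc_scores: pd.DataFrame,
                       soil: pd.DataFrame | None,
                       taxon_specs: list[TaxonSpec],
                       depth: int = 3000,
                       seed: int = 0,
                       ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Draw one multinomial OTU count vector of size ``depth`` per sample.

    Expected proportions are softmax over taxa of the linear predictor
    defined by each :class:`TaxonSpec`. Returns the count table
    (samples x taxa, row sums exactly ``depth``) and the ground-truth map
    taxon -> list of true window ids.
    """
    if depth < 1:
        raise InvalidConfigError("depth must be >= 1")
    if not taxon_specs:
        raise InvalidConfigError("taxon_specs must be non-empty")

    n = len(designs)
    sites = designs["site_id"].to_numpy()
    eta = np.zeros((n, len(taxon_specs)))
    rng = np.random.default_rng(seed)
    for k, spec in enumerate(taxon_specs):
        eta[:, k] = spec.baseline
        for pred, window, coef in spec.effects:
            if window is not None:
                if (pred not in pc_scores.columns):
                    raise InvalidConfigError(
                        f"taxon {spec.taxon_id}: unknown PC {pred!r}")
                idx = pd.MultiIndex.from_arrays([sites, [window] * n])
                vals = pc_scores[pred].reindex(idx).to_numpy()
                if np.isnan(vals).any():
                    raise InvalidConfigError(
                        f"taxon {spec.taxon_id}: window {window!r} not "
                        f"resolvable in score table")
            else:
                if soil is None or pred not in soil.columns:
                    raise InvalidConfigError(
                        f"taxon {spec.taxon_id}: unknown soil property "
                        f"{pred!r}")
                vals = soil.loc[designs.index, pred].to_numpy()
            eta[:, k] += coef * vals
        if spec.overdispersion > 0:
            eta[:, k] += rng.normal(0.0, spec.overdispersion, size=n)

    # softmax per sample, stabilised
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(depth, probs[i]) for i in range(n)])
    table = pd.DataFrame(counts, index=designs.index,
                         columns=[s.taxon_id for s in taxon_specs])
    truth = {s.taxon_id: list(s.true_windows) for s in taxon_specs}
    return table, truth
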