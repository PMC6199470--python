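"""End-to-end glue: simulate a study, run the lag analysis, forecast.

These helpers wire the stage modules together for the common case of a
fully synthetic study: generate a climate grid and sampling design,
build climatologies and PC scores, draw an OTU table whose taxa respond
to a known historical window, run the subset search, and summarise lag
recovery and equilibration forecasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import community
from .climatology import (ClimatePCModel, WindowSchedule, default_window_schedule,
                          extract_at_locations, fit_climate_pca,
                          window_climatology)
from .equilibration import predict_current, predict_equilibrium, shift_table
from .selection import CandidatePool, build_pc_pool, fit_many
from .synthetic import (ClimateGenConfig, TaxonSpec, default_climate_config,
                        generate_climate_grid, generate_otu_table,
                        generate_sites, generate_soil_properties)

DEFAULT_TRUE_WINDOW = "1960-1969"


@dataclass
class SimulatedStudy:
    """All artifacts of one synthetic study realisation."""

    grid: xr.Dataset
    designs: pd.DataFrame
    schedule: WindowSchedule
    climatologies: pd.DataFrame
    pc_model: ClimatePCModel
    scores: pd.DataFrame
    pool: CandidatePool
    otu: pd.DataFrame
    soil: pd.DataFrame | None
    truth: dict[str, list[str]] = field(default_factory=dict)


def default_taxon_specs(true_window: str = DEFAULT_TRUE_WINDOW,
                        n_signal: int = 5, n_noise: int = 25,
                        coefficient: float = 0.8,
                        overdispersion: float = 0.0) -> list[TaxonSpec]:
    """Signal taxa respond to PC1 of one historical window; filler taxa
    are flat, keeping the composition approximately log-linear."""
    specs = [TaxonSpec(taxon_id=f"sig{k:02d}", baseline=0.0,
                       effects=(("PC1", true_window, coefficient),),
                       overdispersion=overdispersion)
             for k in range(n_signal)]
    specs += [TaxonSpec(taxon_id=f"bg{k:02d}", baseline=0.0,
                        overdispersion=overdispersion)
              for k in range(n_noise)]
    return specs


def simulate_study(seed: int = 0,
                   config: ClimateGenConfig | None = None,
                   n_sites: int = 60, plots_per_site: int = 3,
                   taxon_specs: list[TaxonSpec] | None = None,
                   depth: int = 3000,
                   trend_to_noise: float = 0.3,
                   soil_coeffs: dict | None = None,
                   soil_window: str = DEFAULT_TRUE_WINDOW,
                   soil_noise_sd: float = 0.0) -> SimulatedStudy:
    """Simulate one complete study under the default conditions:
    60 sites x 3 plots = 180 samples on a 0.5-degree grid, monthly
    climate 1950-2011, OTU counts at depth 3000."""
    seed = int(seed)
    if config is None:
        config = default_climate_config(trend_to_noise=trend_to_noise,
                                        seed=seed)
    grid = generate_climate_grid(config)
    designs = generate_sites(grid, n_sites=n_sites,
                             plots_per_site=plots_per_site, seed=seed + 1)
    schedule = default_window_schedule(
        collection_year=int(designs["collection_year"].iloc[0]))
    series = extract_at_locations(grid, designs)
    clim = window_climatology(series, schedule)
    pc_model, scores = fit_climate_pca(clim, n_components=3)
    pool = build_pc_pool(scores, designs, schedule)

    soil = None
    if soil_coeffs:
        soil = generate_soil_properties(designs, clim, soil_window,
                                        soil_coeffs, noise_sd=soil_noise_sd,
                                        seed=seed + 2)
    if taxon_specs is None:
        taxon_specs = default_taxon_specs()
    otu, truth = generate_otu_table(designs, scores, soil, taxon_specs,
                                    depth=depth, seed=seed + 3)
    return SimulatedStudy(grid=grid, designs=designs, schedule=schedule,
                          climatologies=clim, pc_model=pc_model,
                          scores=scores, pool=pool, otu=otu, soil=soil,
                          truth=truth)


def taxon_responses(study: SimulatedStudy, taxa: list[str] | None = None,
                    ) -> pd.DataFrame:
    """Logit-transformed relative abundances for the requested taxa."""
    rel = community.relative_abundance(study.otu)
    if taxa is None:
        taxa = [t for t, ws in study.truth.items() if ws]
    out = {}
    for t in taxa:
        out[t] = community.transform_response(rel[t], "logit")
    return pd.DataFrame(out, index=study.otu.index)


def recover_lags(study: SimulatedStudy, max_size: int = 2,
                 taxa: list[str] | None = None):
    """Fit every signal taxon and return (modal selected window,
    per-window selection frequency table, fit result)."""
    responses = taxon_responses(study, taxa)
    result = fit_many(responses, study.pool, max_size=max_size,
                      compute_lmg=False)
    freq = result.frequency
    modal = freq["count"].idxmax() if freq["count"].max() > 0 else None
    return modal, freq, result


def forecast_diversity(study: SimulatedStudy, max_size: int = 2,
                       rarefy_depth: int | None = None, seed: int = 0):
    """Model log-richness and log-Shannon on the study's pool, forecast
    equilibration shifts, and return the per-response shift tables."""
    table = study.otu
    if rarefy_depth is not None:
        table = community.rarefy(table, depth=rarefy_depth, seed=seed)
    div = community.diversity(table)
    responses = pd.DataFrame(
        {"richness": community.transform_response(div["richness"], "log"),
         "shannon": community.transform_response(div["shannon"], "log")},
        index=div.index)
    result = fit_many(responses, study.pool, max_size=max_size)
    shifts = {}
    for name, model in result.models.items():
        cur = predict_current(model, study.pool)
        eq = predict_equilibrium(model, study.pool)
        shifts[name] = shift_table(cur, eq, "log",
                                   index=pd.Index(study.pool.sample_ids))
    return shifts, result
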