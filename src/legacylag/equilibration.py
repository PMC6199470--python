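"""Forecasting community equilibration to contemporary climate.

A lag-fitted model ties a response to climatologies of particular
historical windows. The equilibration forecast asks what the response
would look like if the community tracked today's climate instead:
every historical-window predictor is replaced by the same climate
feature evaluated at the most recent decadal climatology, coefficients
unchanged. Shifts are differences between the equilibrium and current
*predictions* (never observations), back-transformed to the response's
natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import inverse_transform
from .selection import CandidatePool, SelectedModel


def _design(model: SelectedModel, pool: CandidatePool,
            window_map) -> np.ndarray:
    cols = []
    for cand in model.predictors:
        window = window_map(cand.window)
        cols.append(pool.X[:, pool.column(cand.feature, window)])
    if not cols:
        return np.zeros((len(pool.sample_ids), 0))
    return np.column_stack(cols)


def predict_current(model: SelectedModel, pool: CandidatePool) -> np.ndarray:
    """Transformed-scale prediction with the model's own windows."""
    return model.predict(_design(model, pool, lambda w: w))


def predict_equilibrium(model: SelectedModel, pool: CandidatePool,
                        recent_window: str | None = None,
                        substitute_contemporary: bool = False) -> np.ndarray:
    """Transformed-scale prediction after equilibration.

    Historical-window predictors are evaluated at ``recent_window`` (the
    most recent decadal window of the pool's schedule by default);
    contemporary 1-year predictors are left unchanged unless
    ``substitute_contemporary`` is set.
    """
    if recent_window is None:
        hist = [w for w in pool.window_order if w != pool.contemporary_id]
        if not hist:
            raise ValueError("pool has no historical windows")
        recent_window = hist[-1]
    if recent_window not in pool.window_order:
        raise ValueError(f"recent window {recent_window!r} not in pool")

    def window_map(w: str) -> str:
        if w == pool.contemporary_id and not substitute_contemporary:
            return w
        return recent_window

    return model.predict(_design(model, pool, window_map))


def shift_table(current: np.ndarray, equilibrium: np.ndarray, kind: str,
                index: pd.Index | None = None) -> pd.DataFrame:
    """Back-transform paired predictions and tabulate shifts.

    ``current`` and ``equilibrium`` are transformed-scale predictions;
    ``kind`` is the response transform ("log" or "logit"). Percent change
    uses the predicted current value as denominator.
    """
    current = np.asarray(current, dtype=float)
    equilibrium = np.asarray(equilibrium, dtype=float)
    if current.shape != equilibrium.shape:
        raise ValueError("prediction vectors must align")
    cur = inverse_transform(current, kind)
    eq = inverse_transform(equilibrium, kind)
    shift = eq - cur
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * shift / cur
    out = pd.DataFrame({"current": cur, "equilibrium": eq, "shift": shift,
                        "percent_change": pct})
    if index is not None:
        out.index = index
    return out


def _pairwise_percent_differences(values: np.ndarray) -> np.ndarray:
    """|percent change| between every ordered pair of samples,
    100*(v_i - v_j)/v_j for i != j — the intersample analogue of the
    within-sample percent shift."""
    v = np.asarray(values, dtype=float)
    diff = 100.0 * (v[:, None] - v[None, :]) / v[None, :]
    mask = ~np.eye(len(v), dtype=bool)
    return np.abs(diff[mask])


@dataclass
class ShiftSummary:
    """The four equilibration questions for one response.

    (i) prevalence and magnitude of increases; (ii) within-sample shift
    magnitude vs existing intersample variation; (iii) correlation of
    shift with current level (rich-get-richer vs homogenisation);
    (iv) intersample dispersion after vs before equilibration.
    """

    n: int
    fraction_increasing: float
    mean_percent_change: float
    se_percent_change: float
    shift_level_correlation: float
    median_abs_shift_percent: float
    median_intersample_diff_current: float
    median_intersample_diff_equilibrium: float
    dispersion_current: float
    dispersion_equilibrium: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def shift_summaries(table: pd.DataFrame) -> ShiftSummary:
    """Summarise a :func:`shift_table` result across locations."""
    if len(table) < 3:
        raise ValueError("need at least 3 locations")
    shift = table["shift"].to_numpy()
    pct = table["percent_change"].to_numpy()
    cur = table["current"].to_numpy()
    eq = table["equilibrium"].to_numpy()

    n = len(table)
    frac = float(np.mean(shift > 0))
    mean_pct = float(np.mean(pct))
    se_pct = float(np.std(pct, ddof=1) / np.sqrt(n))
    if np.ptp(cur) == 0 or np.ptp(shift) == 0:
        corr = np.nan
    else:
        corr = float(stats.pearsonr(cur, shift).statistic)
    pair_cur = _pairwise_percent_differences(cur)
    pair_eq = _pairwise_percent_differences(eq)
    return ShiftSummary(
        n=n,
        fraction_increasing=frac,
        mean_percent_change=mean_pct,
        se_percent_change=se_pct,
        shift_level_correlation=corr,
        median_abs_shift_percent=float(np.median(np.abs(pct))),
        median_intersample_diff_current=float(np.median(pair_cur)),
        median_intersample_diff_equilibrium=float(np.median(pair_eq)),
        dispersion_current=float(np.std(pair_cur, ddof=1)),
        dispersion_equilibrium=float(np.std(pair_eq, ddof=1)),
    )


def site_mean_shift_table(table: pd.DataFrame,
                          designs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate plot-level shifts to site level (mean of plots) before
    summarising — optional handling of within-site pseudo-replication."""
    grouped = table.join(designs["site_id"]).groupby("site_id").mean(
        numeric_only=True)
    return grouped


def abundance_shift_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-taxon equilibration summary (shift direction and magnitude vs
    current intersample variability in relative abundance)."""
    if not tables:
        raise ValueError("need at least one taxon")
    rows = []
    for taxon, table in tables.items():
        pct = table["percent_change"].to_numpy()
        cur = table["current"].to_numpy()
        pair = _pairwise_percent_differences(cur)
        rows.append({
            "taxon": taxon,
            "n": len(table),
            "fraction_increasing": float(np.mean(table["shift"] > 0)),
            "mean_percent_change": float(np.mean(pct)),
            "median_abs_shift_percent": float(np.median(np.abs(pct))),
            "median_intersample_diff_percent": float(np.median(pair)),
        })
    return pd.DataFrame(rows).set_index("taxon")
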