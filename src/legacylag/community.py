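"""Community-level statistics feeding the lag models.

Rarefaction to a common depth, richness and Shannon diversity,
prevalence filtering, response transforms, Bray-Curtis dissimilarity,
Mantel tests and the FDR-controlled soil-correlation screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_DEPTH = 3000
DEFAULT_MIN_SAMPLES = 40


def rarefy(table: pd.DataFrame, depth: int = DEFAULT_DEPTH,
           seed: int = 0) -> pd.DataFrame:
    """Subsample each sample's counts to ``depth`` reads without
    replacement (multivariate hypergeometric draw per sample).

    Samples with fewer than ``depth`` reads are dropped with a warning;
    they are never scaled up. Every output row sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("OTU table must contain integer counts")
        counts = np.round(counts).astype(np.int64)
    if (counts < 0).any():
        raise ValueError("OTU table must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    kept = []
    for i, sample_id in enumerate(table.index):
        total = int(counts[i].sum())
        if total < depth:
            log.warning("dropping sample %r: %d reads < depth %d",
                        sample_id, total, depth)
            continue
        if total == depth:
            rows.append(counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept.append(sample_id)
    return pd.DataFrame(np.asarray(rows, dtype=np.int64), index=kept,
                        columns=table.columns)


def diversity(table: pd.DataFrame, log_base: float | None = None,
              ) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity.

    Richness counts taxa with nonzero counts; Shannon is
    -sum(p * ln p) over nonzero proportions, in nats by default
    (``log_base`` switches the logarithm).
    """
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = table.index[totals == 0].tolist()
        raise ValueError(f"empty sample(s): {empty}")
    richness = (counts > 0).sum(axis=1)
    shannon = np.array([stats.entropy(row[row > 0]) for row in counts])
    if log_base is not None:
        shannon = shannon / np.log(log_base)
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.index)


def prevalence_filter(table: pd.DataFrame,
                      min_samples: int = DEFAULT_MIN_SAMPLES,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Retain taxa detected in at least ``min_samples`` samples
    (boundary inclusive). Returns the filtered table and the per-taxon
    prevalence counts of the input."""
    prevalence = (table > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_samples].index
    return table[keep], prevalence


def collapse_taxonomy(table: pd.DataFrame,
                      taxonomy: pd.Series) -> pd.DataFrame:
    """Sum OTU counts within each higher-level group (e.g. family).

    ``taxonomy`` maps OTU id -> group name; OTUs absent from the map are
    dropped. Collapsing precedes prevalence filtering so that group and
    OTU tables are filtered independently.
    """
    mapped = [c for c in table.columns if c in taxonomy.index]
    grouped = table[mapped].T.groupby(taxonomy.loc[mapped]).sum().T
    return grouped


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty sample in OTU table")
    return table.div(totals, axis=0)


def transform_response(values: pd.Series | np.ndarray, kind: str,
                       smoothing: bool | str = "auto") -> np.ndarray:
    """Transform a response variable prior to modeling.

    ``log``: natural log (diversity responses); values must be positive.
    ``logit``: ln(x/(1-x)) for proportions in [0, 1]; when smoothing is
    active and any value sits on the boundary, the empirical smoothing
    x' = (x*(n-1) + 0.5)/n is applied to *all* values first (n = sample
    count), keeping the transform finite.
    """
    x = np.asarray(values, dtype=float)
    if kind == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive values")
        return np.log(x)
    if kind == "logit":
        if ((x < 0) | (x > 1)).any():
            raise ValueError("logit transform requires values in [0, 1]")
        boundary = ((x == 0) | (x == 1)).any()
        if smoothing is True or (smoothing == "auto" and boundary):
            n = len(x)
            x = (x * (n - 1) + 0.5) / n
        elif boundary:
            raise ValueError("boundary value with smoothing disabled")
        return np.log(x / (1 - x))
    raise ValueError(f"unknown transform kind {kind!r}")


def inverse_transform(values: pd.Series | np.ndarray, kind: str) -> np.ndarray:
    """Inverse of :func:`transform_response` (on the smoothed scale)."""
    y = np.asarray(values, dtype=float)
    if kind == "log":
        return np.exp(y)
    if kind == "logit":
        from scipy.special import expit
        return expit(y)
    raise ValueError(f"unknown transform kind {kind!r}")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix,
    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i), values in [0, 1]."""
    counts = table.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty sample in OTU table")
    d = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(d, k=-1)
    return d[i, j]


def mantel_test(d1: pd.DataFrame | np.ndarray, d2: pd.DataFrame | np.ndarray,
                n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the lower triangles of two
    distance matrices, with a one-sided permutation p-value obtained by
    jointly permuting rows and columns of the second matrix.

    p = (1 + #{permuted r >= observed r}) / (1 + n_perm).
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and same shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects")
    for m, name in ((a, "d1"), (b, "d2")):
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError(f"{name} has nonzero diagonal")

    va = _lower_triangle(a)
    r_obs = stats.pearsonr(va, _lower_triangle(b)).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = stats.pearsonr(va, _lower_triangle(b[np.ix_(perm, perm)])
                                ).statistic
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def correlation_screen(responses: pd.DataFrame, predictors: pd.DataFrame,
                       q: float = 0.05) -> pd.DataFrame:
    """Pearson-correlate every response with every predictor and control
    the false discovery rate across the whole family of tests
    (Benjamini-Hochberg).

    Returns one row per (response, predictor) with r, p, the BH-adjusted
    q-value and a significance flag at ``q``. Constant columns are
    skipped with a logged reason; pairs need >= 4 complete observations.
    """
    common = responses.index.intersection(predictors.index)
    resp = responses.loc[common]
    pred = predictors.loc[common]

    resp_arr = resp.to_numpy(dtype=float)
    pred_arr = pred.to_numpy(dtype=float)
    rows = []
    for ri, rname in enumerate(resp.columns):
        for pi, pname in enumerate(pred.columns):
            x = resp_arr[:, ri]
            y = pred_arr[:, pi]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                log.warning("skipping %s ~ %s: fewer than 4 complete pairs",
                            rname, pname)
                continue
            x, y = x[ok], y[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                log.warning("skipping %s ~ %s: constant column", rname, pname)
                continue
            res = stats.pearsonr(x, y)
            rows.append({"response": rname, "predictor": pname,
                         "n": int(ok.sum()), "r": res.statistic,
                         "p": res.pvalue})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], significant=[])
    flag, qvals, _, _ = multipletests(out["p"].to_numpy(), alpha=q,
                                      method="fdr_bh")
    out["q"] = qvals
    out["significant"] = flag
    return out
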