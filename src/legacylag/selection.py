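"""Climate-lag detection by all-subset regression under leave-one-out CV.

Climatologies from every decade compete, as candidate predictors, to
explain each response (diversity metric, taxon relative abundance, soil
property). Every subset of candidates up to ``max_size`` is fitted by
OLS; the winner minimises the leave-one-out mean squared prediction
error, with the intercept-only model as a competing null. Predictor
importance within the winning model is decomposed with the
Lindeman-Merenda-Gold (LMG) statistic — a predictor's average
incremental R-squared over all orderings of entry — and lag structure is
summarised as the selection frequency of each time window across
responses.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climatology import WindowSchedule
from .exceptions import RankDeficiencyError

log = logging.getLogger(__name__)

DEFAULT_MAX_SIZE = 5

#: cap on floats in one batched subset-evaluation chunk (~64 MB)
_CHUNK_BUDGET = 8_000_000


@dataclass(frozen=True)
class Candidate:
    """One candidate predictor: a climate feature at a time window."""

    feature: str       # "PC1".."PC3" or a raw climate variable name
    window: str        # window id

    @property
    def label(self) -> str:
        return f"{self.feature}@{self.window}"


@dataclass
class CandidatePool:
    """Per-sample values of every candidate predictor.

    Candidates are ordered oldest window first (contemporary last) and by
    feature within a window, which makes the deterministic tie-break of
    the subset search (earlier window, then lower component index) a
    plain lexicographic preference on candidate indices.
    """

    candidates: list[Candidate]
    X: np.ndarray                      # (n_samples, n_candidates)
    sample_ids: list[str]
    window_order: list[str]            # oldest -> newest, contemporary last
    contemporary_id: str

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.sample_ids), len(self.candidates)):
            raise ValueError("candidate matrix shape mismatch")
        self._by_key = {(c.feature, c.window): k
                        for k, c in enumerate(self.candidates)}

    def __len__(self) -> int:
        return len(self.candidates)

    def column(self, feature: str, window: str) -> int:
        return self._by_key[(feature, window)]

    def subpool(self, indices: list[int]) -> "CandidatePool":
        return CandidatePool(
            candidates=[self.candidates[k] for k in indices],
            X=self.X[:, indices],
            sample_ids=self.sample_ids,
            window_order=self.window_order,
            contemporary_id=self.contemporary_id)


def _pool_from_table(table: pd.DataFrame, designs: pd.DataFrame,
                     schedule: WindowSchedule,
                     features: list[str]) -> CandidatePool:
    sites = designs["site_id"].to_numpy()
    n = len(designs)
    candidates = []
    columns = []
    for w in schedule:
        for feat in features:
            candidates.append(Candidate(feature=feat, window=w.id))
            idx = pd.MultiIndex.from_arrays([sites, [w.id] * n])
            col = table[feat].reindex(idx).to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(
                    f"candidate {feat}@{w.id}: values missing for some "
                    f"locations")
            columns.append(col)
    return CandidatePool(candidates=candidates,
                         X=np.column_stack(columns),
                         sample_ids=list(designs.index),
                         window_order=schedule.ids,
                         contemporary_id=schedule.contemporary_id)


def build_pc_pool(scores: pd.DataFrame, designs: pd.DataFrame,
                  schedule: WindowSchedule) -> CandidatePool:
    """Default pool: the retained principal components at every window
    (3 PCs x 12 windows = 36 candidates)."""
    return _pool_from_table(scores, designs, schedule, list(scores.columns))


def build_raw_pool(climatologies: pd.DataFrame, designs: pd.DataFrame,
                   schedule: WindowSchedule) -> CandidatePool:
    """Robustness pool: the raw climate variables at every window
    (10 variables x 12 windows = 120 candidates)."""
    return _pool_from_table(climatologies, designs, schedule,
                            list(climatologies.columns))


# ---------------------------------------------------------------------------
# leave-one-out machinery


def loo_cv_error(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out mean squared prediction error of the OLS fit of
    ``y`` on ``X`` (an intercept is always included).

    Uses the hat-matrix identity e_(i) = e_i / (1 - h_ii), which equals
    refitting the model n times with one sample left out.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise RankDeficiencyError("rank-deficient design matrix")
    q, _ = np.linalg.qr(A)
    h = np.sum(q ** 2, axis=1)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    loo_resid = resid / (1.0 - h)
    return float(np.mean(loo_resid ** 2))


def _intercept_only_loo(y: np.ndarray) -> float:
    n = len(y)
    resid = (y - y.mean()) * n / (n - 1)
    return float(np.mean(resid ** 2))


def _eval_subsets(A: np.ndarray, y: np.ndarray, subsets: np.ndarray,
                  sstot: float) -> tuple[np.ndarray, np.ndarray]:
    """Batched LOO MSE and in-sample R^2 for many same-size subsets.

    ``A`` is the intercept-augmented candidate matrix (column 0 = ones);
    ``subsets`` holds 0-based candidate indices (m, k). Singular subsets
    get LOO = inf.
    """
    n = len(y)
    m, k = subsets.shape
    idx = np.concatenate([np.zeros((m, 1), dtype=int), subsets + 1], axis=1)
    G = A.T @ A
    Ay = A.T @ y
    XtX = G[idx[:, :, None], idx[:, None, :]]
    Xty = Ay[idx]

    loo = np.full(m, np.inf)
    r2 = np.full(m, -np.inf)
    try:
        inv = np.linalg.inv(XtX)
        ok = np.ones(m, dtype=bool)
    except np.linalg.LinAlgError:
        inv = np.empty_like(XtX)
        ok = np.zeros(m, dtype=bool)
        for t in range(m):
            try:
                inv[t] = np.linalg.inv(XtX[t])
                ok[t] = True
            except np.linalg.LinAlgError:
                pass
    if not ok.any():
        return loo, r2
    # condition guard: near-singular subsets behave like rank-deficient ones
    beta = np.einsum("mij,mj->mi", inv, Xty)
    Xs = A[:, idx]                     # (n, m, k+1)
    fitted = np.einsum("nmk,mk->mn", Xs, beta)
    resid = y[None, :] - fitted
    h = np.einsum("nmk,mkj,nmj->mn", Xs, inv, Xs)
    with np.errstate(divide="ignore", invalid="ignore"):
        loo_resid = resid / (1.0 - h)
        loo_ok = np.mean(loo_resid ** 2, axis=1)
    bad = ~np.isfinite(loo_ok) | (np.abs(h) > 1 + 1e-8).any(axis=1)
    loo_ok[bad | ~ok] = np.inf
    loo = loo_ok
    r2 = 1.0 - np.sum(resid ** 2, axis=1) / sstot
    r2[~ok] = -np.inf
    return loo, r2


@dataclass
class SelectedModel:
    """Winning regression model for one response."""

    response_id: str
    predictors: list[Candidate]
    intercept: float
    coefficients: np.ndarray
    r2: float
    loo_mse: float
    lmg: pd.Series | None = None

    @property
    def size(self) -> int:
        return len(self.predictors)

    @property
    def windows(self) -> list[str]:
        return sorted({c.window for c in self.predictors})

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return np.full(X.shape[0] if X.ndim == 2 else len(X),
                           self.intercept)
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


def _fit_subset(pool: CandidatePool, y: np.ndarray, subset: tuple[int, ...],
                response_id: str) -> SelectedModel:
    n = len(y)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if not subset:
        return SelectedModel(response_id=response_id, predictors=[],
                             intercept=float(y.mean()),
                             coefficients=np.zeros(0), r2=0.0,
                             loo_mse=_intercept_only_loo(y))
    X = pool.X[:, list(subset)]
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    r2 = 1.0 - float(np.sum(resid ** 2)) / sstot
    return SelectedModel(
        response_id=response_id,
        predictors=[pool.candidates[k] for k in subset],
        intercept=float(beta[0]), coefficients=beta[1:],
        r2=r2, loo_mse=loo_cv_error(X, y))


def all_subset_select(y: np.ndarray | pd.Series, pool: CandidatePool,
                      max_size: int = DEFAULT_MAX_SIZE,
                      response_id: str = "response",
                      ) -> tuple[SelectedModel, dict[int, SelectedModel]]:
    """Exhaustive best-subset search under the LOO-MSE criterion.

    Enumerates every candidate subset of size 0..max_size, keeps the
    LOO-minimising subset within each size, and returns the overall
    winner plus the per-size bests. Ties are broken deterministically:
    fewer predictors first, then the lexicographically smallest index
    tuple (candidates are ordered oldest window first, lowest component
    first).
    """
    if isinstance(y, pd.Series):
        response_id = y.name if y.name is not None else response_id
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = len(pool)
    if p == 0:
        raise ValueError("empty candidate pool")
    if n != pool.X.shape[0]:
        raise ValueError("response length does not match pool")
    if max_size >= n - 1:
        raise ValueError("max_size must be < n - 1")
    max_size = min(max_size, p)

    A = np.column_stack([np.ones(n), pool.X])
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("constant response")

    per_size: dict[int, SelectedModel] = {
        0: _fit_subset(pool, y, (), response_id)}
    best = per_size[0]
    for k in range(1, max_size + 1):
        chunk = max(1, _CHUNK_BUDGET // (n * (k + 1)))
        best_loo = np.inf
        best_subset: tuple[int, ...] | None = None
        combos = itertools.combinations(range(p), k)
        while True:
            block = list(itertools.islice(combos, chunk))
            if not block:
                break
            subsets = np.asarray(block, dtype=int)
            loo, _ = _eval_subsets(A, y, subsets, sstot)
            j = int(np.argmin(loo))   # first minimum = smallest index tuple
            if loo[j] < best_loo:
                best_loo = float(loo[j])
                best_subset = tuple(subsets[j])
        if best_subset is None or not np.isfinite(best_loo):
            log.debug("size %d: no non-singular subset for %s", k,
                      response_id)
            continue
        model = _fit_subset(pool, y, best_subset, response_id)
        per_size[k] = model
        if model.loo_mse < best.loo_mse:  # strict: ties favour fewer terms
            best = model
    return best, per_size


# ---------------------------------------------------------------------------
# LMG relative importance


def _r2_cache_fn(X: np.ndarray, y: np.ndarray):
    n = len(y)
    sstot = float(np.sum((y - y.mean()) ** 2))
    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2_of(subset: frozenset) -> float:
        if subset not in cache:
            cols = sorted(subset)
            A = np.column_stack([np.ones(n), X[:, cols]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            cache[subset] = 1.0 - float(np.sum(resid ** 2)) / sstot
        return cache[subset]

    return r2_of


def lmg(X: np.ndarray, y: np.ndarray,
        labels: list[str] | None = None) -> pd.Series:
    """Lindeman-Merenda-Gold decomposition of R^2.

    LMG_j is the average over all p! orderings of entry of the increase
    in R^2 when predictor j enters, computed through the equivalent
    subset-weighting identity

        LMG_j = sum over S not containing j of
                |S|! (p - |S| - 1)! / p!  *  (R^2(S + j) - R^2(S)).

    The per-predictor values are >= 0 for well-behaved designs and sum
    exactly to the full model's R^2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one predictor")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise RankDeficiencyError("collinear predictors in LMG")

    r2_of = _r2_cache_fn(X, y)
    values = np.zeros(p)
    others = list(range(p))
    fact = math.factorial
    for j in range(p):
        rest = [t for t in others if t != j]
        for size in range(p):
            w = fact(size) * fact(p - size - 1) / fact(p)
            for S in itertools.combinations(rest, size):
                s = frozenset(S)
                values[j] += w * (r2_of(s | {j}) - r2_of(s))
    if labels is None:
        labels = [f"x{j}" for j in range(p)]
    return pd.Series(values, index=labels, name="lmg")


def model_lmg(model: SelectedModel, pool: CandidatePool,
              y: np.ndarray) -> pd.Series:
    cols = [pool.column(c.feature, c.window) for c in model.predictors]
    return lmg(pool.X[:, cols], np.asarray(y, dtype=float),
               labels=[c.label for c in model.predictors])


# ---------------------------------------------------------------------------
# many responses + selection-frequency summary


@dataclass
class FitManyResult:
    models: dict[str, SelectedModel]
    frequency: pd.DataFrame          # per window: count and fraction
    earliest_window: pd.Series       # per response, NaN if intercept-only
    skipped: dict[str, str] = field(default_factory=dict)


def selection_frequency(models: dict[str, SelectedModel],
                        window_order: list[str]) -> pd.DataFrame:
    """Per window, the number/fraction of responses whose winning model
    contains a predictor from that window."""
    counts = {w: 0 for w in window_order}
    for model in models.values():
        for w in model.windows:
            counts[w] += 1
    n = max(len(models), 1)
    out = pd.DataFrame({"count": pd.Series(counts)})
    out["fraction"] = out["count"] / n
    return out.loc[window_order]


def fit_many(responses: pd.DataFrame, pool: CandidatePool,
             max_size: int = DEFAULT_MAX_SIZE,
             compute_lmg: bool = True) -> FitManyResult:
    """Run the subset search for every response column (already
    transformed) and summarise lag structure across responses.

    The earliest selected window per response follows the window order of
    the schedule (oldest first); responses whose winner is intercept-only
    get no window.
    """
    models: dict[str, SelectedModel] = {}
    skipped: dict[str, str] = {}
    rank = {w: i for i, w in enumerate(pool.window_order)}
    earliest = {}
    for name in responses.columns:
        y = responses[name].to_numpy(dtype=float)
        try:
            winner, _ = all_subset_select(y, pool, max_size=max_size,
                                          response_id=str(name))
            if compute_lmg and winner.size > 0:
                winner.lmg = model_lmg(winner, pool, y)
        except (ValueError, RankDeficiencyError) as exc:
            log.warning("skipping response %r: %s", name, exc)
            skipped[str(name)] = str(exc)
            continue
        models[str(name)] = winner
        ws = winner.windows
        earliest[str(name)] = (min(ws, key=rank.get) if ws else np.nan)
    freq = selection_frequency(models, pool.window_order)
    return FitManyResult(models=models, frequency=freq,
                         earliest_window=pd.Series(earliest, dtype=object),
                         skipped=skipped)


def two_step_select(y: np.ndarray | pd.Series, raw_pool: CandidatePool,
                    k_top: int = 5, max_size: int = DEFAULT_MAX_SIZE,
                    screen_windows: tuple[str, str] | None = None,
                    response_id: str = "response") -> SelectedModel:
    """Two-step robustness selection over the raw climatology pool.

    Step 1 ranks the raw climate variables by their best univariate LOO
    MSE restricted to the 1960-1969 and contemporary windows and keeps
    the top ``k_top`` variables. Step 2 runs the all-subset search over
    those variables across *all* windows.
    """
    if isinstance(y, pd.Series):
        response_id = y.name if y.name is not None else response_id
        y = y.to_numpy(dtype=float)
    if screen_windows is None:
        screen = [w for w in raw_pool.window_order if w.startswith("1960")]
        if not screen:
            raise ValueError("no 1960s window in pool; pass screen_windows")
        screen_windows = (screen[0], raw_pool.contemporary_id)

    features = sorted({c.feature for c in raw_pool.candidates})
    scores = {}
    for feat in features:
        best = np.inf
        for w in screen_windows:
            try:
                col = raw_pool.column(feat, w)
            except KeyError:
                continue
            try:
                best = min(best, loo_cv_error(raw_pool.X[:, [col]], y))
            except RankDeficiencyError:
                continue
        if np.isfinite(best):
            scores[feat] = best
    top = sorted(scores, key=scores.get)[:k_top]
    keep = [k for k, c in enumerate(raw_pool.candidates) if c.feature in top]
    winner, _ = all_subset_select(y, raw_pool.subpool(keep),
                                  max_size=max_size, response_id=response_id)
    return winner
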