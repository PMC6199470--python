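"""Subset search, LOO shortcut and LMG against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from legacylag import pipeline
from legacylag.climatology import default_window_schedule
from legacylag.exceptions import RankDeficiencyError
from legacylag.selection import (Candidate, CandidatePool, all_subset_select,
                                 build_raw_pool, fit_many, lmg, loo_cv_error,
                                 model_lmg, selection_frequency,
                                 two_step_select)


def explicit_loo_mse(X, y):
    """Oracle: refit OLS n times, each time leaving one sample out."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    errors = []
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        errors.append((y[i] - A[i] @ beta) ** 2)
    return float(np.mean(errors))


def sklearn_r2(X, y):
    from sklearn.linear_model import LinearRegression
    if X.shape[1] == 0:
        return 0.0
    return float(LinearRegression().fit(X, y).score(X, y))


def make_pool(X, window_ids=None):
    n, p = X.shape
    windows = window_ids or [f"w{k}" for k in range(p)]
    cands = [Candidate(feature="PC1", window=w) for w in windows]
    return CandidatePool(candidates=cands, X=X,
                         sample_ids=[f"s{i}" for i in range(n)],
                         window_order=windows, contemporary_id=windows[-1])


class TestLooCv:
    def test_noise_free_linear_response(self, rng):
        X = rng.normal(size=(40, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.25])
        assert loo_cv_error(X, y) <= 1e-20

    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(size=25)
        n = len(y)
        closed = np.mean(((y - y.mean()) * n / (n - 1)) ** 2)
        assert explicit_loo_mse(np.empty((n, 0)), y) == pytest.approx(
            closed, rel=1e-12)

    def test_shortcut_matches_explicit_refits(self, rng):
        for _ in range(50):
            n = int(rng.integers(15, 40))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            assert loo_cv_error(X, y) == pytest.approx(
                explicit_loo_mse(X, y), abs=1e-10, rel=1e-10)

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(RankDeficiencyError):
            loo_cv_error(X, rng.normal(size=20))


class TestAllSubsetSelect:
    def test_perfect_predictor_wins(self, rng):
        X = rng.normal(size=(30, 5))
        y = 1.0 + 3.0 * X[:, 2]
        pool = make_pool(X)
        winner, _ = all_subset_select(y, pool, max_size=2)
        assert [c.window for c in winner.predictors] == ["w2"]
        assert winner.loo_mse <= 1e-18

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive enumeration with explicit LOO refits, 6 candidates."""
        n, p, max_size = 25, 6, 3
        X = rng.normal(size=(n, p))
        for _ in range(5):
            y = X @ rng.normal(size=p) * 0.4 + rng.normal(size=n)
            best_loo, best_subset = np.inf, ()
            for k in range(0, max_size + 1):
                for subset in itertools.combinations(range(p), k):
                    loo = explicit_loo_mse(X[:, list(subset)], y)
                    if loo < best_loo - 1e-12:
                        best_loo, best_subset = loo, subset
            winner, per_size = all_subset_select(y, make_pool(X),
                                                 max_size=max_size)
            got = tuple(sorted(int(c.window[1:]) for c in winner.predictors))
            assert got == best_subset
            assert winner.loo_mse == pytest.approx(best_loo, rel=1e-9)
            assert set(per_size) == set(range(max_size + 1))

    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        pool = make_pool(X)
        w1, _ = all_subset_select(y, pool, max_size=2)
        w2, _ = all_subset_select(y, pool, max_size=2)
        assert [c.label for c in w1.predictors] == \
            [c.label for c in w2.predictors]

    def test_max_size_bound_enforced(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            all_subset_select(rng.normal(size=6), make_pool(X), max_size=5)


class TestLmg:
    def lmg_ordering_oracle(self, X, y):
        """Direct enumeration: average incremental R^2 over all p!
        orderings of entry, subset R^2 from sklearn."""
        p = X.shape[1]
        cache = {}

        def r2(subset):
            key = frozenset(subset)
            if key not in cache:
                cache[key] = sklearn_r2(X[:, sorted(key)], y)
            return cache[key]

        totals = np.zeros(p)
        for order in itertools.permutations(range(p)):
            seen = []
            for j in order:
                totals[j] += r2(seen + [j]) - r2(seen)
                seen.append(j)
        return totals / math.factorial(p)

    def test_single_predictor_is_r2(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2 * x[:, 0] + rng.normal(size=30)
        got = lmg(x, y)
        assert got.iloc[0] == pytest.approx(sklearn_r2(x, y), abs=1e-12)

    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        # orthogonal design: alternating sign patterns
        X = np.column_stack([
            np.tile([1, -1], n // 2),
            np.tile([1, 1, -1, -1], n // 4),
            np.tile([1] * 4 + [-1] * 4, n // 8)]).astype(float)
        rng = np.random.default_rng(5)
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n)
        got = lmg(X, y)
        marginal = [sklearn_r2(X[:, [j]], y) for j in range(3)]
        np.testing.assert_allclose(got.to_numpy(), marginal, atol=1e-10)
        assert got.sum() == pytest.approx(sklearn_r2(X, y), abs=1e-10)

    def test_correlated_three_predictor_oracle(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(40, 3))
        X = base @ np.array([[1.0, 0.6, 0.3], [0.0, 1.0, 0.5],
                             [0.0, 0.0, 1.0]])
        y = X @ np.array([1.0, -0.8, 0.4]) + rng.normal(size=40)
        got = lmg(X, y).to_numpy()
        np.testing.assert_allclose(got, self.lmg_ordering_oracle(X, y),
                                   atol=1e-12)

    def test_sum_equals_r2(self, rng):
        for _ in range(10):
            p = int(rng.integers(1, 6))
            X = rng.normal(size=(30, p))
            y = X @ rng.normal(size=p) + rng.normal(size=30)
            assert lmg(X, y).sum() == pytest.approx(sklearn_r2(X, y),
                                                    abs=1e-10)

    def test_collinear_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(RankDeficiencyError):
            lmg(np.column_stack([x, x]), rng.normal(size=20))


class TestFitMany:
    def test_common_true_window_dominates(self, study):
        modal, freq, result = pipeline.recover_lags(study, max_size=2)
        assert modal == "1960-1969"
        assert freq.loc["1960-1969", "count"] == freq["count"].max()
        # earliest-window bookkeeping points at (or before) the truth
        order = {w: i for i, w in enumerate(study.pool.window_order)}
        for name, w in result.earliest_window.dropna().items():
            assert order[w] <= order["1960-1969"] + 1

    def test_bimodal_truth_gives_bimodal_frequency(self, study):
        from legacylag.synthetic import TaxonSpec, generate_otu_table
        from legacylag.community import relative_abundance, transform_response
        specs = ([TaxonSpec(taxon_id=f"h{k}", effects=(
            ("PC1", "1960-1969", 0.8),)) for k in range(4)]
            + [TaxonSpec(taxon_id=f"c{k}", effects=(
                ("PC1", "contemporary", 0.8),)) for k in range(4)]
            + [TaxonSpec(taxon_id=f"b{k}") for k in range(20)])
        otu, _ = generate_otu_table(study.designs, study.scores, None,
                                    specs, depth=3000, seed=21)
        rel = relative_abundance(otu)
        responses = pd.DataFrame(
            {t: transform_response(rel[t], "logit")
             for t in [s.taxon_id for s in specs[:8]]}, index=otu.index)
        result = fit_many(responses, study.pool, max_size=2,
                          compute_lmg=False)
        freq = result.frequency["count"]
        middle = ["1970-1979", "1975-1984", "1980-1989", "1985-1994"]
        assert freq["1960-1969"] >= 3
        assert freq["contemporary"] >= 3
        assert freq[middle].max() <= min(freq["1960-1969"],
                                         freq["contemporary"])

    def test_lmg_attached_and_sums_to_r2(self, study):
        responses = pipeline.taxon_responses(study, ["sig00"])
        result = fit_many(responses, study.pool, max_size=2)
        model = result.models["sig00"]
        assert model.lmg is not None
        assert (model.lmg >= -1e-10).all()
        assert model.lmg.sum() == pytest.approx(model.r2, abs=1e-10)

    def test_selection_frequency_fractions(self, study):
        _, freq, result = pipeline.recover_lags(study, max_size=2)
        assert ((freq["fraction"] >= 0) & (freq["fraction"] <= 1)).all()
        assert freq["count"].sum() >= len(result.models)  # >=1 window each


@pytest.fixture(scope="module")
def raw_pool(study):
    return build_raw_pool(study.climatologies, study.designs,
                          study.schedule)


class TestTwoStep:
    def test_pool_has_120_candidates(self, raw_pool):
        assert len(raw_pool) == 120

    def test_perfect_raw_signal_recovered(self, study, raw_pool):
        clim = study.climatologies.xs("1960-1969", level="window")
        y = clim.loc[study.designs["site_id"], "pre"].to_numpy()
        winner = two_step_select(y, raw_pool, k_top=5, max_size=2)
        assert any(c.feature == "pre" and c.window == "1960-1969"
                   for c in winner.predictors)
        assert winner.loo_mse <= 1e-12

    def test_step2_confined_to_top_variables(self, study, raw_pool, rng):
        y = rng.normal(size=len(study.designs))
        winner = two_step_select(y, raw_pool, k_top=3, max_size=2)
        assert len({c.feature for c in winner.predictors}) <= 3

    def test_lag_attribution_concordant_with_pc_pool(self, study, raw_pool):
        """The raw-climatology route reaches the same conclusion as the
        PC route for most taxa: whether the taxon is associated with
        historic (pre-1980) climate at all. Exact earliest-window
        identity is not expected — sliding decades overlap by five years,
        so adjacent windows are strongly correlated."""

        def historic(windows):
            return any(w != "contemporary" and int(w.split("-")[0]) < 1980
                       for w in windows)

        responses = pipeline.taxon_responses(study)
        pc_result = fit_many(responses, study.pool, max_size=2,
                             compute_lmg=False)
        agree = 0
        for name in responses.columns:
            raw_winner = two_step_select(responses[name], raw_pool,
                                         k_top=5, max_size=2)
            pc_model = pc_result.models[name]
            agree += (historic(raw_winner.windows)
                      == historic(pc_model.windows))
        assert agree / len(responses.columns) >= 0.8
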