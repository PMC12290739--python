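import numpy as np
import pytest

from pcmrsa import (
    AliasingError,
    bic,
    condition_poi,
    default_candidates,
    greedy_best_first,
    ols_fit,
    reconstruct_us,
    sample_beta_patterns,
    target_similarity,
    vectorize,
    condition_similarity,
)
from pcmrsa.selection import EXACT_FIT_BIC


def normal_equations(y, X):
    """Hand-coded (X'X)^-1 X'y oracle."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    rss = float(((y - X @ beta) ** 2).sum())
    return beta, rss


class TestOLS:
    def test_exact_fit(self):
        poi = vectorize(condition_poi("Aversive Pressure")).values
        betas, rss = ols_fit(2.0 * poi, {"Aversive Pressure": poi})
        assert betas["Aversive Pressure"] == pytest.approx(2.0, abs=1e-12)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_single_centered_predictor_matches_normal_equations(self, rng):
        x = rng.normal(size=30)
        x -= x.mean()
        y = 0.7 * x + rng.normal(size=30)
        betas, rss = ols_fit(y, {"x": x})
        A = np.column_stack([np.ones(30), x])
        expected, expected_rss = normal_equations(y, A)
        assert betas["intercept"] == pytest.approx(expected[0], abs=1e-10)
        assert betas["x"] == pytest.approx(expected[1], abs=1e-10)
        assert rss == pytest.approx(expected_rss, abs=1e-10)
        # slope equals cov/var for a centered predictor
        assert betas["x"] == pytest.approx(np.cov(y, x, bias=True)[0, 1] / x.var(), abs=1e-10)

    def test_orthogonal_predictors_recovered_within_3_se(self, rng):
        a = vectorize(condition_poi("Appetitive Brush")).values
        b = vectorize(condition_poi("Aversive Pressure")).values
        y = 1.0 * a - 0.5 * b + rng.normal(0, 0.1, 15)
        betas, rss = ols_fit(y, {"a": a, "b": b})
        A = np.column_stack([np.ones(15), a, b])
        sigma2 = rss / (15 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
        assert abs(betas["a"] - 1.0) < 3 * se[1]
        assert abs(betas["b"] + 0.5) < 3 * se[2]

    def test_aliasing_reported_by_name(self):
        x = np.arange(10.0)
        with pytest.raises(AliasingError, match="x_copy"):
            ols_fit(x, {"x": x, "x_copy": 2 * x})

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones(2), {"a": np.arange(2.0), "b": np.arange(2.0) ** 2})


class TestBIC:
    def test_unit_mean_square(self):
        for n in (10, 15, 100):
            assert bic(float(n), n, 1) == pytest.approx(np.log(n), abs=1e-12)

    def test_additivity_in_k(self):
        assert bic(2.5, 20, 5) - bic(2.5, 20, 2) == pytest.approx(3 * np.log(20), abs=1e-12)

    def test_direct_arithmetic(self):
        assert bic(2.5, 15, 2) == pytest.approx(15 * np.log(2.5 / 15) + 2 * np.log(15), abs=1e-12)

    def test_exact_fit_sentinel_and_preconditions(self):
        assert bic(0.0, 10, 2) == EXACT_FIT_BIC
        with pytest.raises(ValueError):
            bic(1.0, 3, 3)
        with pytest.raises(ValueError):
            bic(-1.0, 10, 2)


class TestGreedy:
    def test_noise_free_single_poi_recovery(self, design, paired_idx):
        target = target_similarity({"Aversive Pressure": 0.4})
        betas = sample_beta_patterns(design, target, 2000, 0.0, seed=42)
        y = vectorize(condition_similarity(betas, paired_idx).values).values
        fit = greedy_best_first(y, default_candidates())
        assert fit.selected[0] == "Aversive Pressure"
        accepted = [t for t in fit.bic_trace if t.accepted]
        assert accepted[0].poi == "Aversive Pressure"

    def test_single_candidate_semantics(self, rng):
        poi = vectorize(condition_poi("Experimental Task")).values
        y = rng.normal(size=15)
        fit = greedy_best_first(y, {"Experimental Task": poi})
        base_bic = bic(float(((y - y.mean()) ** 2).sum()), 15, 2)
        _, rss1 = ols_fit(y, {"p": poi})
        cand_bic = bic(rss1, 15, 3)
        assert (fit.selected == ["Experimental Task"]) == (base_bic - cand_bic >= 2.0)

    def test_accepted_steps_respect_delta_rule(self, rng):
        cands = default_candidates()
        y = (
            0.5 * cands["Experimental Task"].values
            + 0.4 * cands["Aversive Pressure"].values
            + rng.normal(0, 0.05, 15)
        )
        fit = greedy_best_first(y, cands)
        accepted = [t.bic for t in fit.bic_trace if t.accepted]
        base = bic(float(((y - y.mean()) ** 2).sum()), 15, 2)
        trail = [base] + accepted
        assert all(prev - cur >= fit.delta for prev, cur in zip(trail, trail[1:]))

    def test_candidate_order_invariance(self, rng):
        cands = default_candidates()
        y = 0.6 * cands["Touch Valence"].values + rng.normal(0, 0.05, 15)
        fwd = greedy_best_first(y, cands)
        rev = greedy_best_first(y, dict(reversed(list(cands.items()))))
        assert set(fwd.selected) == set(rev.selected)

    def test_adding_predictors_never_increases_rss(self, rng):
        cands = default_candidates()
        y = rng.normal(size=15)
        rss_prev = ols_fit(y, {})[1]
        names = []
        for nm in ("Experimental Task", "Salience", "Positive Events"):
            names.append(nm)
            rss = ols_fit(y, {k: cands[k] for k in names})[1]
            assert rss <= rss_prev + 1e-12
            rss_prev = rss

    def test_all_aliased_candidates_warns_empty(self):
        const = np.ones(15)
        with pytest.warns(UserWarning, match="aliased"):
            fit = greedy_best_first(np.random.default_rng(0).normal(size=15),
                                    {"flat": const, "flat2": 2 * const})
        assert fit.selected == []


class TestReconstructUS:
    def test_identity_reconstruction(self, design, paired_idx):
        target = target_similarity({"Aversive Pressure": 0.4})
        betas = sample_beta_patterns(design, target, 2000, 0.0, seed=7)
        y = vectorize(condition_similarity(betas, paired_idx).values).values
        fit = greedy_best_first(y, default_candidates())
        fit.betas = {"intercept": 0.0, fit.selected[0]: 1.0}
        fit.selected = fit.selected[:1]
        rus = reconstruct_us(fit, level="condition")
        poi = condition_poi(fit.selected[0]).matrix
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_array_equal(rus.matrix[off], poi[off])
        assert np.isnan(np.diag(rus.matrix)).all()

    def test_weighted_sum_inner_product(self):
        from pcmrsa.selection import POIFitResult

        fit = POIFitResult(
            selected=["Appetitive Brush", "Aversive Pressure"],
            betas={"intercept": 0.0, "Appetitive Brush": 2.0, "Aversive Pressure": -1.0},
            bic_trace=[], n_obs=15, rss=0.0,
        )
        rus = reconstruct_us(fit, level="condition")
        v = vectorize(rus.matrix).values
        a = vectorize(condition_poi("Appetitive Brush")).values
        assert float(v @ a) / float(a @ a) == pytest.approx(2.0, abs=1e-12)

    def test_empty_fit_rejected(self):
        from pcmrsa.selection import POIFitResult

        empty = POIFitResult(selected=[], betas={"intercept": 0.1}, bic_trace=[], n_obs=15, rss=1.0)
        with pytest.raises(ValueError):
            reconstruct_us(empty)

    def test_trial_level_reconstruction(self, design, paired_idx):
        from pcmrsa.selection import POIFitResult

        fit = POIFitResult(
            selected=["Experimental Task"],
            betas={"intercept": 0.1, "Experimental Task": 0.5},
            bic_trace=[], n_obs=15, rss=0.0,
        )
        rus = reconstruct_us(fit, level="trial", trial_table=design, trial_subset=paired_idx)
        assert rus.matrix.shape == (len(paired_idx), len(paired_idx))
        # cross-task trial pair: intercept only
        assert rus.matrix[0, -1] == pytest.approx(0.1)
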