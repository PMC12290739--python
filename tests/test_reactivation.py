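import numpy as np
import pandas as pd
import pytest

from pcmrsa import (
    BetaPatternSet,
    ReactivationConfig,
    bayes_lm,
    consistency_check,
    gg_epsilon,
    ols_fit,
    reactivation_pipeline,
    rm_anova,
    rus_cs_correlation,
    simulate_cohort,
    target_similarity,
    vectorize,
)
from pcmrsa.reactivation import PosteriorSummary
from pcmrsa.selection import POIFitResult, ReconstructedUS, reconstruct_us


def anova_ss_oracle(X):
    """Literal sums-of-squares decomposition, written independently."""
    n, k = X.shape
    grand = X.mean()
    ss_time = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_time - ss_subj
    F = (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return F, ss_time, ss_err


class TestRusCsCorrelation:
    def _rus(self, m):
        fit = POIFitResult(selected=["x"], betas={}, bic_trace=[], n_obs=0, rss=0.0)
        mm = m.copy()
        np.fill_diagonal(mm, np.nan)
        return ReconstructedUS(matrix=mm, labels=list(range(len(m))), level="trial", source_fit=fit)

    def _sim(self, m):
        from pcmrsa import SimilarityMatrix

        mm = m.copy()
        np.fill_diagonal(mm, np.nan)
        return SimilarityMatrix(values=mm, labels=list(range(len(m))))

    def test_self_and_sign_flip(self, rng):
        m = rng.normal(size=(5, 5))
        m = m + m.T
        assert rus_cs_correlation(self._rus(m), self._sim(m)) == pytest.approx(1.0)
        assert rus_cs_correlation(self._rus(m), self._sim(-m)) == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self, rng):
        a = rng.normal(size=(6, 6))
        a = a + a.T
        b = rng.normal(size=(6, 6))
        b = b + b.T
        va, vb = vectorize(a).values, vectorize(b).values
        expected = (
            ((va - va.mean()) * (vb - vb.mean())).sum()
            / np.sqrt(((va - va.mean()) ** 2).sum() * ((vb - vb.mean()) ** 2).sum())
        )
        assert rus_cs_correlation(self._rus(a), self._sim(b)) == pytest.approx(expected, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        a = rng.normal(size=(5, 5)); a = a + a.T
        b = rng.normal(size=(5, 5)); b = b + b.T
        r0 = rus_cs_correlation(self._rus(a), self._sim(b))
        r1 = rus_cs_correlation(self._rus(0.5 + 2.0 * a), self._sim(1.0 + 3.0 * b))
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_support_mismatch_and_min_pairs(self, rng):
        m = rng.normal(size=(5, 5)); m = m + m.T
        sim = self._sim(m)
        sim.labels = list(range(1, 6))
        with pytest.raises(ValueError, match="support"):
            rus_cs_correlation(self._rus(m), sim)
        small = rng.normal(size=(2, 2)); small = small + small.T
        with pytest.raises(ValueError, match="3"):
            rus_cs_correlation(self._rus(small), self._sim(small))


class TestRmAnova:
    def test_uncorrected_df_for_study_sized_cohort(self, rng):
        table = rm_anova(rng.normal(size=(71, 3)), correct="never")
        assert (table.df1, table.df2) == (2.0, 140.0)

    def test_matches_ss_oracle(self, rng):
        X = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        table = rm_anova(X, correct="never")
        F, ss_time, ss_err = anova_ss_oracle(X)
        assert table.F == pytest.approx(F, abs=1e-10)
        assert table.eta_sq == pytest.approx(ss_time / (ss_time + ss_err), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "subject": np.repeat(np.arange(10), 3),
                "time": np.tile(np.arange(3), 10),
            }
        )
        pg = pingouin.rm_anova(data=long, dv="y", within="time", subject="subject",
                               correction=True, detailed=True)
        ours = rm_anova(X, correct="never")
        assert ours.F == pytest.approx(float(pg.loc[0, "F"]), abs=1e-8)
        assert ours.p == pytest.approx(float(pg.loc[0, "p_unc"]), abs=1e-8)
        assert ours.epsilon == pytest.approx(float(pg.loc[0, "eps"]), abs=1e-8)

    def test_correction_shrinks_df_and_raises_p(self, rng):
        base = rng.normal(size=(12, 1))
        X = np.column_stack([base + rng.normal(scale=s, size=(12, 1)) for s in (0.1, 0.5, 2.0)])
        never = rm_anova(X, correct="never")
        always = rm_anova(X, correct="always")
        assert always.epsilon < 1
        assert always.df1 == pytest.approx(always.epsilon * never.df1)
        assert always.p >= never.p
        assert 0 <= always.eta_sq <= 1 and always.F >= 0

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova(np.tile(np.array([[1.0, 2.0, 3.0]]), (4, 1)))
        with pytest.raises(ValueError):
            rm_anova(np.ones((1, 3)))
        with pytest.raises(ValueError):
            rm_anova(np.array([[1.0, np.nan, 2.0], [0.0, 1.0, 2.0]]))


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 0.4 * np.ones((4, 4)) + 0.6 * np.eye(4)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_two_levels_always_one(self, rng):
        a = rng.normal(size=(2, 2))
        assert gg_epsilon(a @ a.T) == 1.0

    def test_matches_literal_box_formula(self, rng):
        a = rng.normal(size=(3, 3))
        S = a @ a.T
        k = 3
        C = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(C @ S @ C)
        expected = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert gg_epsilon(S) == pytest.approx(expected, abs=1e-12)

    def test_clipped_to_lower_bound(self):
        S = np.diag([1.0, 1e-12, 1e-12])
        assert gg_epsilon(S) >= 1 / 2


class TestBayesLM:
    def test_noise_free_exact_fit_limit(self, rng):
        x = rng.normal(size=60)
        post = bayes_lm(2.0 * x, {"x": x}, n_draws=20_000, seed=0)
        assert post["x"].mean_beta == pytest.approx(2.0, abs=1e-3)

    def test_flat_prior_limit_matches_ols(self, rng):
        x1, x2 = rng.normal(size=(2, 200))
        y = 0.3 + 1.2 * x1 - 0.4 * x2 + rng.normal(size=200)
        post = bayes_lm(y, {"x1": x1, "x2": x2}, n_draws=50_000, seed=1)
        ols, _ = ols_fit(y, {"x1": x1, "x2": x2})
        for nm in ("intercept", "x1", "x2"):
            assert post[nm].mean_beta == pytest.approx(ols[nm], abs=0.01)
            assert post[nm].cri_low < ols[nm] < post[nm].cri_high

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        a = bayes_lm(y, {"x": x}, n_draws=2000, seed=3)
        b = bayes_lm(y, {"x": x}, n_draws=2000, seed=3)
        assert a["x"].mean_beta == b["x"].mean_beta
        assert (a["x"].cri_low, a["x"].cri_high) == (b["x"].cri_low, b["x"].cri_high)

    def test_input_validation(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="n_draws"):
            bayes_lm(x, {"x": x}, n_draws=500)
        from pcmrsa import AliasingError

        with pytest.raises(AliasingError):
            bayes_lm(x, {"flat": np.ones(50)}, n_draws=2000)


class TestConsistency:
    def _interval(self, lo, hi):
        return PosteriorSummary("p", "US", (lo + hi) / 2, lo, hi, 1000)

    def test_interior_boundary_exterior(self):
        assert consistency_check(0.5, self._interval(0.2, 0.8)).consistent
        assert consistency_check(0.8, self._interval(0.2, 0.8)).consistent  # closed boundary
        assert not consistency_check(0.9, self._interval(0.2, 0.8)).consistent


class TestReactivationPipeline:
    MIX = {"Experimental Task": 0.4, "Aversive Pressure": 0.3}

    def _targets(self, early=0.0, mid=0.5, late=1.0):
        return {
            "paired": target_similarity(self.MIX),
            "early": target_similarity({k: v * early for k, v in self.MIX.items()}),
            "mid": target_similarity({k: v * mid for k, v in self.MIX.items()}),
            "late": target_similarity({k: v * late for k, v in self.MIX.items()}),
        }

    def test_injected_shift_increases_correlation_and_flags_transition(self, design):
        cohort = simulate_cohort(design, self._targets(), 12, 300, 0.5, seed=11)
        res = reactivation_pipeline(cohort, ReactivationConfig(n_draws=20_000, seed=11))
        assert res.errors == []
        assert set(self.MIX) <= set(res.fit.selected)
        means = res.correlations.mean()
        assert means["early"] < means["mid"] < means["late"]
        assert res.anova.p < 0.05
        ap = {
            (f.point_dataset, f.interval_dataset): f
            for f in res.consistency
            if f.poi_name == "Aversive Pressure"
        }
        # the raised mid/late contribution falls outside the early interval
        assert not ap[("mid", "early")].consistent
        assert not ap[("late", "early")].consistent
        assert ap[("mid", "early")].point > ap[("mid", "early")].cri_high

    def test_null_cohort_type_one_error_rate(self, design):
        """No phase effect: the global RM-ANOVA rejects at about its nominal rate."""
        tgt = target_similarity({"Experimental Task": 0.3})
        targets = {k: tgt for k in ("paired", "early", "mid", "late")}
        rej = 0
        n_cohorts = 200
        cfg = ReactivationConfig(run_components=False)
        for s in range(n_cohorts):
            cohort = simulate_cohort(design, targets, 8, 120, 0.0, seed=s)
            res = reactivation_pipeline(cohort, cfg)
            rej += res.anova.p < 0.05
        assert 0.01 <= rej / n_cohorts <= 0.10

    def test_single_subject_paired_only_partial_contract(self, design):
        paired = design[design["block_type"] == "paired"].reset_index(drop=True).copy()
        paired["trial_index"] = np.arange(len(paired))
        from pcmrsa import sample_beta_patterns

        betas = sample_beta_patterns(paired, target_similarity(self.MIX), 300, 0.3, seed=2)
        res = reactivation_pipeline([betas], ReactivationConfig(n_draws=2000, seed=0))
        assert res.anova is None and res.correlations is None
        assert any("global stage" in e for e in res.errors)
        assert set(res.posteriors) == {"rUS"}

    def test_missing_paired_data_raises(self, design, rng):
        unpaired = design[design["block_type"] == "unpaired"].reset_index(drop=True).copy()
        unpaired["trial_index"] = np.arange(len(unpaired))
        betas = BetaPatternSet(values=rng.normal(size=(len(unpaired), 20)), trial_table=unpaired)
        with pytest.raises(ValueError, match="paired"):
            reactivation_pipeline([betas])
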