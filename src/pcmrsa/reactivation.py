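"""Global and component-wise reactivation of the US pattern by CS data.

Global reactivation: per subject, the reconstructed US (rUS) similarity
structure estimated from paired-block data is correlated with the
similarity structure of unpaired-block CS data at early, mid and late
stages of conditioning; the correlations enter a one-way repeated-measures
ANOVA with time point as the within-subject factor (Greenhouse-Geisser
corrected when sphericity is doubtful).

Component reactivation: the US-identified POIs are used as predictors in
Bayesian linear models of the rUS structure and of each phase's CS
structure; a POI's contribution at time point X is deemed consistent with
dataset Y when the point estimate from X falls inside Y's 95% credible
interval, and different when it falls outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pois import ModelVector, SalienceConfig, condition_poi, vectorize
from .rsa import BetaPatternSet, SimilarityMatrix, condition_similarity
from .selection import (
    AliasingError,
    POIFitResult,
    ReconstructedUS,
    default_candidates,
    greedy_best_first,
    ols_fit,
    reconstruct_us,
)
from .synthetic import DEFAULT_SPLIT, PHASES, phase_trial_indices


# --------------------------------------------------------------------------
# global reactivation: rUS-CS correlation and repeated-measures ANOVA
# --------------------------------------------------------------------------

def rus_cs_correlation(rus: ReconstructedUS, cs_sim: SimilarityMatrix) -> float:
    """Pearson correlation of the vectorized upper triangles of rUS and CS data."""
    if list(rus.labels) != list(cs_sim.labels):
        raise ValueError(
            f"support mismatch: rUS labels {rus.labels} vs CS labels {cs_sim.labels}"
        )
    a = vectorize(rus.matrix).values
    b = vectorize(cs_sim.values).values
    if len(a) < 3:
        raise ValueError("need at least 3 off-diagonal pairs")
    return float(np.corrcoef(a, b)[0, 1])


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k timepoint covariance.

    Box's formula on the double-centered covariance S_c = C S C with
    C = I - J/k: eps = tr(S_c)^2 / ((k-1) * tr(S_c^2)), clipped to
    [1/(k-1), 1].  Equals 1 exactly under compound symmetry or k = 2.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need k >= 2 timepoints")
    if np.abs(S - S.T).max() > 1e-10:
        raise ValueError("covariance must be symmetric")
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    denom = (k - 1) * np.trace(Sc @ Sc)
    if denom <= 0:
        return 1.0
    eps = np.trace(Sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


@dataclass
class AnovaTable:
    """One-way within-subject ANOVA result (optionally GG-corrected)."""

    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float
    epsilon: float
    corrected: bool
    ss_time: float = 0.0
    ss_error: float = 0.0


def rm_anova(data: np.ndarray, correct: str = "auto") -> AnovaTable:
    """One-way repeated-measures ANOVA on an n_subjects x k_timepoints matrix.

    Standard two-way (subject x time) decomposition without replication:
    F = MS_time / MS_error with df (k-1, (k-1)(n-1)); eta^2 is partial,
    SS_time / (SS_time + SS_error).  ``correct`` is the sphericity policy:
    'auto' applies the Greenhouse-Geisser correction when epsilon < 0.95,
    'always'/'never' force it on/off.  Corrected dfs are eps * uncorrected.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be n_subjects x k_timepoints")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 timepoints, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("missing cells are not supported")
    if correct not in ("auto", "always", "never"):
        raise ValueError("correct must be auto/always/never")

    grand = X.mean()
    ss_time = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_time - ss_subj
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    if ss_error <= 0:
        raise ValueError("degenerate data: zero residual variability")
    F = (ss_time / df1) / (ss_error / df2)
    eta = ss_time / (ss_time + ss_error)

    eps = gg_epsilon(np.cov(X, rowvar=False))
    corrected = correct == "always" or (correct == "auto" and eps < 0.95)
    if corrected:
        df1, df2 = eps * df1, eps * df2
    p = float(stats.f.sf(F, df1, df2))
    return AnovaTable(
        F=float(F), df1=float(df1), df2=float(df2), p=p, eta_sq=float(eta),
        epsilon=float(eps), corrected=corrected,
        ss_time=float(ss_time), ss_error=float(ss_error),
    )


# --------------------------------------------------------------------------
# component reactivation: Bayesian linear model and consistency rule
# --------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior mean and central 95% credible interval for one coefficient."""

    poi_name: str
    dataset: str
    mean_beta: float
    cri_low: float
    cri_high: float
    n_draws: int


def bayes_lm(
    y,
    X: dict[str, object],
    n_draws: int = 1_000_000,
    seed=None,
    dataset: str = "data",
    prior_scale: float = 10.0,
) -> dict[str, PosteriorSummary]:
    """Bayesian linear model with a conjugate normal-inverse-gamma prior.

    Coefficient prior: beta_j | sigma^2 ~ N(0, sigma^2 (prior_scale/sd_xj)^2)
    — a weak prior whose conditional sd is about prior_scale * sd_y / sd_xj
    at sigma ~ sd_y — with a diffuse intercept (scale 100) and
    sigma^2 ~ IG(0.001, 0.001).  The posterior is sampled exactly
    (sigma^2 from its marginal inverse gamma, beta | sigma^2 Gaussian), so
    the summaries are seeded and reproducible.  Returns one
    :class:`PosteriorSummary` per predictor plus the intercept.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    yv = np.asarray(y.values if isinstance(y, ModelVector) else y, dtype=float)
    names = ["intercept"] + list(X)
    cols = [np.ones(len(yv))]
    scales = [100.0]
    for nm, v in X.items():
        c = np.asarray(v.values if isinstance(v, ModelVector) else v, dtype=float)
        sd = c.std()
        if sd == 0:
            raise AliasingError([nm])
        cols.append(c)
        scales.append(prior_scale / sd)
    A = np.column_stack(cols)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"need n_obs > predictors ({n} <= {p})")
    # rank check (aliasing beyond the per-column zero-variance case)
    _, r = np.linalg.qr(A)
    aliased = [names[j] for j in range(p) if abs(r[j, j]) < 1e-10 * max(1.0, np.abs(r).max())]
    if aliased:
        raise AliasingError(aliased)

    V0_inv = np.diag(1.0 / np.square(scales))
    Vn = np.linalg.inv(V0_inv + A.T @ A)
    mn = Vn @ (A.T @ yv)
    a0 = b0 = 0.001
    an = a0 + n / 2.0
    bn = b0 + 0.5 * float(yv @ yv - mn @ (V0_inv + A.T @ A) @ mn)
    bn = max(bn, 1e-300)  # guard exact fits

    rng = np.random.default_rng(seed)
    sigma2 = bn / rng.gamma(an, 1.0, size=n_draws)
    L = np.linalg.cholesky((Vn + Vn.T) / 2)
    z = rng.standard_normal((n_draws, p))
    draws = mn + (z @ L.T) * np.sqrt(sigma2)[:, None]

    out = {}
    for j, nm in enumerate(names):
        lo, hi = np.quantile(draws[:, j], (0.025, 0.975))
        out[nm] = PosteriorSummary(
            poi_name=nm, dataset=dataset,
            mean_beta=float(draws[:, j].mean()),
            cri_low=float(lo), cri_high=float(hi), n_draws=n_draws,
        )
    return out


@dataclass
class ConsistencyFlag:
    """Is dataset X's point estimate inside dataset Y's credible interval?"""

    poi_name: str
    point_dataset: str
    interval_dataset: str
    point: float
    cri_low: float
    cri_high: float
    consistent: bool


def consistency_check(point: float, interval: PosteriorSummary) -> ConsistencyFlag:
    """Closed-interval membership: consistent iff cri_low <= point <= cri_high."""
    if not interval.cri_low <= interval.cri_high:
        raise ValueError("malformed credible interval")
    return ConsistencyFlag(
        poi_name=interval.poi_name,
        point_dataset="point",
        interval_dataset=interval.dataset,
        point=float(point),
        cri_low=interval.cri_low,
        cri_high=interval.cri_high,
        consistent=bool(interval.cri_low <= point <= interval.cri_high),
    )


# --------------------------------------------------------------------------
# end-to-end reactivation pipeline
# --------------------------------------------------------------------------

@dataclass
class ReactivationConfig:
    """Knobs of the reactivation analysis (defaults follow the study design)."""

    delta: float = 2.0
    candidates: list[str] | None = None  # default: all condition-level POIs
    component_pois: list[str] | None = None  # default: the selected set
    selection_on: str = "average"  # 'average' or 'per_subject'
    split: dict[str, tuple[int, ...]] = field(default_factory=lambda: dict(DEFAULT_SPLIT))
    cs_subset: str = "all"  # unpaired data include CS+ and CS- by default
    sphericity: str = "auto"
    n_draws: int = 1_000_000
    prior_scale: float = 10.0
    salience: SalienceConfig | None = None
    seed: int = 0
    run_components: bool = True


@dataclass
class ReactivationResult:
    fit: POIFitResult
    subject_betas: dict[str, dict[str, float]]
    correlations: pd.DataFrame | None  # subjects x phases
    anova: AnovaTable | None
    posteriors: dict[str, dict[str, PosteriorSummary]]  # dataset -> poi -> summary
    consistency: list[ConsistencyFlag]
    errors: list[str]
    config: ReactivationConfig


def _paired_indices(table: pd.DataFrame) -> np.ndarray:
    return table.loc[table["block_type"] == "paired", "trial_index"].to_numpy()


def reactivation_pipeline(
    subjects: list[BetaPatternSet],
    config: ReactivationConfig | None = None,
) -> ReactivationResult:
    """Run the full reactivation analysis for one ROI.

    Stages: per-subject paired-block condition similarity -> greedy BIC
    selection (on the subject-averaged vector by default) -> per-subject
    weight re-estimation and rUS -> per-phase unpaired similarity ->
    global RM-ANOVA on rUS-CS correlations -> Bayesian component models
    with pairwise consistency flags.  Recoverable stage failures (e.g. no
    unpaired data) are recorded in ``errors`` while the remaining stages
    run; hard contract violations (missing paired data) raise.
    """
    config = config or ReactivationConfig()
    if not subjects:
        raise ValueError("need at least one subject")
    errors: list[str] = []

    candidates = default_candidates(salience=config.salience, names=config.candidates)

    # --- paired-block similarity and selection -----------------------------
    paired_vecs = []
    for s in subjects:
        idx = _paired_indices(s.trial_table)
        if idx.size == 0:
            raise ValueError(f"subject {s.subject_id} has no paired-block data")
        sim = condition_similarity(s, idx)
        paired_vecs.append(vectorize(sim.values))
    y_avg = np.mean([v.values for v in paired_vecs], axis=0)

    if config.selection_on == "average":
        fit = greedy_best_first(y_avg, candidates, delta=config.delta)
    elif config.selection_on == "per_subject":
        # select on each subject, keep POIs chosen for a majority
        counts: dict[str, int] = {}
        for v in paired_vecs:
            for nm in greedy_best_first(v.values, candidates, delta=config.delta).selected:
                counts[nm] = counts.get(nm, 0) + 1
        keep = [nm for nm in candidates if counts.get(nm, 0) > len(subjects) / 2]
        fit = greedy_best_first(y_avg, {nm: candidates[nm] for nm in keep} or candidates,
                                delta=config.delta)
    else:
        raise ValueError("selection_on must be 'average' or 'per_subject'")

    if not fit.selected:
        errors.append("selection is empty: no POI improved BIC by >= delta")
        return ReactivationResult(fit, {}, None, None, {}, [], errors, config)

    subject_betas = {}
    rus_by_subject = {}
    for s, v in zip(subjects, paired_vecs):
        betas, _ = ols_fit(v.values, {nm: candidates[nm] for nm in fit.selected})
        subject_betas[s.subject_id] = betas
        rus_by_subject[s.subject_id] = reconstruct_us(
            fit, level="condition", salience=config.salience, betas=betas
        )

    # --- per-phase unpaired similarity and global ANOVA --------------------
    phase_sims: dict[str, list[SimilarityMatrix]] = {}
    correlations = None
    anova = None
    try:
        rows = {}
        for s in subjects:
            phases = phase_trial_indices(s.trial_table, split=config.split,
                                         cs_subset=config.cs_subset)
            row = {}
            for phase in config.split:
                idx = phases[phase]
                if idx.size < 2:
                    raise ValueError(f"phase {phase!r} has fewer than 2 trials")
                sim = condition_similarity(s, idx)
                phase_sims.setdefault(phase, []).append(sim)
                rus = rus_by_subject[s.subject_id]
                keep = [rus.labels.index(l) for l in sim.labels]
                rus_sub = ReconstructedUS(
                    matrix=rus.matrix[np.ix_(keep, keep)],
                    labels=list(sim.labels), level="condition", source_fit=fit,
                )
                row[phase] = rus_cs_correlation(rus_sub, sim)
            rows[s.subject_id] = row
        correlations = pd.DataFrame.from_dict(rows, orient="index")[list(config.split)]
        anova = rm_anova(correlations.to_numpy(), correct=config.sphericity)
    except ValueError as exc:
        errors.append(f"global stage: {exc}")

    # --- component reactivation --------------------------------------------
    posteriors: dict[str, dict[str, PosteriorSummary]] = {}
    consistency: list[ConsistencyFlag] = []
    if config.run_components:
        comp_names = list(config.component_pois or fit.selected)
        rng = np.random.default_rng(config.seed)
        datasets: dict[str, tuple[np.ndarray, list]] = {}
        rus_mean = np.mean(
            [vectorize(r.matrix).values for r in rus_by_subject.values()], axis=0
        )
        datasets["rUS"] = (rus_mean, list(rus_by_subject[subjects[0].subject_id].labels))
        for phase, sims in phase_sims.items():
            datasets[phase] = (
                np.mean([vectorize(m.values).values for m in sims], axis=0),
                list(sims[0].labels),
            )
        for name, (yv, labels) in datasets.items():
            X = {}
            for nm in comp_names:
                poi = condition_poi(nm, salience=config.salience)
                sel = [poi.labels.index(l) for l in labels]
                X[nm] = vectorize(poi.matrix[np.ix_(sel, sel)]).values
            try:
                posteriors[name] = bayes_lm(
                    yv, X, n_draws=config.n_draws, seed=rng.integers(2**31),
                    dataset=name, prior_scale=config.prior_scale,
                )
            except (AliasingError, ValueError) as exc:
                errors.append(f"component stage ({name}): {exc}")
        for nm in comp_names:
            for dx in posteriors:
                for dy in posteriors:
                    if dx == dy or nm not in posteriors[dx] or nm not in posteriors[dy]:
                        continue
                    flag = consistency_check(posteriors[dx][nm].mean_beta, posteriors[dy][nm])
                    flag.point_dataset = dx
                    consistency.append(flag)

    return ReactivationResult(
        fit=fit,
        subject_betas=subject_betas,
        correlations=correlations,
        anova=anova,
        posteriors=posteriors,
        consistency=consistency,
        errors=errors,
        config=config,
    )
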