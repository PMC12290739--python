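"""Greedy best-first BIC selection of POI combinations and US reconstruction.

The observed (vectorized) similarity structure is modeled as a linear
combination of POI model vectors plus an intercept.  Selection proceeds
best-first: level 1 fits each candidate alone and keeps the lowest-BIC
POI; each subsequent level tries adding every remaining candidate to the
kept set and accepts the best addition iff it lowers BIC by at least
``delta`` (default 2).  Final weights come from one multiple regression
on the selected set.  The reconstructed US (rUS) pattern is the
beta-weighted sum of the selected POI matrices, a denoised stand-in for
the US-evoked similarity structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pois import (
    CONDITION_POIS,
    ModelVector,
    POIMatrix,
    SalienceConfig,
    condition_poi,
    expand_to_trials,
    vectorize,
)

_ALIAS_TOL = 1e-10
_TIE_TOL = 1e-9

EXACT_FIT_BIC = -np.inf


class AliasingError(ValueError):
    """Raised when predictors are collinear beyond tolerance."""

    def __init__(self, names):
        self.names = list(names)
        super().__init__(f"aliased/collinear predictors: {self.names}")


@dataclass
class BICStep:
    step: int
    poi: str
    bic: float
    accepted: bool


@dataclass
class POIFitResult:
    """Outcome of greedy selection plus the final multiple regression."""

    selected: list[str]
    betas: dict[str, float]  # selected POIs plus 'intercept'
    bic_trace: list[BICStep]
    n_obs: int
    rss: float
    delta: float = 2.0
    exact_fit: bool = False


def _as_array(v) -> np.ndarray:
    return np.asarray(v.values if isinstance(v, ModelVector) else v, dtype=float)


def ols_fit(
    y,
    X: dict[str, object],
    include_intercept: bool = True,
) -> tuple[dict[str, float], float]:
    """Least squares of y on named predictor vectors.

    Returns (betas, rss) with betas keyed by predictor name (plus
    'intercept').  Rank-deficient designs raise :class:`AliasingError`
    naming the aliased predictors (identified via QR pivoting order:
    a column whose projection onto the span of earlier columns leaves
    negligible residual norm is aliased).
    """
    yv = _as_array(y)
    names = list(X)
    cols = [_as_array(v) for v in X.values()]
    n = len(yv)
    for nm, c in zip(names, cols):
        if len(c) != n:
            raise ValueError(f"predictor {nm!r} length {len(c)} != n obs {n}")
    if include_intercept:
        names = ["intercept"] + names
        cols = [np.ones(n)] + cols
    if n <= len(cols):
        raise ValueError(f"need n > number of predictors ({n} <= {len(cols)})")
    A = np.column_stack(cols) if cols else np.empty((n, 0))

    # detect aliasing: sequential residual norms via QR
    q, r = np.linalg.qr(A)
    col_norms = np.linalg.norm(A, axis=0)
    scale = max(col_norms.max(initial=0.0), 1.0)
    aliased = [names[j] for j in range(A.shape[1]) if abs(r[j, j]) < _ALIAS_TOL * scale]
    if aliased:
        raise AliasingError(aliased)

    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    rss = float(resid @ resid)
    return dict(zip(names, beta.tolist())), rss


def bic(rss: float, n: int, k: int) -> float:
    """Gaussian profile-likelihood BIC: n*ln(rss/n) + k*ln(n).

    ``k`` counts all estimated parameters (slopes + intercept + residual
    variance).  An exact fit (rss = 0) returns ``-inf`` as a sentinel.
    """
    if n <= k:
        raise ValueError(f"need n > k ({n} <= {k})")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return EXACT_FIT_BIC
    return float(n * np.log(rss / n) + k * np.log(n))


def _model_bic(y, X: dict, n: int) -> tuple[float, dict, float]:
    betas, rss = ols_fit(y, X, include_intercept=True)
    # k = slopes + intercept + residual variance
    return bic(rss, n, len(X) + 2), betas, rss


def greedy_best_first(
    y,
    candidates: dict[str, object],
    delta: float = 2.0,
) -> POIFitResult:
    """Select the POI combination minimizing BIC by greedy best-first search.

    ``candidates`` maps POI name -> model vector; insertion order is the
    registry order used to break BIC ties (within 1e-9) deterministically.
    An addition is accepted iff it lowers the current BIC by >= delta;
    level 1 competes against the intercept-only model under the same
    rule.  Candidates aliased with the current model are skipped; if all
    candidates alias the intercept the selection is empty (with a warning).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    yv = _as_array(y)
    if not np.isfinite(yv).all():
        raise ValueError("y must be finite")
    n = len(yv)

    current_bic, current_betas, current_rss = _model_bic(yv, {}, n)
    selected: list[str] = []
    remaining = dict(candidates)
    trace: list[BICStep] = []
    step = 0

    while remaining:
        step += 1
        scores: list[tuple[float, str]] = []
        evals: dict[str, tuple[float, dict, float]] = {}
        for name, vec in remaining.items():
            trial_X = {s: candidates[s] for s in selected}
            trial_X[name] = vec
            try:
                b, betas, rss = _model_bic(yv, trial_X, n)
            except AliasingError:
                continue
            except ValueError:
                continue  # e.g. too few observations for a larger model
            scores.append((b, name))
            evals[name] = (b, betas, rss)
            trace.append(BICStep(step=step, poi=name, bic=b, accepted=False))
        if not scores:
            if not selected:
                warnings.warn("all candidates aliased with the intercept; empty selection")
            break
        best_bic = min(b for b, _ in scores)
        # deterministic tie-break: first candidate (registry order) within tolerance
        best_name = next(nm for b, nm in scores if b <= best_bic + _TIE_TOL)
        best_bic = evals[best_name][0]
        if current_bic - best_bic >= delta:
            selected.append(best_name)
            current_bic, current_betas, current_rss = evals[best_name]
            for t in trace:
                if t.step == step and t.poi == best_name:
                    t.accepted = True
            del remaining[best_name]
            if current_bic == EXACT_FIT_BIC:
                break  # exact fit: nothing left to explain
        else:
            break

    if selected:
        betas, rss = ols_fit(yv, {s: candidates[s] for s in selected}, include_intercept=True)
    else:
        betas, rss = ols_fit(yv, {}, include_intercept=True)
    return POIFitResult(
        selected=selected,
        betas=betas,
        bic_trace=trace,
        n_obs=n,
        rss=rss,
        delta=delta,
        exact_fit=(rss == 0.0),
    )


@dataclass
class ReconstructedUS:
    """Beta-weighted sum of selected POI matrices (+ intercept off-diagonal)."""

    matrix: np.ndarray  # diagonal masked (NaN)
    labels: list
    level: str
    source_fit: POIFitResult


def reconstruct_us(
    fit: POIFitResult,
    level: str = "condition",
    trial_table: pd.DataFrame | None = None,
    trial_subset=None,
    salience: SalienceConfig | None = None,
    betas: dict[str, float] | None = None,
) -> ReconstructedUS:
    """Build the rUS matrix from a fit at condition or trial level.

    ``betas`` overrides the fit's weights (used when weights are
    re-estimated per subject on a shared selection).  The intercept is
    applied uniformly to the off-diagonal support; the diagonal is masked.
    """
    if not fit.selected:
        raise ValueError("cannot reconstruct from an empty selection")
    betas = betas if betas is not None else fit.betas
    mats: list[POIMatrix] = []
    for name in fit.selected:
        if name not in betas:
            raise KeyError(f"no beta for selected POI {name!r}")
        if level == "condition":
            mats.append(condition_poi(name, salience=salience))
        elif level == "trial":
            if trial_table is None:
                raise ValueError("trial-level reconstruction needs a trial_table")
            mats.append(expand_to_trials(name, trial_table, trial_subset, salience=salience))
        else:
            raise ValueError("level must be 'condition' or 'trial'")
    t = len(mats[0].matrix)
    out = np.full((t, t), float(betas.get("intercept", 0.0)))
    for name, poi in zip(fit.selected, mats):
        out += betas[name] * poi.matrix
    np.fill_diagonal(out, np.nan)
    return ReconstructedUS(matrix=out, labels=mats[0].labels, level=level, source_fit=fit)


def default_candidates(
    salience: SalienceConfig | None = None,
    names: list[str] | None = None,
) -> dict[str, ModelVector]:
    """Vectorized condition-level POI candidates in registry order."""
    names = list(names) if names is not None else list(CONDITION_POIS)
    return {n: vectorize(condition_poi(n, salience=salience)) for n in names}
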