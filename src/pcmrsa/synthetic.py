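"""Synthetic voxel patterns with a known representational structure.

The generator inverts the modeling direction of the POI analysis: given a
weighted mixture of POI matrices it builds a target condition-level
correlation structure, then draws voxel patterns whose empirical
condition correlations converge to that target as the voxel count grows.
The generative model is condition-means-plus-noise: each voxel's 6-vector
of condition means is one draw from a zero-mean multivariate normal with
the target as covariance, and each trial adds independent Gaussian noise
to its condition mean.  No hemodynamics are simulated — the pipeline
consumes beta patterns, not time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITIONS, unpaired_block_ordinal
from .pois import SalienceConfig, condition_poi
from .rsa import BetaPatternSet

#: Phase assignment of the seven unpaired blocks used throughout: the
#: first two precede/straddle initial learning, the final two probe the
#: consolidated association.
DEFAULT_SPLIT: dict[str, tuple[int, ...]] = {
    "early": (1, 2),
    "mid": (3, 4, 5),
    "late": (6, 7),
}

PHASES = ("early", "mid", "late")

_PSD_TOL = 1e-8


@dataclass
class ConditionCovariance:
    """Target 6x6 condition correlation structure for the generator."""

    matrix: np.ndarray
    labels: list
    projection_changed: bool = False
    no_structure: bool = False


def target_similarity(
    poi_weights: dict[str, float],
    baseline: float = 1.0,
    salience: SalienceConfig | None = None,
    tol: float = _PSD_TOL,
) -> ConditionCovariance:
    """Compose a PSD condition correlation matrix from a POI mixture.

    Off-diagonal entries are sum(w_i * POI_i) / baseline; the result is
    projected to the nearest positive-semidefinite correlation matrix by
    clipping negative eigenvalues at zero and rescaling to unit diagonal.
    ``projection_changed`` reports whether projection moved any entry by
    more than ``tol`` (e.g. when mixture weights push entries past the
    correlation bounds); ``no_structure`` flags an all-zero off-diagonal.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    k = len(CONDITIONS)
    m = np.zeros((k, k))
    for name, w in poi_weights.items():
        m += w * condition_poi(name, salience=salience).matrix  # KeyError/ValueError if unknown
    corr0 = m / baseline
    np.fill_diagonal(corr0, 1.0)

    vals, vecs = np.linalg.eigh(corr0)
    clipped = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    if (d == 0).any():
        raise ValueError("projection produced a zero-variance condition")
    corr = clipped / np.outer(d, d)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)

    off = ~np.eye(k, dtype=bool)
    return ConditionCovariance(
        matrix=corr,
        labels=list(CONDITIONS),
        projection_changed=bool(np.abs(corr - corr0).max() > tol),
        no_structure=bool(np.allclose(corr[off], 0.0)),
    )


def sample_beta_patterns(
    trial_table: pd.DataFrame,
    target: ConditionCovariance | np.ndarray,
    n_voxels: int,
    trial_noise_sd: float,
    seed,
    roi_name: str = "synthetic",
    subject_id: str = "sub-synth",
) -> BetaPatternSet:
    """Draw a trials x voxels beta matrix with the given condition structure.

    Identical seeds reproduce identical output bit-for-bit.  ``seed`` may
    be anything :func:`numpy.random.default_rng` accepts.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    if trial_noise_sd < 0:
        raise ValueError("trial_noise_sd must be >= 0")
    cov = target.matrix if isinstance(target, ConditionCovariance) else np.asarray(target, float)
    if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
        raise ValueError(
            "target covariance is not positive semidefinite; "
            "project it first (target_similarity does this)"
        )
    rng = np.random.default_rng(seed)
    means = rng.multivariate_normal(np.zeros(len(cov)), cov, size=n_voxels, method="eigh")
    cond_idx = np.array([CONDITIONS.index(c) for c in trial_table["condition"]])
    values = means[:, cond_idx].T
    if trial_noise_sd > 0:
        values = values + rng.normal(0.0, trial_noise_sd, size=values.shape)
    return BetaPatternSet(
        values=values,
        trial_table=trial_table.reset_index(drop=True),
        roi_name=roi_name,
        subject_id=subject_id,
    )


def phase_trial_indices(
    trial_table: pd.DataFrame,
    split: dict[str, tuple[int, ...]] | None = None,
    cs_subset: str = "all",
) -> dict[str, np.ndarray]:
    """Unpaired-trial indices per learning phase.

    ``split`` maps phase name -> unpaired-block ordinals (1-based within
    task); it must partition the unpaired blocks present.  ``cs_subset``
    is 'all' (CS+ and CS- trials) or 'csp_only'.
    """
    split = split or DEFAULT_SPLIT
    ordinal = unpaired_block_ordinal(trial_table)
    present = set(ordinal.dropna().astype(int))
    claimed: list[int] = []
    for phase, blocks in split.items():
        if len(blocks) == 0:
            raise ValueError(f"phase {phase!r} has no blocks")
        claimed.extend(int(b) for b in blocks)
    if sorted(claimed) != sorted(present):
        raise ValueError(
            f"split blocks {sorted(claimed)} must partition unpaired blocks {sorted(present)}"
        )
    out = {}
    for phase, blocks in split.items():
        mask = ordinal.isin(list(blocks)).to_numpy()
        if cs_subset == "csp_only":
            mask &= trial_table["condition"].str.contains("CSP").to_numpy()
        elif cs_subset != "all":
            raise ValueError("cs_subset must be 'all' or 'csp_only'")
        out[phase] = trial_table.loc[mask, "trial_index"].to_numpy()
    return out


def simulate_cohort(
    trial_table: pd.DataFrame,
    segment_targets: dict[str, ConditionCovariance | np.ndarray],
    n_subjects: int,
    n_voxels: int,
    trial_noise_sd: float,
    seed,
    split: dict[str, tuple[int, ...]] | None = None,
    roi_name: str = "synthetic",
) -> list[BetaPatternSet]:
    """Generate one BetaPatternSet per subject with phase-specific structure.

    ``segment_targets`` maps each segment ('paired', 'early', 'mid',
    'late') to its own condition covariance; segments are drawn
    independently, so representational structure can change over learning
    (the construction behind the reactivation simulations).  A single
    'all' key applies one target to every trial.
    """
    rng = np.random.default_rng(seed)
    if set(segment_targets) == {"all"}:
        segments = {"all": trial_table["trial_index"].to_numpy()}
    else:
        segments = dict(phase_trial_indices(trial_table, split=split))
        segments["paired"] = trial_table.loc[
            trial_table["block_type"] == "paired", "trial_index"
        ].to_numpy()
        missing = set(segments) - set(segment_targets)
        if missing:
            raise ValueError(f"segment_targets missing {sorted(missing)}")
    cohort = []
    for s in range(n_subjects):
        values = np.empty((len(trial_table), n_voxels))
        for seg, idx in segments.items():
            part = sample_beta_patterns(
                trial_table.iloc[idx].reset_index(drop=True),
                segment_targets[seg],
                n_voxels,
                trial_noise_sd,
                seed=rng.integers(2**31),
            )
            values[idx] = part.values
        cohort.append(
            BetaPatternSet(
                values=values,
                trial_table=trial_table,
                roi_name=roi_name,
                subject_id=f"sub-{s + 1:02d}",
            )
        )
    return cohort
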