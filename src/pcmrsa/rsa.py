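"""Trial- and condition-wise representational similarity.

Similarity between two events is the Pearson correlation of their voxel
beta patterns, Fisher z-transformed (atanh) so that coefficients can be
averaged and regressed across participants.  Correlations are always
computed within a single ROI; ROIs are analyzed separately and never
statistically compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITIONS

#: |r| >= 1 - FISHER_EPS is capped at atanh(1 - FISHER_EPS) to keep the
#: regression stage finite when patterns are identical (r = 1).
FISHER_EPS = 1e-7


@dataclass
class BetaPatternSet:
    """Trials x voxels response-magnitude matrix for one ROI/participant."""

    values: np.ndarray
    trial_table: pd.DataFrame
    roi_name: str = "roi"
    subject_id: str = "sub"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a trials x voxels matrix")
        if len(self.values) != len(self.trial_table):
            raise ValueError(
                f"row count {len(self.values)} != trial table length "
                f"{len(self.trial_table)}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("beta values must be finite")


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of Fisher-z Pearson similarities, diagonal masked (NaN)."""

    values: np.ndarray
    labels: list
    level: str = "trial"
    roi_name: str = "roi"
    subject_id: str = "sub"
    z_capped: bool = False


def fisher_z(r, eps: float = FISHER_EPS):
    """Fisher transformation z = atanh(r), capped near |r| = 1.

    Scalar in, scalar out; array in, array out.  |r| > 1 (beyond floating
    slop) is a domain error.
    """
    arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(arr), initial=0.0) > 1 + 1e-12:
        raise ValueError("correlation outside [-1, 1]")
    clipped = np.clip(arr, -(1 - eps), 1 - eps)
    z = np.arctanh(clipped)
    return z if arr.ndim else float(z)


def _correlate(patterns: np.ndarray, labels: list, level: str, roi: str, sub: str,
               eps: float) -> SimilarityMatrix:
    t, v = patterns.shape
    if t < 2:
        raise ValueError("need at least 2 patterns to correlate")
    if v < 3:
        raise ValueError("need at least 3 voxels")
    sd = patterns.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance pattern(s) at {', '.join(str(labels[i]) for i in dead)}")
    r = np.corrcoef(patterns)
    np.clip(r, -1.0, 1.0, out=r)
    off = ~np.eye(t, dtype=bool)
    capped = bool((np.abs(r[off]) >= 1 - eps).any())
    z = fisher_z(r, eps=eps)
    z = (z + z.T) / 2  # enforce exact symmetry against float noise
    np.fill_diagonal(z, np.nan)
    return SimilarityMatrix(values=z, labels=labels, level=level,
                            roi_name=roi, subject_id=sub, z_capped=capped)


def pearson_similarity(
    betas: BetaPatternSet,
    trial_subset: list[int] | np.ndarray | None = None,
    eps: float = FISHER_EPS,
) -> SimilarityMatrix:
    """Trial-by-trial similarity over a subset of trials.

    Entry (i, j) is the Fisher-z Pearson correlation across voxels of the
    beta patterns of trials i and j; the diagonal is masked.
    """
    if trial_subset is None:
        trial_subset = betas.trial_table["trial_index"].to_numpy()
    idx = np.asarray(trial_subset, dtype=int)
    patterns = betas.values[idx]
    return _correlate(patterns, list(idx), "trial", betas.roi_name, betas.subject_id, eps)


def condition_similarity(
    betas: BetaPatternSet,
    trial_subset: list[int] | np.ndarray | None = None,
    eps: float = FISHER_EPS,
) -> SimilarityMatrix:
    """Condition-by-condition similarity over a subset of trials.

    Beta patterns are averaged per condition within the subset before
    correlating, yielding one pattern per condition present (ordered as in
    :data:`~pcmrsa.design.CONDITIONS`).
    """
    if trial_subset is None:
        trial_subset = betas.trial_table["trial_index"].to_numpy()
    idx = np.asarray(trial_subset, dtype=int)
    sub = betas.trial_table.set_index("trial_index").loc[idx]
    conds = [c for c in CONDITIONS if c in set(sub["condition"])]
    means = np.stack(
        [betas.values[idx[(sub["condition"] == c).to_numpy()]].mean(axis=0) for c in conds]
    )
    return _correlate(means, conds, "condition", betas.roi_name, betas.subject_id, eps)
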