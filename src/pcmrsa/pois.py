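"""The library of theoretical patterns of interest (POIs).

A POI is an idealized similarity matrix: the correlation structure an ROI
would show if it represented exactly one theoretical construct (task
identity, touch type, valence, ...).  Entries are therefore +1, -1 or 0.
Ten POIs are defined over the six experimental conditions (two CS+ and one
CS- in each of the appetitive and aversive tasks); three are defined only
at the level of individual trials because they depend on face identity,
temporal order, or block context (Face Stimulus, Temporal Adjacency,
Violation of Expectation).

Valence assignment: brush-paired CS+ trials and the aversive-task CS-
(omission of pressure) are positive events; pressure-paired CS+ trials and
the appetitive-task CS- (omission of caress) are negative events.  The CS-
thus inherits the opposite of its task's US valence via omission.

Diagonal entries are stored as +1 but always masked before vectorization:
the self-correlation carries no model information ("minus the
autocorrelation").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS

POI_NAMES: tuple[str, ...] = (
    "Experimental Task",
    "Nonspecific Touch",
    "Specific Touch",
    "Appetitive Brush",
    "Aversive Pressure",
    "Touch Valence",
    "Positive Events",
    "Negative Events",
    "All Valence",
    "Salience",
    "Face Stimulus",
    "Violation of Expectation",
    "Temporal Adjacency",
)

#: POIs that have no condition-level form: they depend on trial-level
#: attributes (face identity, temporal order, block context).
TRIAL_ONLY_POIS: tuple[str, ...] = (
    "Face Stimulus",
    "Violation of Expectation",
    "Temporal Adjacency",
)

CONDITION_POIS: tuple[str, ...] = tuple(n for n in POI_NAMES if n not in TRIAL_ONLY_POIS)

# Per-condition attributes used by the pairwise rules.
_TASK = {c: ("appetitive" if c.startswith("APP") else "aversive") for c in CONDITIONS}
_TOUCH = {
    "APP_CSP1": "brush",
    "APP_CSP2": "brush",
    "APP_CSM": "none",
    "AVR_CSP1": "pressure",
    "AVR_CSP2": "pressure",
    "AVR_CSM": "none",
}
# Positive events: appetitive caress, or no stimulation in the aversive task.
_VALENCE = {
    "APP_CSP1": "positive",
    "APP_CSP2": "positive",
    "APP_CSM": "negative",
    "AVR_CSP1": "negative",
    "AVR_CSP2": "negative",
    "AVR_CSM": "positive",
}


@dataclass(frozen=True)
class SalienceConfig:
    """How the ambiguous Salience POI is resolved.

    ``class_map`` assigns each condition to 'high' or 'low' salience; the
    default marks touch conditions high and CS- conditions low.  The
    printed definition does not pin down where the -1 sits; ``negative``
    selects between a -1 within low-salience pairs ('within_low', default,
    the most literal reading) or a -1 between high and low pairs
    ('between').  ``block_aware`` reassigns classes at the trial level from
    block context instead (paired-block trials high — touched or expecting
    touch — unpaired trials low); block-aware matrices are not functions of
    condition and so cannot be collapsed back to a condition matrix.
    """

    class_map: dict[str, str] = field(
        default_factory=lambda: {c: ("low" if _TOUCH[c] == "none" else "high") for c in CONDITIONS}
    )
    negative: str = "within_low"
    block_aware: bool = False

    def __post_init__(self) -> None:
        if self.negative not in ("within_low", "between"):
            raise ValueError("negative must be 'within_low' or 'between'")
        bad = {v for v in self.class_map.values()} - {"high", "low"}
        if bad:
            raise ValueError(f"salience classes must be high/low, got {sorted(bad)}")


@dataclass
class POIMatrix:
    """A model similarity matrix with entries in {-1, 0, +1}.

    ``level`` is 'condition' (6x6 over :data:`~pcmrsa.design.CONDITIONS`)
    or 'trial' (square over a trial subset).  ``degenerate`` is set when
    every off-diagonal entry is identical, in which case the matrix is
    collinear with the regression intercept and cannot be fit.
    """

    name: str
    level: str
    matrix: np.ndarray
    labels: list
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("POI matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("POI matrix must be symmetric")
        off = m[~np.eye(len(m), dtype=bool)]
        if off.size and not np.isin(off, (-1.0, 0.0, 1.0)).all():
            raise ValueError("POI entries must be in {-1, 0, +1}")
        if off.size:
            self.degenerate = bool(np.all(off == off[0]))
        else:
            self.degenerate = True


def _pair_rule(name: str, salience: SalienceConfig):
    """Return f(condition_i, condition_j) -> {-1, 0, +1} for i != j."""
    if name == "Experimental Task":
        return lambda a, b: 1.0 if _TASK[a] == _TASK[b] else 0.0
    if name == "Nonspecific Touch":
        return lambda a, b: 1.0 if _TOUCH[a] != "none" and _TOUCH[b] != "none" else 0.0
    if name == "Specific Touch":
        return lambda a, b: 1.0 if _TOUCH[a] == _TOUCH[b] else 0.0
    if name == "Appetitive Brush":
        return lambda a, b: 1.0 if _TOUCH[a] == _TOUCH[b] == "brush" else 0.0
    if name == "Aversive Pressure":
        return lambda a, b: 1.0 if _TOUCH[a] == _TOUCH[b] == "pressure" else 0.0
    if name == "Touch Valence":

        def rule(a, b):
            if _TOUCH[a] == "none" or _TOUCH[b] == "none":
                return 0.0
            return 1.0 if _TASK[a] == _TASK[b] else -1.0

        return rule
    if name == "Positive Events":
        return lambda a, b: 1.0 if _VALENCE[a] == _VALENCE[b] == "positive" else 0.0
    if name == "Negative Events":
        return lambda a, b: 1.0 if _VALENCE[a] == _VALENCE[b] == "negative" else 0.0
    if name == "All Valence":
        return lambda a, b: 1.0 if _VALENCE[a] == _VALENCE[b] else -1.0
    if name == "Salience":
        cls = salience.class_map

        def rule(a, b):
            if cls[a] == cls[b] == "high":
                return 1.0
            if cls[a] != cls[b]:
                return -1.0 if salience.negative == "between" else 0.0
            return -1.0 if salience.negative == "within_low" else 0.0

        return rule
    raise KeyError(name)


def condition_poi(name: str, salience: SalienceConfig | None = None) -> POIMatrix:
    """Build the 6x6 condition-level matrix for one POI.

    Raises a level error for the three trial-only POIs, directing callers
    to :func:`expand_to_trials`.
    """
    if name in TRIAL_ONLY_POIS:
        raise ValueError(
            f"{name!r} is only defined at trial level; use expand_to_trials"
        )
    if name not in POI_NAMES:
        raise KeyError(f"unknown POI {name!r}; known: {POI_NAMES}")
    salience = salience or SalienceConfig()
    rule = _pair_rule(name, salience)
    k = len(CONDITIONS)
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = rule(CONDITIONS[i], CONDITIONS[j])
    return POIMatrix(name=name, level="condition", matrix=m, labels=list(CONDITIONS))


def _trial_salience_classes(sub: pd.DataFrame, salience: SalienceConfig) -> list[str]:
    if salience.block_aware:
        return ["high" if bt == "paired" else "low" for bt in sub["block_type"]]
    return [salience.class_map[c] for c in sub["condition"]]


def expand_to_trials(
    name: str,
    trial_table: pd.DataFrame,
    trial_subset: list[int] | np.ndarray | None = None,
    salience: SalienceConfig | None = None,
) -> POIMatrix:
    """Expand a POI to a trial-level matrix over ``trial_subset``.

    Condition-level POIs map each trial pair to its condition-pair entry;
    two distinct trials of the same condition take +1 (same condition =
    maximal model similarity).  Face Stimulus marks pairs with identical
    faces; Temporal Adjacency marks within-task pairs of consecutive
    trials; Violation of Expectation marks pairs of paired-block CS-
    trials (touch was expected but omitted).
    """
    if name not in POI_NAMES:
        raise KeyError(f"unknown POI {name!r}; known: {POI_NAMES}")
    salience = salience or SalienceConfig()
    if trial_subset is None:
        trial_subset = trial_table["trial_index"].to_numpy()
    idx = np.asarray(trial_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("trial_subset must be non-empty")
    sub = trial_table.set_index("trial_index").loc[idx].reset_index()
    t = len(sub)
    m = np.eye(t)

    if name == "Face Stimulus":
        face = sub["face_id"].to_numpy()
        pair = (face[:, None] == face[None, :]).astype(float)
    elif name == "Temporal Adjacency":
        ti = sub["trial_index"].to_numpy()
        task = sub["task"].to_numpy()
        adjacent = np.abs(ti[:, None] - ti[None, :]) == 1
        same_task = task[:, None] == task[None, :]
        pair = (adjacent & same_task).astype(float)
    elif name == "Violation of Expectation":
        voe = ((sub["block_type"] == "paired") & sub["condition"].str.contains("CSM")).to_numpy()
        pair = (voe[:, None] & voe[None, :]).astype(float)
    elif name == "Salience" and salience.block_aware:
        cls = np.array(_trial_salience_classes(sub, salience))
        rule = _pair_rule("Salience", salience)
        # rule consumes condition labels; evaluate on classes directly
        pair = np.zeros((t, t))
        for i in range(t):
            for j in range(t):
                a, b = cls[i], cls[j]
                if a == b == "high":
                    pair[i, j] = 1.0
                elif a != b:
                    pair[i, j] = -1.0 if salience.negative == "between" else 0.0
                else:
                    pair[i, j] = -1.0 if salience.negative == "within_low" else 0.0
    else:
        cond = condition_poi(name, salience=salience)
        ci = np.array([cond.labels.index(c) for c in sub["condition"]])
        pair = cond.matrix[np.ix_(ci, ci)]

    off = ~np.eye(t, dtype=bool)
    m[off] = pair[off]
    # same-condition trial pairs map to the (masked) condition diagonal: +1
    if name in CONDITION_POIS and not (name == "Salience" and salience.block_aware):
        same_cond = (
            sub["condition"].to_numpy()[:, None] == sub["condition"].to_numpy()[None, :]
        )
        m[same_cond & off] = 1.0
    return POIMatrix(name=name, level="trial", matrix=m, labels=list(idx))


def collapse_to_conditions(trial_poi: POIMatrix, trial_table: pd.DataFrame) -> np.ndarray:
    """Average a trial-level matrix over condition pairs (6x6 result).

    Within-condition cells average distinct trial pairs only; condition
    pairs with no trial pair in the subset are NaN.
    """
    sub = trial_table.set_index("trial_index").loc[list(trial_poi.labels)].reset_index()
    cond = sub["condition"].to_numpy()
    k = len(CONDITIONS)
    out = np.full((k, k), np.nan)
    m = trial_poi.matrix
    off = ~np.eye(len(m), dtype=bool)
    for a in range(k):
        for b in range(k):
            mask = (cond[:, None] == CONDITIONS[a]) & (cond[None, :] == CONDITIONS[b]) & off
            if mask.any():
                out[a, b] = m[mask].mean()
    return out


@dataclass
class ModelVector:
    """Strict-upper-triangle vectorization of a symmetric matrix.

    ``index_map`` lists the (i, j) pair (i < j, row-major) behind each
    element; length is t(t-1)/2 for a t x t matrix.
    """

    values: np.ndarray
    index_map: list[tuple[int, int]]
    name: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def vectorize(matrix: POIMatrix | np.ndarray, name: str | None = None) -> ModelVector:
    """Vectorize the strict upper triangle (diagonal excluded) row-major."""
    if isinstance(matrix, POIMatrix):
        name = name or matrix.name
        m = matrix.matrix
    else:
        m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    t = m.shape[0]
    off = ~np.eye(t, dtype=bool)
    asym = np.nanmax(np.abs((m - m.T)[off])) if t > 1 else 0.0
    if asym > 1e-10:
        raise ValueError(f"matrix asymmetric beyond tolerance: max |m - m.T| = {asym:g}")
    iu = np.triu_indices(t, k=1)
    return ModelVector(
        values=m[iu].copy(),
        index_map=list(zip(iu[0].tolist(), iu[1].tolist())),
        name=name,
    )


def registry(salience: SalienceConfig | None = None) -> dict[str, POIMatrix]:
    """All condition-level POI matrices, keyed by name in registry order."""
    return {n: condition_poi(n, salience=salience) for n in CONDITION_POIS}
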