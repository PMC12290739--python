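"""Experimental design generation for the two-task tactile conditioning paradigm.

The paradigm pairs neutral face stimuli (conditioned stimuli, CS) with
valenced touch (unconditioned stimuli, US): a soft brush stroke in the
appetitive task and a painful pressure stimulus in the aversive task.
Each task presents seven unpaired CS blocks interleaved with six CS-US
paired blocks (U P U P ... U); every block shows each of the task's three
faces (two CS+, one CS-) exactly once.  The CS order of unpaired blocks is
held constant so that changes in pattern similarity across learning cannot
be attributed to changes in temporal distance between trials, while paired
block orders are randomized per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical condition labels, appetitive task first.  Face identities are
#: bijective with conditions (1..6 in this order).
CONDITIONS: tuple[str, ...] = (
    "APP_CSP1",
    "APP_CSP2",
    "APP_CSM",
    "AVR_CSP1",
    "AVR_CSP2",
    "AVR_CSM",
)

TASKS: tuple[str, ...] = ("appetitive", "aversive")

#: Within-task condition stems in the fixed unpaired-block presentation order.
_STEMS: tuple[str, ...] = ("CSP1", "CSP2", "CSM")

_TASK_PREFIX = {"appetitive": "APP", "aversive": "AVR"}
_TASK_TOUCH = {"appetitive": "brush", "aversive": "pressure"}

TRIAL_TABLE_COLUMNS = (
    "trial_index",
    "task",
    "block_index",
    "block_type",
    "position_in_block",
    "condition",
    "face_id",
    "touch_type",
    "us_delivered",
)


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the block design.

    Defaults reproduce the study layout: 7 unpaired + 6 paired blocks per
    task, 3 stimuli per block, two tasks, 78 trials in total.
    """

    n_unpaired_blocks: int = 7
    n_paired_blocks: int = 6
    stimuli_per_block: int = 3
    tasks: tuple[str, ...] = TASKS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_unpaired_blocks", "n_paired_blocks", "stimuli_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.stimuli_per_block != 3:
            raise ValueError(
                "stimuli_per_block must be 3: each block presents the task's "
                "two CS+ faces and one CS- face exactly once"
            )
        if self.n_unpaired_blocks != self.n_paired_blocks + 1:
            raise ValueError(
                "interleaving U P U P ... U requires "
                "n_unpaired_blocks == n_paired_blocks + 1"
            )
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")


def condition_label(task: str, stem: str) -> str:
    return f"{_TASK_PREFIX[task]}_{stem}"


def generate_design(params: DesignParams | None = None) -> pd.DataFrame:
    """Build the trial table for one participant.

    Tasks are generated as separate runs and concatenated (appetitive
    first).  Unpaired blocks use the fixed canonical order (CS+1, CS+2,
    CS-) in every block; paired-block orders are drawn from the seed, one
    permutation per block.  The US is delivered only on paired-block CS+
    trials: a brush stroke in the appetitive task, pressure in the
    aversive task.

    Returns a DataFrame with columns :data:`TRIAL_TABLE_COLUMNS`;
    ``trial_index`` is 0-based over the whole experiment, ``block_index``
    is 1-based within task.
    """
    params = params or DesignParams()
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    trial_index = 0
    for task in params.tasks:
        n_blocks = params.n_unpaired_blocks + params.n_paired_blocks
        for block_index in range(1, n_blocks + 1):
            block_type = "unpaired" if block_index % 2 == 1 else "paired"
            if block_type == "unpaired":
                order = list(_STEMS)
            else:
                order = [_STEMS[i] for i in rng.permutation(len(_STEMS))]
            for position, stem in enumerate(order, start=1):
                cond = condition_label(task, stem)
                us = block_type == "paired" and stem != "CSM"
                rows.append(
                    {
                        "trial_index": trial_index,
                        "task": task,
                        "block_index": block_index,
                        "block_type": block_type,
                        "position_in_block": position,
                        "condition": cond,
                        "face_id": CONDITIONS.index(cond) + 1,
                        "touch_type": _TASK_TOUCH[task] if us else "none",
                        "us_delivered": us,
                    }
                )
                trial_index += 1
    table = pd.DataFrame(rows, columns=list(TRIAL_TABLE_COLUMNS))
    validate_trial_table(table)
    return table


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a trial table."""
    missing = set(TRIAL_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if not (table["trial_index"].to_numpy() == np.arange(len(table))).all():
        raise ValueError("trial_index must be 0..n-1 in order")
    is_csp = table["condition"].str.contains("CSP")
    expect_us = (table["block_type"] == "paired") & is_csp
    if not (table["us_delivered"] == expect_us).all():
        raise ValueError("us_delivered must hold iff paired-block CS+ trial")
    touched = table["touch_type"] != "none"
    if not (touched == table["us_delivered"]).all():
        raise ValueError("touch_type must be 'none' exactly on non-US trials")
    bad_brush = touched & (table["task"] == "appetitive") & (table["touch_type"] != "brush")
    bad_press = touched & (table["task"] == "aversive") & (table["touch_type"] != "pressure")
    if bad_brush.any() or bad_press.any():
        raise ValueError("touch_type must be brush (appetitive US) or pressure (aversive US)")
    for (task, block), grp in table.groupby(["task", "block_index"]):
        if sorted(grp["condition"]) != sorted(
            condition_label(task, s) for s in _STEMS
        ):
            raise ValueError(
                f"block {block} of task {task} must contain each condition once"
            )


def unpaired_block_ordinal(table: pd.DataFrame) -> pd.Series:
    """Ordinal position (1-based) of each trial's unpaired block within its task.

    Paired-block trials get ``<NA>``.  With the U P U P ... U layout the
    k-th unpaired block sits at within-task block index 2k-1.
    """
    ordinal = (table["block_index"] + 1) // 2
    return ordinal.where(table["block_type"] == "unpaired", other=pd.NA).astype("Int64")
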