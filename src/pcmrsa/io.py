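"""File I/O for trial tables, beta patterns, similarity matrices and results.

Conventions: tabular data as TSV (diffable, headers carry labels), configs
as YAML, results as JSON, volumetric inputs as NIfTI.  Trial indices are
0-based everywhere in files and memory; ``block_index`` and ``face_id``
are 1-based as in the human-facing design description.  Every written
result carries a ``schema_version`` field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TRIAL_TABLE_COLUMNS, validate_trial_table
from .rsa import BetaPatternSet, SimilarityMatrix

SCHEMA_VERSION = "1"


# --- trial tables ----------------------------------------------------------

def write_trial_table(table: pd.DataFrame, path) -> None:
    table[list(TRIAL_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["us_delivered"] = table["us_delivered"].astype(bool)
    validate_trial_table(table)
    return table


# --- beta patterns ---------------------------------------------------------

def write_beta_patterns(betas: BetaPatternSet, matrix_path, trial_table_path=None) -> None:
    """Write values as a TSV matrix plus a JSON sidecar (<matrix>.json).

    Floats are written with repr precision so that a read-back round-trips
    bit-exactly.
    """
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, betas.values, delimiter="\t", fmt="%.17g")
    if trial_table_path is not None:
        write_trial_table(betas.trial_table, trial_table_path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "roi_name": betas.roi_name,
        "subject_id": betas.subject_id,
        "trial_table_path": str(trial_table_path) if trial_table_path else None,
        "n_voxels": int(betas.values.shape[1]),
    }
    matrix_path.with_suffix(matrix_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_beta_patterns(matrix_path, trial_table: pd.DataFrame | None = None) -> BetaPatternSet:
    matrix_path = Path(matrix_path)
    values = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    sidecar_path = matrix_path.with_suffix(matrix_path.suffix + ".json")
    roi, sub = "roi", "sub"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        roi = sidecar.get("roi_name", roi)
        sub = sidecar.get("subject_id", sub)
        if trial_table is None and sidecar.get("trial_table_path"):
            trial_table = read_trial_table(sidecar["trial_table_path"])
    if trial_table is None:
        raise ValueError("a trial table is required (argument or sidecar path)")
    return BetaPatternSet(values=values, trial_table=trial_table, roi_name=roi, subject_id=sub)


def load_beta_data(
    path,
    format: str = "tsv",
    trial_table: pd.DataFrame | None = None,
    mask_path=None,
) -> BetaPatternSet:
    """Load beta patterns from TSV or from a 4D NIfTI volume + 3D ROI mask.

    For NIfTI, ``path`` is a 4D beta volume with one volume per trial and
    ``mask_path`` a binary mask on the same grid; the result is the
    trials x in-mask-voxels matrix aligned to ``trial_table``.
    """
    if format == "tsv":
        return read_beta_patterns(path, trial_table=trial_table)
    if format != "nifti":
        raise ValueError("format must be 'tsv' or 'nifti'")
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D beta volume, got shape {data.shape}")
    if mask_path is None:
        raise ValueError("nifti input requires a mask_path")
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj)
    if mask.shape != data.shape[:3]:
        raise ValueError(f"mask grid {mask.shape} != volume grid {data.shape[:3]}")
    mask = mask > 0
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask: no in-mask voxels")
    if trial_table is None:
        raise ValueError("nifti input requires a trial_table")
    if data.shape[3] != len(trial_table):
        raise ValueError(
            f"volume count {data.shape[3]} != trial table length {len(trial_table)}"
        )
    values = data[mask, :].T.astype(float)
    return BetaPatternSet(values=values, trial_table=trial_table)


# --- similarity matrices and results ---------------------------------------

def write_similarity(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels).to_csv(path, sep="\t")


def read_similarity(path, level: str = "trial") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(values=df.to_numpy(), labels=list(df.columns), level=level)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns),
                "values": _jsonable(obj.to_numpy())}
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_result_json(result, path) -> None:
    """Serialize a (dataclass-based) result deterministically to JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
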