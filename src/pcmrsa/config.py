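"""Pipeline configuration: a YAML-round-trippable bundle of every knob.

Each run writes its resolved configuration beside its outputs so that any
result directory is self-describing and reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignParams
from .pois import CONDITION_POIS, POI_NAMES, SalienceConfig
from .reactivation import ReactivationConfig
from .synthetic import DEFAULT_SPLIT


@dataclass
class SimulationConfig:
    """Synthetic-cohort settings: study-sized design, weak mixed structure."""

    n_subjects: int = 12
    n_voxels: int = 200
    trial_noise_sd: float = 0.5
    baseline: float = 1.0
    #: generative POI mixture for paired-block (US) data
    paired_weights: dict[str, float] = field(
        default_factory=lambda: {"Experimental Task": 0.4, "Aversive Pressure": 0.3}
    )
    #: per-phase mixtures for unpaired data (defaults: no structure early,
    #: paired structure scaled in at mid/late — the reactivation scenario)
    phase_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "early": {},
            "mid": {"Experimental Task": 0.2, "Aversive Pressure": 0.15},
            "late": {"Experimental Task": 0.4, "Aversive Pressure": 0.3},
        }
    )


@dataclass
class PipelineConfig:
    design: DesignParams = field(default_factory=DesignParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reactivation: ReactivationConfig = field(default_factory=ReactivationConfig)
    seed: int = 0
    out_dir: str = "pcmrsa_out"

    def __post_init__(self) -> None:
        for name in self.simulation.paired_weights:
            if name not in POI_NAMES:
                raise ValueError(f"unknown POI in paired_weights: {name!r}")
        for phase, weights in self.simulation.phase_weights.items():
            for name in weights:
                if name not in POI_NAMES:
                    raise ValueError(f"unknown POI in phase_weights[{phase!r}]: {name!r}")
        for name in self.reactivation.candidates or []:
            if name not in CONDITION_POIS:
                raise ValueError(f"unknown condition-level POI candidate: {name!r}")
        for name in self.reactivation.component_pois or []:
            if name not in CONDITION_POIS:
                raise ValueError(f"unknown component POI: {name!r}")


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, list):
        return [_to_dict(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=True))


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    design = DesignParams(**{**raw.get("design", {}),
                             **({"tasks": tuple(raw["design"]["tasks"])}
                                if "tasks" in raw.get("design", {}) else {})})
    sim = SimulationConfig(**raw.get("simulation", {}))
    re_raw = dict(raw.get("reactivation", {}))
    if "split" in re_raw:
        re_raw["split"] = {k: tuple(v) for k, v in re_raw["split"].items()}
    if re_raw.get("salience") is not None:
        re_raw["salience"] = SalienceConfig(**re_raw["salience"])
    react = ReactivationConfig(**re_raw)
    return PipelineConfig(
        design=design,
        simulation=sim,
        reactivation=react,
        seed=raw.get("seed", 0),
        out_dir=raw.get("out_dir", "pcmrsa_out"),
    )
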