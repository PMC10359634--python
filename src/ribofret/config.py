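"""Experiment configuration: structured, validated, YAML round-trippable.

A configuration is a seeded set of named conditions, each fully describing
its kinetic scheme, photophysics, delivery model, camera and molecule count,
plus per-condition analysis settings (HMM state count, minimum dwell length
in frames).  Every pipeline output embeds the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .simulate import CameraModel, DeliveryModel, ExpMixture, KineticScheme, PhotophysicsModel

__all__ = ["AnalysisSettings", "ConditionConfig", "ExperimentConfig", "load_config", "save_config"]


@dataclass
class AnalysisSettings:
    """Per-condition analysis thresholds."""

    hmm_states: int = 2
    hmm_restarts: int = 10
    min_dwell_frames: int = 2
    dead_time_frames: Optional[float] = None  # default: min_dwell_frames + 0.7
    dwell_model: str = "auto"        # single-exp / double-exp / auto
    correct_missed_events: bool = True
    min_flank_frames: int = 2        # "unambiguous" transition flank length
    arrival_m_consecutive: int = 3


@dataclass
class ConditionConfig:
    name: str
    scheme: KineticScheme
    photo: PhotophysicsModel
    delivery: DeliveryModel
    camera: CameraModel
    n_molecules: int
    wash_time_s: Optional[float] = None
    wash_scheme: Optional[KineticScheme] = None
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def validate(self) -> None:
        if self.n_molecules < 0:
            raise ValueError(f"{self.name}: n_molecules must be >= 0")
        if self.camera.duration > self.delivery.window_s + 1e-9:
            raise ValueError(
                f"{self.name}: frame count x exposure exceeds the observation window"
            )
        if self.wash_time_s is not None:
            if not 0 < self.wash_time_s < self.delivery.window_s:
                raise ValueError(f"{self.name}: wash time outside the observation window")
            if self.wash_scheme is None:
                raise ValueError(f"{self.name}: wash_time_s set but no wash_scheme")


@dataclass
class ExperimentConfig:
    name: str
    seed: int
    conditions: list = field(default_factory=list)

    def validate(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        for c in self.conditions:
            c.validate()

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        conds = [_condition_from_dict(c) for c in d.get("conditions", [])]
        cfg = cls(name=d["name"], seed=int(d["seed"]), conditions=conds)
        cfg.validate()
        return cfg

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _mixture_from_dict(d: dict) -> ExpMixture:
    return ExpMixture(weights=tuple(d["weights"]), taus=tuple(d["taus"]))


def _scheme_from_dict(d: dict) -> KineticScheme:
    dwell = {k: _mixture_from_dict(v) for k, v in (d.get("dwell_dists") or {}).items()}
    first = d.get("first_dwell_dists")
    return KineticScheme(
        states=tuple(d["states"]),
        dwell_dists=dwell,
        static_fraction=d.get("static_fraction", 0.0),
        static_state=d.get("static_state"),
        initial_state_probs=tuple(d["initial_state_probs"]) if d.get("initial_state_probs") else None,
        first_dwell_dists={k: _mixture_from_dict(v) for k, v in first.items()} if first else None,
        heterogeneity=d.get("heterogeneity", "dwell"),
        condition=d.get("condition", {}),
    )


def _condition_from_dict(d: dict) -> ConditionConfig:
    return ConditionConfig(
        name=d["name"],
        scheme=_scheme_from_dict(d["scheme"]),
        photo=PhotophysicsModel(**d["photo"]),
        delivery=DeliveryModel(**d["delivery"]),
        camera=CameraModel(**d["camera"]),
        n_molecules=int(d["n_molecules"]),
        wash_time_s=d.get("wash_time_s"),
        wash_scheme=_scheme_from_dict(d["wash_scheme"]) if d.get("wash_scheme") else None,
        analysis=AnalysisSettings(**(d.get("analysis") or {})),
    )


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path) -> ExperimentConfig:
    return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()))
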