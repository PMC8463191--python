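"""Experiment configuration: a flat, human-editable YAML document binding
model parameters, stimulation protocol, integration settings, sweep grids
and classifier thresholds into one reproducible unit.

The bundled defaults profile is the published operating point of the
model; a run's config echo plus its seed reproduces the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analysis import ClassifierConfig
from .model import ModelParameters
from .simulate import SimulationConfig
from .stimulation import StimulusProtocol

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment bit-identically."""

    model: ModelParameters = field(default_factory=ModelParameters)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    h7_grid: list[float] = field(
        default_factory=lambda: np.linspace(1.5, 2.5, 41).tolist())
    h8_grid: list[float] = field(
        default_factory=lambda: np.linspace(9.0, 11.0, 41).tolist())
    outdir: str = "thalcor-out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "protocol": self.protocol.to_dict(),
            "simulation": self.simulation.to_dict(),
            "classifier": self.classifier.to_dict(),
            "h7_grid": list(map(float, self.h7_grid)),
            "h8_grid": list(map(float, self.h8_grid)),
            "outdir": self.outdir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = {}
        if "model" in d:
            kwargs["model"] = ModelParameters.from_dict(d["model"])
        if "protocol" in d:
            kwargs["protocol"] = StimulusProtocol.from_dict(d["protocol"])
        if "simulation" in d:
            kwargs["simulation"] = SimulationConfig(**d["simulation"])
        if "classifier" in d:
            c = dict(d["classifier"])
            for k in ("swd_band", "freq_band"):
                if k in c:
                    c[k] = tuple(c[k])
            kwargs["classifier"] = ClassifierConfig(**c)
        for k in ("h7_grid", "h8_grid", "outdir", "log_level"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
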