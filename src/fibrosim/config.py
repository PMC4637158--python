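"""Run configuration: validated, hashable, serialized with every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]

_MODELS = ("microscopic", "discrete")
_IONICS = ("bondarenko", "surrogate")
_PROTOCOLS = ("left_edge_plane", "bottom_edge_plane", "center_point", "s1s2_crossfield")


@dataclass
class RunConfig:
    """Everything needed to reproduce one tissue run."""

    model: str = "discrete"
    ionic: str = "bondarenko"
    tissue_cm: tuple[float, float] = (0.4, 0.4)
    phi: float = 0.0
    seed: int = 0
    protocol: str = "left_edge_plane"
    T_end: float = 120.0
    dt_o: float = 1e-4
    dt_p: float = 0.01
    beta: float | None = None          # None: the calibrated package default
    probes: list | None = None
    outdir: str = "runs"

    def validate(self) -> "RunConfig":
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.ionic not in _IONICS:
            raise ValueError(f"ionic must be one of {_IONICS}")
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"protocol must be one of {_PROTOCOLS}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if self.T_end <= 0 or self.dt_o <= 0 or self.dt_p < self.dt_o:
            raise ValueError("need T_end > 0 and 0 < dt_o <= dt_p")
        if min(self.tissue_cm) <= 0:
            raise ValueError("tissue size must be positive")
        return self

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if "tissue_cm" in data:
            data["tissue_cm"] = tuple(data["tissue_cm"])
        return cls(**data).validate()

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
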