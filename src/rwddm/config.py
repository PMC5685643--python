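"""Run configuration: a YAML-serialisable description of one experiment run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .protocols import PRESET_NAMES, UnknownDesignError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``overrides`` holds model-parameter overrides (m, alpha_t, theta,
    sigma, alpha_V, H, dt_ms, A_init, flags) applied on top of the
    preset's figure-caption values; ``record`` selects which trials keep
    their per-step CR series ("all", "peak", "reinforced", "extinction",
    "none").
    """

    design: str
    seed: int = 0
    replications: int = 1
    out_dir: str = "rwddm_out"
    overrides: dict = field(default_factory=dict)
    record: str = "all"
    per_step_csv: bool = False

    def __post_init__(self) -> None:
        if self.design not in PRESET_NAMES:
            raise UnknownDesignError(
                f"unknown design {self.design!r}; available presets: "
                + ", ".join(sorted(PRESET_NAMES))
            )
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.record not in ("all", "peak", "reinforced", "extinction", "none"):
            raise ValueError(f"bad record rule {self.record!r}")
        if "H" in self.overrides and self.overrides["H"] < 0:
            raise ValueError("H must be >= 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc

    def digest(self) -> str:
        """Stable content hash, recorded in run metadata."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
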