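"""Run configuration: a plain-text (YAML) record sufficient to reproduce a run."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import yaml

from .models import ModelSpec
from .sampling import SamplerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything an evaluation run needs, serializable to one YAML file."""

    panel_path: str
    intervention_date: _dt.date
    model: ModelSpec
    sampler: SamplerConfig
    output_dir: str = "."
    force: bool = False

    def to_dict(self) -> dict:
        return {
            "panel_path": str(self.panel_path),
            "intervention_date": self.intervention_date.isoformat(),
            "model": self.model.to_dict(),
            "sampler": self.sampler.to_dict(),
            "output_dir": str(self.output_dir),
            "force": bool(self.force),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        date = d["intervention_date"]
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        return cls(
            panel_path=d["panel_path"],
            intervention_date=date,
            model=ModelSpec.from_dict(d["model"]),
            sampler=SamplerConfig(**d["sampler"]),
            output_dir=d.get("output_dir", "."),
            force=bool(d.get("force", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
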