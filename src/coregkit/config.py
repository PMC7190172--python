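"""Run configuration: pipeline + generator settings in one serializable bag."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .coregister import CoregConfig
from .synthetic_data import CohortConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Merged pipeline/generator configuration with a master seed.

    Round-trips unchanged through its JSON form; unknown keys in a config
    file are rejected rather than silently ignored.
    """

    seed: int = 7
    n_subjects: int = 30
    coreg: CoregConfig = field(default_factory=CoregConfig)
    generator: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "coreg": dataclasses.asdict(self.coreg),
            "generator": dataclasses.asdict(self.generator),
        }

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"seed", "n_subjects", "coreg", "generator"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(dc_type, sub: dict):
            fields = {f.name for f in dataclasses.fields(dc_type)}
            extra = set(sub) - fields
            if extra:
                raise ValueError(f"unknown {dc_type.__name__} keys: "
                                 f"{sorted(extra)}")
            kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in sub.items()}
            return dc_type(**kwargs)

        return cls(
            seed=raw.get("seed", 7),
            n_subjects=raw.get("n_subjects", 30),
            coreg=build(CoregConfig, raw.get("coreg", {})),
            generator=build(CohortConfig, raw.get("generator", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
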