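"""Pipeline configuration: a YAML file mapping onto plain dataclasses.

Every stochastic stage must carry an explicit seed — a config without
``selection.seed`` (or, when simulating, ``simulate.seed``) is refused, so a
run is reproducible from its config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .design import EncodingConfig

__all__ = ["DataConfig", "SimulateConfig", "SelectionConfig", "RebuildConfig", "PipelineConfig"]


@dataclass
class DataConfig:
    condition_path: str
    factor_path: str
    external_condition_path: str | None = None
    external_factor_path: str | None = None


@dataclass
class SimulateConfig:
    seed: int
    n_donors: int = 4
    n_replicates: int = 2
    cytokine_background: float = 10.0
    noise_sd: float = 3000.0
    missing_rate: float = 0.05
    external: bool = False
    external_background: float = 30.0
    external_scale: float = 1.0   # global proliferation multiplier of the external truth
    external_seed: int | None = None  # defaults to seed + 1


@dataclass
class SelectionConfig:
    seed: int
    k: int = 7
    alpha: float = 0.10
    n_perm: int = 10_000
    vip_threshold: float = 0.8
    max_components: int = 15


@dataclass
class RebuildConfig:
    cutpoints: list[float] = field(default_factory=lambda: [1.6, 1.3, 1.1])


@dataclass
class PipelineConfig:
    selection: SelectionConfig
    data: DataConfig | None = None
    simulate: SimulateConfig | None = None
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    rebuild: RebuildConfig = field(default_factory=RebuildConfig)
    output_dir: str = "nichepls_out"

    def __post_init__(self) -> None:
        if (self.data is None) == (self.simulate is None):
            raise ValueError("config must provide exactly one of a 'data' or a 'simulate' block")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sel = d.get("selection")
        if not isinstance(sel, dict) or "seed" not in sel:
            raise ValueError("config must set selection.seed explicitly (reproducibility)")
        sim = d.get("simulate")
        if sim is not None and "seed" not in sim:
            raise ValueError("config must set simulate.seed explicitly (reproducibility)")
        return cls(
            selection=SelectionConfig(**sel),
            data=DataConfig(**d["data"]) if d.get("data") else None,
            simulate=SimulateConfig(**sim) if sim else None,
            encoding=EncodingConfig(**d.get("encoding", {})),
            rebuild=RebuildConfig(**d.get("rebuild", {})),
            output_dir=d.get("output_dir", "nichepls_out"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = {
            "selection": asdict(self.selection),
            "encoding": asdict(self.encoding),
            "rebuild": asdict(self.rebuild),
            "output_dir": self.output_dir,
        }
        if self.data is not None:
            d["data"] = asdict(self.data)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
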