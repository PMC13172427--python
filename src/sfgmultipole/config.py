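"""Run configuration: a serializable description of a full pipeline run.

A saved config plus its seed reproduces a run bit for bit.  All physical
defaults mirror the printed study conditions: bending-band limits
1507/1772 cm⁻¹, red shifts 28/166 cm⁻¹ with the 2500 cm⁻¹ boundary, and
Δk_z = 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    label: str = "toy-biaxial-slab"
    seed: int = 1
    output: str = "out"
    # model overrides applied on top of ToyWaterModel defaults
    model: dict = field(default_factory=dict)
    slab: dict = field(default_factory=lambda: {
        "box": [20.0, 20.0, 60.0], "n_molecules": 352, "thickness": 26.3,
        "recipe": "biaxial", "spread": 12.0})
    dynamics: dict = field(default_factory=lambda: {
        "steps": 8192, "dt": 1.0, "temperature": 298.0, "stride": 1})
    grids: dict = field(default_factory=lambda: {
        "depth_width": 0.5, "n_lags": 2048, "nu_max": 4100.0})
    bands: dict = field(default_factory=lambda: {"nu1": 1507.0,
                                                 "nu2": 1772.0})
    shifts: dict = field(default_factory=lambda: {
        "bend": 28.0, "stretch": 166.0, "boundary": 2500.0})
    dkz: float = 0.0
    coupling: bool = False          # dipole–dipole coupling in the DQ split
    components: tuple = ("yyz", "zzz")

    def validate(self):
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        for key in ("box", "n_molecules", "thickness"):
            if key not in self.slab:
                raise ConfigError(f"slab block missing '{key}'")
        for key in ("steps", "dt", "temperature"):
            if key not in self.dynamics:
                raise ConfigError(f"dynamics block missing '{key}'")
        if self.dynamics["dt"] <= 0:
            raise ConfigError("dynamics dt must be positive")
        if self.bands["nu1"] >= self.bands["nu2"]:
            raise ConfigError("band limits must satisfy nu1 < nu2")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list)
            .encode()).hexdigest()[:16]

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "components" in data:
            cfg.components = tuple(data["components"])
        return cfg.validate()


def toy_biaxial_slab(**overrides) -> RunConfig:
    """The bundled demonstration config: a three-layer biaxially ordered
    slab small enough to run in minutes on one CPU."""
    cfg = RunConfig()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg.validate()
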