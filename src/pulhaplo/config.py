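"""Pipeline configuration: every screening threshold in one place.

Defaults are the published survey settings: 80% identity for locus detection,
95% per-gene coverage in the strict screen, 54-nt exact-match probes, the
>=10-read filter for group characterization and the strictly-above-80%
dominance rule.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from pulhaplo.simulate import SimulationConfig


@dataclass
class PipelineConfig:
    identity_min: float = 80.0
    coverage_min: float = 95.0
    probe_len: int = 54
    min_reads: int = 10
    dom_threshold: float = 0.80
    tie_margin: float = 0.5
    truncation_frac: float = 0.95
    seed: int = 0
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not 0 < self.identity_min <= 100:
            raise ValueError("identity_min outside (0,100]")
        if not 0 < self.coverage_min <= 100:
            raise ValueError("coverage_min outside (0,100]")
        if self.probe_len < 20:
            raise ValueError("probe_len too short to be diagnostic")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.dom_threshold < 1:
            raise ValueError("dom_threshold outside (0,1)")
        if not 0 <= self.truncation_frac <= 1:
            raise ValueError("truncation_frac outside [0,1]")
        self.simulation.validate()

    # --- TOML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d.pop("simulation")
        sim["gii_identity_band"] = list(sim["gii_identity_band"])
        sim["giii_identity_band"] = list(sim["giii_identity_band"])
        sim["depth_bounds"] = list(sim["depth_bounds"])
        d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        for key in ("gii_identity_band", "giii_identity_band", "depth_bounds"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg = cls(**d, simulation=SimulationConfig(**sim))
        cfg.validate()
        return cfg

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_emit_toml(self.to_dict()))


def _emit_toml(d: dict, prefix: str = "") -> str:
    """Minimal TOML emitter for the flat/nested-dict configs used here."""
    scalars, tables = [], []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        elif v is not None:
            scalars.append((k, v))
    out = []
    for k, v in scalars:
        out.append(f"{k} = {_toml_value(v)}")
    for k, v in tables:
        name = f"{prefix}{k}"
        out.append(f"\n[{name}]")
        out.append(_emit_toml(v, prefix=name + "."))
    return "\n".join(out) + ("\n" if not prefix else "")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)
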