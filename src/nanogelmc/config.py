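"""Run configuration schema, JSON round-trip, and the NG1-NG4 presets.

The four study systems share one network (100 chains of 30 monomers joined
by 66 tetrafunctional cross-linkers in a 150 nm box) and differ only in
the number of charged monomers per chain (1-4, i.e. bare charge
Z = 100-400).  The nanocomposite presets NP@NGn add 40 nanoparticles of
-5e plus their 200 monovalent cations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

from .thermo import ModelParams


@dataclass
class SystemConfig:
    n_chains: int = 100
    monomers_per_chain: int = 30
    n_crosslinkers: int = 66
    charged_per_chain: int = 1
    n_nanoparticles: int = 0
    np_valence: int = -5
    box_length: float = 150.0
    bond_length: float = 0.65
    ion_diameter: float = 0.70
    np_diameter: float = 5.00

    def __post_init__(self) -> None:
        for name in (
            "n_chains", "monomers_per_chain", "n_crosslinkers",
            "charged_per_chain", "n_nanoparticles",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"system.{name} must be non-negative")
        for name in ("box_length", "bond_length", "ion_diameter", "np_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"system.{name} must be positive")

    @property
    def bare_charge(self) -> int:
        return self.n_chains * self.charged_per_chain


@dataclass
class ScheduleConfig:
    n_equilibration: int = 300_000_000
    n_production: int = 200_000_000
    sample_interval: int = 100_000
    seed: int = 0
    temperature_celsius: float = 20.0


@dataclass
class MovesConfig:
    adapt_interval: int = 1000
    cluster_move_period: int | None = None
    scale_moves_enabled: bool = True
    scale_dmax: float = 0.03


@dataclass
class EwaldConfig:
    accuracy: float = 1e-4
    alpha: float | None = None
    r_cut: float | None = None
    k_max: int | None = None


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    system: SystemConfig = field(default_factory=SystemConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    moves: MovesConfig = field(default_factory=MovesConfig)
    ewald: EwaldConfig = field(default_factory=EwaldConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "model": ModelParams,
            "system": SystemConfig,
            "schedule": ScheduleConfig,
            "moves": MovesConfig,
            "ewald": EwaldConfig,
        }
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, klass in sections.items():
            if name not in data:
                continue
            section = data[name]
            known = {f.name for f in fields(klass)}
            bad = set(section) - known
            if bad:
                raise ValueError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            kwargs[name] = klass(**section)
        return cls(**kwargs)


PRESETS: dict[str, dict] = {}
for _n in (1, 2, 3, 4):
    PRESETS[f"NG{_n}"] = {"system": {"charged_per_chain": _n}}
    PRESETS[f"NP@NG{_n}"] = {
        "system": {"charged_per_chain": _n, "n_nanoparticles": 40}
    }


def preset_config(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return RunConfig.from_dict(PRESETS[name])


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
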