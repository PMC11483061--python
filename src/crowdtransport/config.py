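"""Analysis configuration: defaults, validation, TOML round-trip."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import units


@dataclass
class AnalysisConfig:
    """Central knobs of the analysis pipeline.

    Attributes
    ----------
    temperature : float
        Simulation/analysis temperature, K.
    equilibration_cutoff : float
        Initial stretch of trajectory discarded before averaging, ns.
    msd_fit_window : tuple
        Lag interval for the linear MSD fit, ns.
    rot_fit_window : tuple
        Lag interval for the rotational double-exponential fit, ns.
    contact_cutoff : float
        Heavy-atom minimum-distance cutoff defining a molecular contact, Å.
    residue_contact_cutoff : float
        Cα-to-crowder-heavy-atom cutoff for per-residue counts, Å.
    eta_model : float
        Shear viscosity of the simulation water model, cP.
    eta_reference : float
        Experimental reference viscosity of water at 298 K, cP.
    conc_per_phi : float
        Coefficient converting volume fraction to mass concentration, g/L.
    seed : int
        Master random seed for stochastic analysis steps.
    """

    temperature: float = units.T_DEFAULT
    equilibration_cutoff: float = 400.0
    msd_fit_window: tuple[float, float] = (2.0, 10.0)
    rot_fit_window: tuple[float, float] = (0.0, 20.0)
    contact_cutoff: float = 5.0
    residue_contact_cutoff: float = 7.0
    eta_model: float = 0.334
    eta_reference: float = 0.890
    conc_per_phi: float = 1430.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.equilibration_cutoff < 0:
            raise ValueError("equilibration cutoff must be >= 0")
        for name in ("contact_cutoff", "residue_contact_cutoff",
                     "eta_model", "eta_reference", "conc_per_phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("msd_fit_window", "rot_fit_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} lower bound must be < upper bound")
            if lo < 0:
                raise ValueError(f"{name} bounds must be non-negative")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("msd_fit_window", "rot_fit_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        write_toml(path, dataclasses.asdict(self))


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value)!r} to TOML")


def write_toml(path: str | Path, data: dict[str, Any]) -> None:
    """Write a flat (or one-level-nested) dict of scalars/lists as TOML."""
    lines: list[str] = []
    tables: list[str] = []
    for key, value in data.items():
        if isinstance(value, dict):
            tables.append(f"[{key}]")
            for k, v in value.items():
                tables.append(f"{k} = {_toml_value(v)}")
            tables.append("")
        elif value is not None:
            lines.append(f"{key} = {_toml_value(value)}")
    Path(path).write_text("\n".join(lines + [""] + tables))
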