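"""Plain-text (YAML/JSON) configuration for switch parameters and libraries.

Concentrations are molar by default; values may be given as strings with an
explicit unit tag, e.g. ``"150 nM"`` or ``"1 uM"``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from .switch_thermo import MutationEffect, ReadoutModel, SwitchParams, Totals

__all__ = [
    "parse_concentration",
    "load_config",
    "switch_params_from_dict",
    "totals_from_dict",
    "mutations_from_list",
    "readout_from_dict",
]

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def parse_concentration(value: Any) -> float:
    """Parse a molar concentration, accepting '<number> <unit>' strings."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) == 2 and parts[1] in _UNIT_SCALE:
        return float(parts[0]) * _UNIT_SCALE[parts[1]]
    if len(parts) == 1:
        return float(parts[0])
    raise ValueError(f"cannot parse concentration {value!r}")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def switch_params_from_dict(d: dict) -> SwitchParams:
    return SwitchParams(
        dG_close=float(d["dG_close"]),
        Kd_key=parse_concentration(d["Kd_key"]),
        Kd_target=parse_concentration(d["Kd_target"]),
        temperature_K=float(d.get("temperature_K", 298.15)),
    )


def totals_from_dict(d: dict) -> Totals:
    return Totals(
        C_tot=parse_concentration(d["C_tot"]),
        K_tot=parse_concentration(d["K_tot"]),
        T_tot=parse_concentration(d.get("T_tot", 0.0)),
    )


def mutations_from_list(entries: list[dict]) -> list[MutationEffect]:
    return [
        MutationEffect(name=e["name"], interface=e["interface"], ddG=float(e["ddG"]))
        for e in entries
    ]


def readout_from_dict(d: dict) -> ReadoutModel:
    return ReadoutModel(R_min=float(d["R_min"]), R_max=float(d["R_max"]))
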