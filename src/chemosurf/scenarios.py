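"""Scenario presets, configuration parsing, and unit handling.

A scenario is a structured description of one study condition: flow,
chemoattractant source, chemotaxis parameters, domain geometry, and
fertilization kinetics.  Three presets ship with the package:

fig2_arbacia
    Sea urchin *Arbacia punctulata* in its natural spawning habitat: low egg
    density, long exposure, continuous chemoattractant release — the
    optimal-shear-rate scenario.
fig3_rufescens
    Red abalone *Haliotis rufescens* in a Taylor-Couette chamber: high egg
    density and a high chemoattractant background accumulated before the
    experiment (near-field regime).
fig4_purpuratus
    Sea urchin *Strongylocentrotus purpuratus* in strong turbulence: very
    high background concentration makes chemotaxis ineffective, so it is
    switched off and encounters are purely mechanical.

Every parameter carries a provenance tag: 'paper-printed' (stated in the
main text of the study being modelled), 'reconstructed' (chosen here to be
consistent with printed derived quantities and literature ranges), or
'user' (supplied as an override).  Values are given in field-friendly units
and converted to SI on load.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field as _dfield
from pathlib import Path

import numpy as np
import yaml

from .agents import ChemotaxisParams
from .ensemble import DomainConfig
from .field import SourceParams
from .flow import ShearFlow, SphereDisturbance, TurbulenceScales
from .kinetics import KineticsParams

__all__ = ["Scenario", "load_scenario", "available_presets", "to_si"]

# multiplicative conversion to SI for the units accepted in config files
_UNIT_TO_SI: dict[str, float] = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "s": 1.0,
    "min": 60.0,
    "1/s": 1.0,
    "m/s": 1.0,
    "mm/s": 1e-3,
    "um/s": 1e-6,
    "m^2/s": 1.0,
    "um^2/s": 1e-12,
    "m^2/s^3": 1.0,
    "mol/m^3": 1.0,
    "M": 1e3,
    "nM": 1e-6,
    "pM": 1e-9,
    "mol/s": 1.0,
    "fmol/min": 1e-15 / 60.0,
    "1/m^3": 1.0,
    "1/mL": 1e6,
    "rad^2/s": 1.0,
    "": 1.0,
    None: 1.0,
}

_PROVENANCES = {"paper-printed", "reconstructed", "user"}


def to_si(value: float, unit: str | None) -> float:
    """Convert a value in one of the accepted units to SI."""
    if unit not in _UNIT_TO_SI:
        raise ValueError(f"unknown unit {unit!r}")
    return float(value) * _UNIT_TO_SI[unit]


def _entry_si(entry, path: str) -> float:
    """Resolve a config entry ({value, unit, provenance} or bare number)."""
    if isinstance(entry, dict):
        if "value" not in entry:
            raise ValueError(f"missing 'value' for parameter {path}")
        prov = entry.get("provenance", "reconstructed")
        if prov not in _PROVENANCES:
            raise ValueError(f"unknown provenance {prov!r} for {path}")
        return to_si(entry["value"], entry.get("unit"))
    return float(entry)


def _provenance(entry) -> str:
    if isinstance(entry, dict):
        return entry.get("provenance", "reconstructed")
    return "reconstructed"


_REQUIRED = {
    "flow": ["alpha"],
    "source": ["Qdot", "D", "t_release", "c_bg"],
    "chemotaxis": ["v_h", "v_phi", "c_b", "r0", "g"],
    "domain": ["rho_egg", "r_egg", "t_max", "n_sperm"],
    "kinetics": ["p_f", "rho_sperm"],
}
_FLAGS = {
    "flow": ["unsteady", "D_rot", "sphere_enabled"],
    "chemotaxis": ["chemotaxis_on", "corotation_on"],
    "turbulence": ["nu", "a"],
}


@dataclass
class Scenario:
    """A fully resolved study condition in SI units."""

    name: str
    raw: dict
    values: dict
    provenance: dict

    # -- constructors for the model objects --------------------------------
    def flow(self, alpha: float | None = None, seed: int = 0) -> ShearFlow:
        a = self.values["flow.alpha"] if alpha is None else float(alpha)
        return ShearFlow(
            alpha=a,
            unsteady=bool(self.values.get("flow.unsteady", False)),
            D_rot=float(self.values.get("flow.D_rot", 0.0)),
            seed=seed,
        )

    def sphere(self) -> SphereDisturbance:
        return SphereDisturbance(
            r_egg=self.values["domain.r_egg"],
            enabled=bool(self.values.get("flow.sphere_enabled", True)),
        )

    def source(self) -> SourceParams:
        v = self.values
        return SourceParams(
            Qdot=v["source.Qdot"],
            D=v["source.D"],
            t_release=v["source.t_release"],
            c_bg=v["source.c_bg"],
            r_egg=v["domain.r_egg"],
        )

    def chemotaxis(self) -> ChemotaxisParams:
        v = self.values
        return ChemotaxisParams(
            v_h=v["chemotaxis.v_h"],
            v_phi=v["chemotaxis.v_phi"],
            c_b=v["chemotaxis.c_b"],
            r0=v["chemotaxis.r0"],
            g=v["chemotaxis.g"],
            chemotaxis_on=bool(v.get("chemotaxis.chemotaxis_on", True)),
            corotation_on=bool(v.get("chemotaxis.corotation_on", True)),
        )

    def domain(self, n_sperm: int | None = None, seed: int = 0) -> DomainConfig:
        v = self.values
        return DomainConfig(
            rho_egg=v["domain.rho_egg"],
            r_egg=v["domain.r_egg"],
            t_max=v["domain.t_max"],
            n_sperm=int(n_sperm if n_sperm is not None else v["domain.n_sperm"]),
            seed=seed,
        )

    def kinetics(self) -> KineticsParams:
        v = self.values
        return KineticsParams(
            p_f=v["kinetics.p_f"],
            rho_sperm=v["kinetics.rho_sperm"],
            rho_egg=v["domain.rho_egg"],
        )

    def turbulence(self, epsilon: float) -> TurbulenceScales:
        v = self.values
        return TurbulenceScales(
            nu=v.get("turbulence.nu", 1e-6), epsilon=epsilon,
            a=v.get("turbulence.a", 0.075),
        )

    def provenance_report(self) -> dict[str, list[str]]:
        """Parameters grouped by provenance tag."""
        out: dict[str, list[str]] = {p: [] for p in _PROVENANCES}
        for key, prov in self.provenance.items():
            out.setdefault(prov, []).append(key)
        return {k: sorted(v) for k, v in out.items() if v}


def available_presets() -> list[str]:
    root = importlib.resources.files("chemosurf") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path: str, overrides: dict | None = None) -> Scenario:
    """Load a preset by name or a YAML scenario file by path.

    ``overrides`` maps dotted keys to SI values, e.g. {'flow.alpha': 0.2};
    overridden parameters get provenance 'user'.  Missing required
    parameters and unknown keys raise with the offending name.
    """
    path = Path(name_or_path)
    if path.suffix == ".yaml" and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        res = importlib.resources.files("chemosurf") / "presets" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"no preset or file named {name_or_path!r}; "
                f"available presets: {available_presets()}"
            )
        raw = yaml.safe_load(res.read_text())
    raw = copy.deepcopy(raw)
    name = raw.pop("name", str(name_or_path))
    raw.pop("description", None)
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for section, content in raw.items():
        if section not in _REQUIRED and section not in _FLAGS:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        for key, entry in content.items():
            dotted = f"{section}.{key}"
            known = key in _REQUIRED.get(section, []) or key in _FLAGS.get(section, [])
            if not known:
                raise ValueError(f"unknown parameter {dotted!r}")
            if isinstance(entry, bool):
                values[dotted] = entry
                provenance[dotted] = "reconstructed"
            else:
                values[dotted] = _entry_si(entry, dotted)
                provenance[dotted] = _provenance(entry)
    for section, keys in _REQUIRED.items():
        for key in keys:
            dotted = f"{section}.{key}"
            if dotted not in values:
                raise ValueError(f"missing required parameter {dotted!r}")
    for dotted, val in (overrides or {}).items():
        if dotted not in values and not any(
            dotted == f"{s}.{k}" for s, ks in {**_REQUIRED, **_FLAGS}.items() for k in ks
        ):
            raise ValueError(f"unknown override key {dotted!r}")
        values[dotted] = val
        provenance[dotted] = "user"
    return Scenario(name=name, raw=raw, values=values, provenance=provenance)
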