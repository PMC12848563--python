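"""Material modelling: chemical formulae, contrast-agent solutions, and
volume-fraction mixing of organ media with contrast media.

A material is an elemental composition (mass fractions) plus a density.
Contrast agents are aqueous solutions/suspensions whose solute mass
fraction follows from concentration (g solute per mL) and solution
density; mixing with organ media is by volume, conserving component
masses.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atomic import ATOMIC_WEIGHT, atomic_weight
from . import xsdata

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ElementalComposition:
    """A named material: density (g/cm^3) and elemental mass fractions."""

    name: str
    density: float
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"material {self.name!r}: mass fractions sum to {total!r}, not 1")
        for sym in self.fractions:
            if sym not in xsdata.available_elements():
                raise ValueError(
                    f"material {self.name!r}: element {sym!r} has no attenuation data")

    @staticmethod
    def normalized(name: str, density: float,
                   fractions: dict[str, float]) -> "ElementalComposition":
        total = sum(fractions.values())
        return ElementalComposition(
            name, density, {s: w / total for s, w in fractions.items()})


@dataclass(frozen=True)
class ContrastAgent:
    """An aqueous contrast solution/suspension.

    components: (compound formula, molecular weight g/mol, mass fraction of
    solution) for each solute; water makes up the remainder.
    """

    name: str
    components: tuple[tuple[str, float, float], ...]
    density: float            # g/mL
    concentration: float      # g of principal solute per mL

    def __post_init__(self):
        total = sum(f for _, _, f in self.components)
        if abs(total - 1.0) > 1e-4:
            raise ValueError(
                f"agent {self.name!r}: component mass fractions sum to {total}")
        if any(mw <= 0 for _, mw, _ in self.components):
            raise ValueError(f"agent {self.name!r}: molecular weights must be positive")


@dataclass(frozen=True)
class MixtureSpec:
    """Volume-fraction recipe over a material library."""

    parts: tuple[tuple[str, float], ...]

    def __post_init__(self):
        vols = [v for _, v in self.parts]
        if any(v < 0 or v > 1 for v in vols):
            raise ValueError("volume fractions must lie in [0, 1]")
        if abs(sum(vols) - 1.0) > _FRACTION_TOL:
            raise ValueError(f"volume fractions sum to {sum(vols)}, not 1")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_molecular_formula(formula: str) -> dict[str, int]:
    """Parse e.g. ``"C19H26I3N3O9"`` into element -> atom count.

    Only element symbols with optional integer subscripts are supported.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(
                f"malformed formula {formula!r} at position {pos}: "
                f"unexpected {formula[pos]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ATOMIC_WEIGHT:
            raise ValueError(
                f"malformed formula {formula!r} at position {m.start()}: "
                f"unknown element {sym!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(
                f"malformed formula {formula!r} at position {m.start()}: "
                "subscript must be positive")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(
            f"malformed formula {formula!r} at position {pos}")
    return counts


def molecular_weight(counts: dict[str, int]) -> float:
    """Molecular weight in g/mol from element counts."""
    return sum(atomic_weight(sym) * n for sym, n in counts.items())


def solution_mass_fractions(agent: ContrastAgent) -> dict[str, float]:
    """Compound -> mass fraction for an aqueous solution.

    The principal solute fraction is concentration/density; declared minor
    components keep their stated fractions; water is the remainder.
    """
    if agent.concentration > agent.density:
        raise ValueError(
            f"agent {agent.name!r}: concentration {agent.concentration} g/mL "
            f"exceeds solution density {agent.density} g/mL")
    fractions: dict[str, float] = {}
    principal = agent.components[0][0]
    fractions[principal] = agent.concentration / agent.density
    for formula, _, frac in agent.components[1:]:
        if formula != "H2O":
            fractions[formula] = frac
    fractions["H2O"] = 1.0 - sum(fractions.values())
    if fractions["H2O"] < -1e-9:
        raise ValueError(f"agent {agent.name!r}: component fractions exceed 1")
    return fractions


def compound_to_elements(compound_fractions: dict[str, float], *,
                         name: str = "mixture",
                         density: float = 1.0) -> ElementalComposition:
    """Expand compound mass fractions into an elemental composition."""
    elem: dict[str, float] = {}
    for formula, w in compound_fractions.items():
        counts = parse_molecular_formula(formula)
        mw = molecular_weight(counts)
        for sym, n in counts.items():
            elem[sym] = elem.get(sym, 0.0) + w * n * atomic_weight(sym) / mw
    return ElementalComposition.normalized(name, density, elem)


def agent_composition(agent: ContrastAgent) -> ElementalComposition:
    """Transport-ready elemental composition of a contrast agent."""
    return compound_to_elements(solution_mass_fractions(agent),
                                name=agent.name, density=agent.density)


def mix_by_volume(spec: MixtureSpec,
                  materials: dict[str, ElementalComposition],
                  name: str | None = None) -> ElementalComposition:
    """Mix materials by volume fraction, conserving component masses.

    density = sum(v_j rho_j); element fractions are mass-weighted.
    """
    parts = []
    for mat_id, vf in spec.parts:
        if mat_id not in materials:
            raise KeyError(f"material id {mat_id!r} not in library")
        parts.append((materials[mat_id], vf))
    density = sum(vf * m.density for m, vf in parts)
    elem: dict[str, float] = {}
    for m, vf in parts:
        for sym, w in m.fractions.items():
            elem[sym] = elem.get(sym, 0.0) + vf * m.density * w / density
    label = name or "+".join(f"{vf:g}*{m.name}" for m, vf in parts)
    return ElementalComposition.normalized(label, density, elem)


def mass_attenuation(material: ElementalComposition, energy_kev):
    """(mu/rho, mu_en/rho) of a material in cm^2/g via the mixture rule."""
    mu = sum(w * xsdata.mu_rho_element(sym, energy_kev, "total")
             for sym, w in material.fractions.items())
    mu_en = sum(w * xsdata.mu_rho_element(sym, energy_kev, "mu_en")
                for sym, w in material.fractions.items())
    return mu, mu_en


# --------------------------------------------------------------------------
# Packaged contrast agents (printed solution data; densities are named
# constants obtained by algebraic inversion of the printed mass fractions)
# --------------------------------------------------------------------------

EZ_PAQUE_DENSITY = 1.4641      # g/mL, = 0.600 / 0.4098
OMNIPAQUE140_DENSITY = 1.1638  # g/mL, = 0.302 / 0.2595

EZ_PAQUE = ContrastAgent(
    name="E-Z-PAQUE",
    components=(
        ("BaSO4", 233.3880, 0.4098),
        ("H2O", 18.0146, 0.5902),
    ),
    density=EZ_PAQUE_DENSITY,
    concentration=0.600,       # barium sulfate 60% w/v
)

OMNIPAQUE_140 = ContrastAgent(
    name="OMNIPAQUE-140",
    components=(
        ("C19H26I3N3O9", 821.1238, 0.2595),    # iohexol, 302 mg/mL
        ("C10H12CaN2Na2O8", 374.2676, 0.0001),  # edetate calcium disodium
        ("C4H11NO3", 121.1338, 0.0010),         # tromethamine
        ("H2O", 18.0146, 0.7394),
    ),
    density=OMNIPAQUE140_DENSITY,
    concentration=0.302,
)


# --------------------------------------------------------------------------
# Reference organ/body media (ICRU-44 style adult reference compositions;
# the licensed phantom media are not reproduced)
# --------------------------------------------------------------------------

def _mat(name, density, **fr):
    return ElementalComposition.normalized(name, density, fr)


REFERENCE_MATERIALS: dict[str, ElementalComposition] = {
    m.name: m for m in (
        _mat("air", xsdata.AIR_DENSITY, **xsdata.AIR_COMPOSITION),
        _mat("water", 1.0, **xsdata.WATER_COMPOSITION),
        _mat("soft_tissue", 1.03, H=0.105, C=0.256, N=0.027, O=0.602,
             Na=0.001, P=0.002, S=0.003, Cl=0.002, K=0.002),
        _mat("muscle", 1.05, H=0.102, C=0.143, N=0.034, O=0.710,
             Na=0.001, P=0.002, S=0.003, Cl=0.001, K=0.004),
        _mat("tongue", 1.05, H=0.102, C=0.143, N=0.034, O=0.710,
             Na=0.001, P=0.002, S=0.003, Cl=0.001, K=0.004),
        _mat("adipose", 0.95, H=0.114, C=0.598, N=0.007, O=0.278,
             Na=0.001, S=0.001, Cl=0.001),
        _mat("lung", 0.26, H=0.103, C=0.105, N=0.031, O=0.749,
             Na=0.002, P=0.002, S=0.003, Cl=0.003, K=0.002),
        _mat("skin", 1.09, H=0.100, C=0.204, N=0.042, O=0.645,
             Na=0.002, P=0.001, S=0.002, Cl=0.003, K=0.001),
        _mat("brain", 1.04, H=0.107, C=0.145, N=0.022, O=0.712,
             Na=0.002, P=0.004, S=0.002, Cl=0.003, K=0.003),
        # homogenised skeleton: mineral bone + marrow, no marrow substructure
        _mat("skeleton", 1.30, H=0.071, C=0.265, N=0.037, O=0.479,
             Na=0.001, Mg=0.001, P=0.047, S=0.002, Ca=0.097),
        _mat("gi_contents", 1.03, H=0.100, C=0.222, N=0.022, O=0.644,
             Na=0.001, P=0.002, S=0.003, Cl=0.001, K=0.005),
        _mat("aluminium", 2.699, Al=1.0),
        _mat("copper", 8.960, Cu=1.0),
        _mat("tungsten", 19.30, W=1.0),
    )
}
REFERENCE_MATERIALS["ez_paque"] = agent_composition(EZ_PAQUE)
REFERENCE_MATERIALS["omnipaque_140"] = agent_composition(OMNIPAQUE_140)


# --------------------------------------------------------------------------
# Material library round-trip (plain JSON)
# --------------------------------------------------------------------------

def save_material_library(materials: dict[str, ElementalComposition],
                          path: str | Path) -> None:
    payload = {
        mid: {"name": m.name,
              "density": float(f"{m.density:.9g}"),
              "fractions": {s: float(f"{w:.9g}")
                            for s, w in sorted(m.fractions.items())}}
        for mid, m in materials.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_material_library(path: str | Path) -> dict[str, ElementalComposition]:
    payload = json.loads(Path(path).read_text())
    return {
        mid: ElementalComposition.normalized(
            rec["name"], rec["density"], dict(rec["fractions"]))
        for mid, rec in payload.items()
    }
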