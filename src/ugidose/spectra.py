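"""Tungsten-anode x-ray spectra in 1-keV bins: generation, filtration,
half-value-layer (HVL) computation and matching, and energy sampling.

The unfiltered spectrum is a semi-empirical tungsten-anode model: a Kramers
bremsstrahlung continuum hardened by anode self-filtration, plus the
tungsten K characteristic lines above the K-shell binding energy
(69.525 keV).  Only the behaviour of the beam after HVL matching is relied
upon downstream, and that is validated against published
(kVp, HVL, mean energy) benchmarks.

HVL is defined on narrow-beam air-kerma transmission: the aluminium
thickness halving sum(w_i * E_i * mu_en_air(E_i) * exp(-mu_Al(E_i) t)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import xsdata
from .materials import ElementalComposition, REFERENCE_MATERIALS

W_K_EDGE_KEV = 69.525
AL_DENSITY = 2.699   # g/cm^3
CU_DENSITY = 8.960

# Tungsten K lines: (energy keV, relative intensity)
_K_LINES = ((59.318, 1.00), (57.982, 0.576), (67.244, 0.219),
            (66.951, 0.114), (69.067, 0.083))
# Effective anode self-filtration path, mm of tungsten.
ANODE_SELF_FILTRATION_MM_W = 0.004
# Scales the K-line yield; set so clinically filtered beams at 110-120 kVp
# carry the textbook ~10% characteristic fluence share.
_K_LINE_YIELD = 0.10


@dataclass
class Spectrum:
    """Relative photon fluence per 1-keV bin up to the peak tube potential."""

    kvp: float
    energies: np.ndarray   # bin centres, keV
    weights: np.ndarray    # relative photons per bin, >= 0

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.energies.shape != self.weights.shape:
            raise ValueError("energies and weights must have equal shape")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("spectrum has no fluence")
        if np.any((self.weights > 0) & (self.energies > self.kvp + 1e-9)):
            raise ValueError("fluence above the peak tube potential")

    @property
    def hvl_mm_al(self) -> float:
        return compute_hvl(self)

    @property
    def mean_energy_kev(self) -> float:
        return mean_energy(self)


def _kerma_weights(s: Spectrum) -> np.ndarray:
    mu_en_air = np.array([
        sum(w * xsdata.mu_rho_element(sym, e, "mu_en")
            for sym, w in xsdata.AIR_COMPOSITION.items())
        for e in s.energies])
    return s.weights * s.energies * mu_en_air


def generate_unfiltered_spectrum(kvp: float) -> Spectrum:
    """Semi-empirical tube output spectrum at `kvp` kilovolts (20-150)."""
    if not 20.0 <= kvp <= 150.0:
        raise ValueError(f"kVp {kvp} outside the supported 20-150 range")
    energies = np.arange(1.0, np.floor(kvp) + 1.0)
    w = np.clip(kvp - energies, 0.0, None) / energies
    mu_w = np.array([xsdata.mu_rho_element("W", e, "total") for e in energies])
    self_filter = np.exp(-mu_w * 19.30 * ANODE_SELF_FILTRATION_MM_W / 10.0)
    w = w * self_filter
    if kvp > W_K_EDGE_KEV:
        overvoltage = kvp / W_K_EDGE_KEV - 1.0
        yield_total = _K_LINE_YIELD * overvoltage**1.63 * w.sum()
        norm = sum(r for _, r in _K_LINES)
        for e_line, rel in _K_LINES:
            idx = int(round(e_line)) - 1
            w[idx] += yield_total * rel / norm
    return Spectrum(kvp=float(kvp), energies=energies, weights=w)


def filter_spectrum(s: Spectrum, material: ElementalComposition,
                    thickness_mm: float) -> Spectrum:
    """Attenuate each bin by exp(-mu(E) * t); energies unchanged."""
    if thickness_mm < 0:
        raise ValueError("filter thickness must be nonnegative")
    mu = np.array([
        sum(w * xsdata.mu_rho_element(sym, e, "total")
            for sym, w in material.fractions.items())
        for e in s.energies]) * material.density
    return Spectrum(kvp=s.kvp, energies=s.energies,
                    weights=s.weights * np.exp(-mu * thickness_mm / 10.0))


def mean_energy(s: Spectrum) -> float:
    """Fluence-weighted mean energy, keV."""
    total = s.weights.sum()
    if total <= 0:
        raise ValueError("spectrum has no fluence")
    return float((s.weights * s.energies).sum() / total)


def compute_hvl(s: Spectrum) -> float:
    """First half-value layer in mm of aluminium (air-kerma transmission)."""
    k = _kerma_weights(s)
    mu_al = np.array([xsdata.mu_rho_element("Al", e, "total")
                      for e in s.energies]) * AL_DENSITY
    k0 = k.sum()

    def transmitted(t_mm: float) -> float:
        return float((k * np.exp(-mu_al * t_mm / 10.0)).sum())

    lo, hi = 0.0, 1.0
    while transmitted(hi) > 0.5 * k0:
        hi *= 2.0
        if hi > 1024.0:
            raise RuntimeError("HVL search did not bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if transmitted(mid) > 0.5 * k0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-5:
            break
    return 0.5 * (lo + hi)


_HVL_TOL_MM = 0.01


def match_hvl(kvp: float, target_mm_al: float) -> Spectrum:
    """Filter a `kvp` spectrum with aluminium until its HVL matches.

    Falls back to a fixed 0.9 Cu / 0.1 Al thickness mix if aluminium alone
    cannot reach the target; raises if the target is unachievable.
    """
    base = generate_unfiltered_spectrum(kvp)
    hvl0 = compute_hvl(base)
    if target_mm_al < hvl0 - _HVL_TOL_MM:
        raise ValueError(
            f"target HVL {target_mm_al} mm Al below the unfiltered beam's "
            f"{hvl0:.3f} mm Al at {kvp} kVp")
    if abs(target_mm_al - hvl0) <= _HVL_TOL_MM:
        return base

    def try_filtration(apply) -> Spectrum | None:
        lo, hi = 0.0, 1.0
        while compute_hvl(apply(hi)) < target_mm_al:
            hi *= 2.0
            if hi > 512.0:
                return None
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            s_mid = apply(mid)
            h = compute_hvl(s_mid)
            if abs(h - target_mm_al) < _HVL_TOL_MM:
                return s_mid
            if h < target_mm_al:
                lo = mid
            else:
                hi = mid
        return None

    al = REFERENCE_MATERIALS["aluminium"]
    cu = REFERENCE_MATERIALS["copper"]
    matched = try_filtration(lambda t: filter_spectrum(base, al, t))
    if matched is None:
        matched = try_filtration(
            lambda t: filter_spectrum(filter_spectrum(base, cu, 0.9 * t),
                                      al, 0.1 * t))
    if matched is None:
        raise ValueError(
            f"target HVL {target_mm_al} mm Al unachievable at {kvp} kVp")
    return matched


def sample_energy(s: Spectrum, rng: np.random.Generator,
                  n: int = 1) -> np.ndarray:
    """Sample photon energies: inverse-CDF over bins, uniform within bin."""
    cdf = np.cumsum(s.weights)
    cdf = cdf / cdf[-1]
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return s.energies[idx] + rng.uniform(-0.5, 0.5, size=n)


def save_spectrum(s: Spectrum, path: str | Path) -> None:
    header = (f"# kVp {s.kvp:.6g}\n"
              f"# HVL_mm_Al {compute_hvl(s):.6g}\n"
              f"# mean_energy_keV {mean_energy(s):.6g}\n")
    body = "\n".join(f"{e:.6g} {w:.9g}"
                     for e, w in zip(s.energies, s.weights))
    Path(path).write_text(header + body + "\n")


def load_spectrum(path: str | Path) -> Spectrum:
    kvp = None
    energies, weights = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields and fields[0] == "kVp":
                kvp = float(fields[1])
            continue
        e, w = line.split()
        energies.append(float(e))
        weights.append(float(w))
    if kvp is None:
        raise ValueError(f"{path}: missing '# kVp' header")
    return Spectrum(kvp=kvp, energies=np.array(energies),
                    weights=np.array(weights))
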