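"""Dose coefficients, the kerma-area-product scaling model, examination
dose synthesis, and detriment-weighted dose.

Dose coefficients (DCs) are organ absorbed dose per unit kerma-area
product, mGy/(Gy cm^2).  DCs computed on a (kVp, HVL) grid are
interpolated linearly in HVL and log-linearly in kVp to the clinical
technique factors.  Per-examination kerma-area product is distributed over
fluoroscopy pulses and radiographic spot frames by

    P_KA_total = P_KA_pulse * (t * R + k * N)

with t the fluoroscopy time, R the pulse rate, k the pulse-equivalents per
spot film and N the number of films; the per-pulse product is obtained by
pooling the reference normal examinations against the published median
total of 0.02 Gy cm^2.  Total organ doses follow the per-field linear
combination of fluoroscopy and spot-film components, and the
detriment-weighted dose applies the ICRP-103 tissue weighting factors to
the female phantom's organ doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --------------------------------------------------------------------------
# KAP scaling model
# --------------------------------------------------------------------------

MEDIAN_TOTAL_KAP_GY_CM2 = 0.02   # published median for 0-1 year-old studies
PULSE_RATE_HZ = 7.5              # fluoroscopy pulses per second
PULSES_PER_SPOT_FILM = 26.0      # measured pulse-equivalents per spot film
SPOT_FILMS_PER_EXAM = 6
NORMAL_FLUORO_SECONDS = {"newborn": 75.0, "one_year": 95.0}


@dataclass(frozen=True)
class KAPModel:
    """Solved per-pulse/per-frame kerma-area products (mGy cm^2)."""

    p_pulse_mgy_cm2: float
    p_frame_mgy_cm2: float
    pulse_rate_hz: float = PULSE_RATE_HZ
    pulses_per_film: float = PULSES_PER_SPOT_FILM


def solve_pulse_kap(median_total_gy_cm2: float = MEDIAN_TOTAL_KAP_GY_CM2,
                    fluoro_seconds: tuple[float, ...] = (
                        NORMAL_FLUORO_SECONDS["newborn"],
                        NORMAL_FLUORO_SECONDS["one_year"]),
                    pulse_rate_hz: float = PULSE_RATE_HZ,
                    pulses_per_film: float = PULSES_PER_SPOT_FILM,
                    films: int = SPOT_FILMS_PER_EXAM) -> KAPModel:
    """Pooled solve of the pulse scaling model over the reference exams.

    Each examination delivers the median total KAP; pooling the listed
    examinations gives
    n_exam * median = P_pulse * (sum(t) * R + n_exam * k * N).
    """
    if median_total_gy_cm2 <= 0 or min(fluoro_seconds) <= 0:
        raise ValueError("model inputs must be positive")
    n = len(fluoro_seconds)
    pulses = sum(fluoro_seconds) * pulse_rate_hz + n * pulses_per_film * films
    p_pulse_gy = n * median_total_gy_cm2 / pulses
    return KAPModel(p_pulse_mgy_cm2=p_pulse_gy * 1e3,
                    p_frame_mgy_cm2=p_pulse_gy * 1e3 * pulses_per_film,
                    pulse_rate_hz=pulse_rate_hz,
                    pulses_per_film=pulses_per_film)


@dataclass(frozen=True)
class KAPSchedule:
    """Per-field kerma-area products, Gy cm^2."""

    field_ids: tuple[str, ...]
    fluoro_gy_cm2: tuple[float, ...]
    rad_gy_cm2: tuple[float, ...]

    @property
    def total_fluoro(self) -> float:
        return sum(self.fluoro_gy_cm2)

    @property
    def total_rad(self) -> float:
        return sum(self.rad_gy_cm2)

    @property
    def total(self) -> float:
        return self.total_fluoro + self.total_rad


def kap_schedule(protocol, model: KAPModel) -> KAPSchedule:
    """Per-field fluoro/spot-film KAPs for an examination protocol."""
    p_pulse_gy = model.p_pulse_mgy_cm2 * 1e-3
    p_frame_gy = model.p_frame_mgy_cm2 * 1e-3
    ids, fl, rad = [], [], []
    for f in protocol.fields:
        ids.append(f.field_id)
        fl.append(p_pulse_gy * f.fluoro_seconds * model.pulse_rate_hz)
        rad.append(p_frame_gy if f.spot_film else 0.0)
    return KAPSchedule(tuple(ids), tuple(fl), tuple(rad))


# --------------------------------------------------------------------------
# Dose coefficients
# --------------------------------------------------------------------------

def compute_dc(dose_per_history: dict[str, float],
               kap_per_history_gy_cm2: float) -> dict[str, float]:
    """Organ dose coefficients, mGy/(Gy cm^2), from tally and KAP."""
    if kap_per_history_gy_cm2 <= 0:
        raise ValueError("kerma-area product per history must be positive")
    return {organ: 1e3 * d / kap_per_history_gy_cm2
            for organ, d in dose_per_history.items()}


def interpolate_dc(grid: dict[tuple[float, float], float],
                   kvp: float, hvl: float) -> float:
    """Interpolate a DC grid: linear in HVL, then log-linear in kVp.

    `grid` maps (kVp, HVL mm Al) -> DC with two HVL nodes per kVp.
    Out-of-range targets raise (no extrapolation).
    """
    by_kvp: dict[float, list[tuple[float, float]]] = {}
    for (kv, h), v in grid.items():
        by_kvp.setdefault(kv, []).append((h, v))
    kvps = sorted(by_kvp)
    if not kvps[0] <= kvp <= kvps[-1]:
        raise ValueError(f"kVp {kvp} outside grid range {kvps[0]}-{kvps[-1]}")

    def at_kvp(kv: float) -> float:
        nodes = sorted(by_kvp[kv])
        hvls = [h for h, _ in nodes]
        if not hvls[0] - 1e-9 <= hvl <= hvls[-1] + 1e-9:
            raise ValueError(
                f"HVL {hvl} outside grid range {hvls[0]}-{hvls[-1]} "
                f"at {kv} kVp")
        return float(np.interp(hvl, hvls, [v for _, v in nodes]))

    if kvp in by_kvp:
        return at_kvp(kvp)
    hi = min(kv for kv in kvps if kv > kvp)
    lo = max(kv for kv in kvps if kv < kvp)
    w_lo = (np.log(hi) - np.log(kvp)) / (np.log(hi) - np.log(lo))
    return float(w_lo * at_kvp(lo) + (1.0 - w_lo) * at_kvp(hi))


def interpolate_dc_set(grid: dict[tuple[float, float], dict[str, float]],
                       kvp: float, hvl: float) -> dict[str, float]:
    """Per-organ DC interpolation (applies `interpolate_dc` organ-wise)."""
    organs = next(iter(grid.values())).keys()
    return {
        organ: interpolate_dc({node: dcs[organ] for node, dcs in grid.items()},
                              kvp, hvl)
        for organ in organs
    }


# --------------------------------------------------------------------------
# Dose synthesis (per-field linear combination)
# --------------------------------------------------------------------------

@dataclass
class DoseCoefficientSet:
    """DCs per (field, component): component is 'fluoro' or 'rad'."""

    dcs: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def get(self, field_id: str, component: str) -> dict[str, float]:
        try:
            return self.dcs[(field_id, component)]
        except KeyError:
            raise KeyError(
                f"no dose coefficients for field {field_id!r}, "
                f"component {component!r}") from None


def total_dose(dcs: DoseCoefficientSet, sched: KAPSchedule) -> dict[str, float]:
    """Total examination organ doses, mGy.

    Dose_i = sum_f KAP_f^fluoro DC_{i,f}^fluoro + KAP_f^rad DC_{i,f}^rad.
    A single-field dose is the same sum restricted to that field.
    """
    totals: dict[str, float] = {}
    for fid, kap_fl, kap_rad in zip(sched.field_ids, sched.fluoro_gy_cm2,
                                    sched.rad_gy_cm2):
        parts = [(kap_fl, dcs.get(fid, "fluoro"))]
        if kap_rad > 0:
            parts.append((kap_rad, dcs.get(fid, "rad")))
        for kap, organ_dcs in parts:
            for organ, dc in organ_dcs.items():
                if dc < 0:
                    raise ValueError(f"negative DC for {organ!r} in {fid!r}")
                totals[organ] = totals.get(organ, 0.0) + kap * dc
    return totals


# --------------------------------------------------------------------------
# Detriment-weighted dose (ICRP-103 tissue weighting)
# --------------------------------------------------------------------------

#: ICRP-103 tissue weighting factors (sum to 1.00).
TISSUE_WEIGHTS: dict[str, float] = {
    "red_marrow": 0.12, "colon": 0.12, "lung": 0.12, "stomach": 0.12,
    "breast": 0.12, "remainder": 0.12,
    "gonads": 0.08,
    "bladder": 0.04, "oesophagus": 0.04, "liver": 0.04, "thyroid": 0.04,
    "bone_surface": 0.01, "brain": 0.01, "salivary_glands": 0.01,
    "skin": 0.01,
}

#: ICRP-103 remainder tissues (female list).
REMAINDER_TISSUES = (
    "adrenals", "extrathoracic", "gall_bladder", "heart", "kidneys",
    "lymph_nodes", "muscle", "oral_mucosa", "pancreas", "small_intestine",
    "spleen", "thymus", "uterus_cervix",
)

#: tissue -> phantom region providing its dose.  Tissues the synthetic
#: phantom does not resolve take the residual-soft-tissue dose; marrow and
#: bone surface take the homogenised skeleton dose.
TISSUE_REGION_MAP: dict[str, str] = {
    "red_marrow": "skeleton", "bone_surface": "skeleton",
    "colon": "colon", "lung": "lungs", "stomach": "stomach_wall",
    "breast": "breast", "gonads": "ovaries", "bladder": "bladder",
    "oesophagus": "oesophagus", "liver": "liver", "thyroid": "thyroid",
    "brain": "brain", "skin": "skin", "salivary_glands": "residual",
    "adrenals": "residual", "extrathoracic": "residual",
    "gall_bladder": "residual", "heart": "heart_wall", "kidneys": "kidneys",
    "lymph_nodes": "residual", "muscle": "residual",
    "oral_mucosa": "tongue", "pancreas": "residual",
    "small_intestine": "si_wall", "spleen": "spleen", "thymus": "thymus",
    "uterus_cervix": "residual",
}


def detriment_weighted_dose(region_doses: dict[str, float],
                            weights: dict[str, float] | None = None,
                            region_map: dict[str, str] | None = None) -> float:
    """Detriment-weighted dose, mSv, from per-region doses in mGy.

    Photon radiation weighting is 1 so H_T (mSv) = D_T (mGy); the
    remainder term is the arithmetic mean over the remainder tissues.
    """
    weights = TISSUE_WEIGHTS if weights is None else weights
    region_map = TISSUE_REGION_MAP if region_map is None else region_map
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-6:
        raise ValueError(f"tissue weights sum to {total_w}, not 1")

    def tissue_dose(tissue: str) -> float:
        region = region_map.get(tissue)
        if region is None:
            raise KeyError(f"tissue {tissue!r} has no phantom region mapping")
        if region not in region_doses:
            raise KeyError(f"region {region!r} missing from dose set")
        return region_doses[region]

    out = 0.0
    for tissue, w in weights.items():
        if tissue == "remainder":
            out += w * float(np.mean([tissue_dose(t)
                                      for t in REMAINDER_TISSUES]))
        else:
            out += w * tissue_dose(tissue)
    return out


# --------------------------------------------------------------------------
# Ratio tables
# --------------------------------------------------------------------------

def contrast_ratio_table(with_contrast: dict[str, dict[str, float]],
                         without_contrast: dict[str, dict[str, float]],
                         decimals: int | None = 2
                         ) -> dict[str, dict[str, float | None]]:
    """Per-organ, per-field with/without-contrast dose ratios.

    Inputs map column (field id or 'Total') -> organ -> dose.  The 'Total'
    column ratio is the ratio of the summed doses, not the mean of field
    ratios.  Zero denominators yield None entries.
    """
    if set(with_contrast) != set(without_contrast):
        raise ValueError("field sets differ between the two dose sets")
    table: dict[str, dict[str, float | None]] = {}
    for col, w_doses in with_contrast.items():
        wo_doses = without_contrast[col]
        if set(w_doses) != set(wo_doses):
            raise ValueError(f"organ sets differ in column {col!r}")
        row: dict[str, float | None] = {}
        for organ, w in w_doses.items():
            wo = wo_doses[organ]
            if w == wo:
                row[organ] = 1.0   # shared simulation / identical inputs
            elif wo == 0:
                row[organ] = None
            else:
                r = w / wo
                row[organ] = round(r, decimals) if decimals is not None else r
        table[col] = row
    return table
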