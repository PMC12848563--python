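"""End-to-end examination runs: phantom + contrast -> transport -> dose
coefficients -> KAP schedule -> total and detriment-weighted doses ->
with/without-contrast ratio tables, plus report writing.

Each imaging field is simulated twice (with and without contrast); fields
that carry no contrast share the same simulation so their dose ratios are
exactly 1.  Oesophagus and tongue doses in the with-contrast arm are
replaced by the without-contrast values before detriment weighting: the
synthetic anatomy (like the reference voxel anatomy) has no separate
oesophageal lumen or oral cavity, so contrast is mixed into those organs
themselves, which would artificially inflate their reported doses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .dosimetry import (DoseCoefficientSet, KAPSchedule, REMAINDER_TISSUES,
                        TISSUE_REGION_MAP, compute_dc, contrast_ratio_table,
                        detriment_weighted_dose, interpolate_dc_set,
                        kap_schedule, solve_pulse_kap, total_dose)
from .phantom import apply_contrast, build_phantom
from .protocols import ExaminationProtocol, load_protocol
from .spectra import Spectrum, compute_hvl, match_hvl, mean_energy, save_spectrum
from .transport import (TransportConfig, TallyResult, air_kerma_per_history,
                        kap_per_history, run_transport)

#: clinical technique factors (kVp, HVL mm Al)
CLINICAL_TECHNIQUES = {"fluoro": (65.0, 4.41), "rad": (85.0, 3.22)}
#: the six-node DC grid (kVp, HVL mm Al)
DC_GRID_NODES = ((60.0, 2.5000), (60.0, 5.7448), (80.0, 2.9000),
                 (80.0, 7.7020), (110.0, 3.9000), (110.0, 9.9905))

#: organs whose doses are replaced by the non-contrast values before
#: detriment weighting (no separate lumen/cavity in the voxel anatomy).
SUBSTITUTED_ORGANS = ("oesophagus", "tongue")

#: ratio-report rows: display name -> phantom region ('remainder' and
#: 'detriment_weighted' are synthesised).
REPORT_ORGANS = {
    "colon": "colon", "heart_wall": "heart_wall", "kidneys": "kidneys",
    "lungs": "lungs", "marrow_surrogate": "skeleton", "si_wall": "si_wall",
    "spleen": "spleen", "stomach_wall": "stomach_wall", "thymus": "thymus",
    "thyroid": "thyroid",
}


@dataclass(frozen=True)
class RunConfig:
    age: str = "newborn"
    diagnosis: str = "normal"
    contrast: bool = True
    histories: int = 40_000
    batches: int = 20
    seed: int = 1
    voxel_mm: float = 4.0
    output_dir: str | None = None
    dc_mode: str = "clinical"        # 'clinical' or 'grid'
    fluoro_kvp: float = CLINICAL_TECHNIQUES["fluoro"][0]
    fluoro_hvl: float = CLINICAL_TECHNIQUES["fluoro"][1]
    rad_kvp: float = CLINICAL_TECHNIQUES["rad"][0]
    rad_hvl: float = CLINICAL_TECHNIQUES["rad"][1]


@dataclass
class ExaminationResult:
    config: RunConfig
    protocol: ExaminationProtocol
    schedule: KAPSchedule
    field_doses: dict[str, dict[str, dict[str, float]]]      # state -> field -> organ
    total_doses: dict[str, dict[str, float]]                 # state -> organ
    dw_doses: dict[str, float]                               # state -> mSv
    dc_sets: dict[str, DoseCoefficientSet]
    dc_errors: dict[str, dict[tuple[str, str], dict[str, float]]]
    spectra: dict[str, Spectrum]

    def ratio_table(self) -> dict[str, dict[str, float | None]]:
        """Tables shaped like the published per-field ratio reports."""
        cols_with, cols_without = {}, {}
        for fid in self.schedule.field_ids:
            cols_with[fid] = _report_row(self.field_doses["contrast"][fid])
            cols_without[fid] = _report_row(self.field_doses["reference"][fid])
        cols_with["Total"] = _report_row(self.total_doses["contrast"])
        cols_without["Total"] = _report_row(self.total_doses["reference"])
        # per-field detriment-weighted entries
        for fid in list(self.schedule.field_ids):
            cols_with[fid]["detriment_weighted"] = _dw(
                self.field_doses["contrast"][fid])
            cols_without[fid]["detriment_weighted"] = _dw(
                self.field_doses["reference"][fid])
        cols_with["Total"]["detriment_weighted"] = self.dw_doses["contrast"]
        cols_without["Total"]["detriment_weighted"] = self.dw_doses["reference"]
        return contrast_ratio_table(cols_with, cols_without)


def _report_row(organ_doses: dict[str, float]) -> dict[str, float]:
    row = {name: organ_doses[region] for name, region in REPORT_ORGANS.items()}
    row["remainder"] = float(np.mean(
        [organ_doses[TISSUE_REGION_MAP[t]] for t in REMAINDER_TISSUES]))
    return row


def _dw(organ_doses: dict[str, float]) -> float:
    return detriment_weighted_dose(organ_doses)


def _clinical_spectra(config: RunConfig) -> dict[str, Spectrum]:
    return {"fluoro": match_hvl(config.fluoro_kvp, config.fluoro_hvl),
            "rad": match_hvl(config.rad_kvp, config.rad_hvl)}


def _tally_doses(tally: TallyResult) -> dict[str, float]:
    return {r: d for r, d in tally.dose.items() if r != "air"}


def run_examination(config: RunConfig) -> ExaminationResult:
    """Execute a full with/without-contrast examination simulation."""
    protocol = load_protocol(config.age, config.diagnosis)
    phantom = build_phantom(config.age, config.voxel_mm)
    dist = protocol.contrast_distribution()
    model = solve_pulse_kap()
    schedule = kap_schedule(protocol, model)
    spectra = _clinical_spectra(config)
    if config.dc_mode == "grid":
        grid_spectra = {node: match_hvl(*node) for node in DC_GRID_NODES}
    elif config.dc_mode != "clinical":
        raise ValueError(f"unknown dc_mode {config.dc_mode!r}")

    states = ("reference", "contrast") if config.contrast else ("reference",)
    dc_sets = {s: DoseCoefficientSet() for s in states}
    dc_errors: dict[str, dict] = {s: {} for s in states}
    field_doses: dict[str, dict] = {s: {} for s in states}

    base_cfg = dict(histories=config.histories, batches=config.batches)
    kap_cache: dict[tuple, float] = {}
    for idx, f in enumerate(protocol.fields):
        beam = protocol.beam_for_field(phantom, f)
        components = [("fluoro", True)]
        if f.spot_film:
            components.append(("rad", True))
        has_contrast = bool(f.contrast)
        for state in states:
            if state == "contrast" and has_contrast:
                ph = apply_contrast(phantom, dist, f.field_id)
            elif state == "contrast" and not has_contrast:
                # share the reference simulation: identical geometry/material
                dc_sets["contrast"].dcs.update({
                    (f.field_id, c): dc_sets["reference"].dcs[(f.field_id, c)]
                    for c, _ in components})
                dc_errors["contrast"].update({
                    (f.field_id, c): dc_errors["reference"][(f.field_id, c)]
                    for c, _ in components})
                continue
            else:
                ph = phantom
            for ci, (comp, _) in enumerate(components):
                spectrum = spectra[comp]
                seed = (config.seed + 1009 * idx + 101 * ci) % (2**31 - 1)
                tcfg = TransportConfig(seed=seed, **base_cfg)
                tally = run_transport(ph, beam, spectrum, tcfg)
                kap_key = (f.field_id, comp)
                if kap_key not in kap_cache:
                    kcfg = TransportConfig(seed=seed, **base_cfg)
                    kap_cache[kap_key], _ = kap_per_history(beam, spectrum,
                                                            kcfg)
                dcs = compute_dc(_tally_doses(tally), kap_cache[kap_key])
                dc_sets[state].dcs[(f.field_id, comp)] = dcs
                dc_errors[state][(f.field_id, comp)] = {
                    r: e for r, e in tally.relative_error.items()
                    if r != "air"}

    total_doses, dw_doses, per_field = {}, {}, {}
    for state in states:
        per_field[state] = {}
        for fid, kap_fl, kap_rad in zip(schedule.field_ids,
                                        schedule.fluoro_gy_cm2,
                                        schedule.rad_gy_cm2):
            sub = KAPSchedule((fid,), (kap_fl,), (kap_rad,))
            per_field[state][fid] = total_dose(dc_sets[state], sub)
        total_doses[state] = total_dose(dc_sets[state], schedule)
    if "contrast" in states:
        # lumen/cavity substitution before detriment weighting
        for fid in schedule.field_ids:
            for organ in SUBSTITUTED_ORGANS:
                per_field["contrast"][fid][organ] = \
                    per_field["reference"][fid][organ]
        for organ in SUBSTITUTED_ORGANS:
            total_doses["contrast"][organ] = total_doses["reference"][organ]
    for state in states:
        dw_doses[state] = detriment_weighted_dose(total_doses[state])
    if "contrast" not in states:
        per_field["contrast"] = per_field["reference"]
        total_doses["contrast"] = total_doses["reference"]
        dw_doses["contrast"] = dw_doses["reference"]
        dc_sets["contrast"] = dc_sets["reference"]
        dc_errors["contrast"] = dc_errors["reference"]

    result = ExaminationResult(
        config=config, protocol=protocol, schedule=schedule,
        field_doses=per_field, total_doses=total_doses, dw_doses=dw_doses,
        dc_sets=dc_sets, dc_errors=dc_errors, spectra=spectra)
    if config.output_dir is not None:
        emit_reports(result, Path(config.output_dir))
    return result


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def emit_reports(result: ExaminationResult, outdir: Path) -> list[Path]:
    """Write KAP-schedule, DC, dose, ratio and summary reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    sched = result.schedule
    lines = ["component," + ",".join(sched.field_ids) + ",Total"]
    lines.append("fluoroscopy," + ",".join(f"{v:.4g}" for v in
                                           sched.fluoro_gy_cm2)
                 + f",{sched.total:.4g}")
    lines.append("spot_film," + ",".join(
        f"{v:.4g}" if v > 0 else "-" for v in sched.rad_gy_cm2) + ",")
    p = outdir / "kap_schedule.csv"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    for state in ("reference", "contrast"):
        rows = ["organ,field,component,value_mgy_per_gycm2,rel_error"]
        for (fid, comp), dcs in sorted(result.dc_sets[state].dcs.items()):
            errs = result.dc_errors[state][(fid, comp)]
            for organ in sorted(dcs):
                rows.append(f"{organ},{fid},{comp},{dcs[organ]:.6g},"
                            f"{errs.get(organ, 0.0):.4g}")
        p = outdir / f"dose_coefficients_{state}.csv"
        p.write_text("\n".join(rows) + "\n")
        written.append(p)

    ratios = result.ratio_table()
    cols = list(sched.field_ids) + ["Total"]
    rows = ["organ," + ",".join(cols)]
    organs = list(next(iter(ratios.values())).keys())
    for organ in organs:
        cells = []
        for c in cols:
            v = ratios[c][organ]
            cells.append("-" if v is None else f"{v:.2f}")
        rows.append(f"{organ}," + ",".join(cells))
    p = outdir / "contrast_dose_ratios.csv"
    p.write_text("\n".join(rows) + "\n")
    written.append(p)

    for comp, s in result.spectra.items():
        p = outdir / f"spectrum_{comp}.txt"
        save_spectrum(s, p)
        written.append(p)

    summary = {
        "version": __version__,
        "config": {k: getattr(result.config, k) for k in
                   ("age", "diagnosis", "contrast", "histories", "batches",
                    "seed", "voxel_mm", "dc_mode")},
        "spectra": {comp: {"kvp": s.kvp, "hvl_mm_al": compute_hvl(s),
                           "mean_energy_kev": mean_energy(s)}
                    for comp, s in result.spectra.items()},
        "kap_total_gy_cm2": sched.total,
        "detriment_weighted_dose_msv": result.dw_doses,
        "total_organ_doses_mgy": result.total_doses,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(p)
    return written
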