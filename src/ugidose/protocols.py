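"""Reference upper-GI examination protocols: newborn / 1-year-old female,
normal (barium) and abnormal (iodinated, tube-administered) diagnoses.

Each protocol is a JSON file packaged under ``ugidose/data/protocols``
(one per age/diagnosis) defining the ordered imaging fields: projection,
fluoroscopy seconds, spot-film flag, the per-field contrast recipe, and an
anatomical field box resolved against phantom landmarks at run time.

Normal series: nine fields following swallowed barium from mouth to small
intestine, spot films on fields 4-9.  Abnormal series: seven fields with
iodinated contrast injected directly into the stomach, spot films on
fields 1 and 3-7.  Fluoroscopy totals: 75 s (newborn normal), 95 s
(1-year-old normal), 80 s (newborn abnormal), 95 s (1-year-old abnormal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .beam import BeamField, window_for_box, PROJECTION_ANGLES
from .materials import MixtureSpec
from .phantom import ContrastDistribution, VoxelPhantom, CONTRAST_REGIONS
from .dosimetry import PULSE_RATE_HZ, SPOT_FILMS_PER_EXAM

ALLOWED_FLUORO_SECONDS = (5.0, 10.0, 15.0, 20.0)

#: total fluoroscopy seconds per (age, diagnosis)
TOTAL_FLUORO_SECONDS = {
    ("newborn", "normal"): 75.0,
    ("one_year", "normal"): 95.0,
    ("newborn", "abnormal"): 80.0,
    ("one_year", "abnormal"): 95.0,
}


@dataclass(frozen=True)
class FieldBox:
    """Anatomical field box: longitudinal range from organ anchors plus a
    transverse width as a fraction of the trunk width."""

    z_lo: tuple[str, str, float]   # (region, 'lo'|'hi'|'mid', offset cm)
    z_hi: tuple[str, str, float]
    width_fraction: float

    def resolve(self, phantom: VoxelPhantom) -> tuple[float, float, float]:
        """(z bottom, z top, width cm) on a concrete phantom."""
        scale = phantom.height_cm / 51.0

        def anchor(spec):
            region, edge, off = spec
            lo, hi = phantom.region_bbox_cm(region)
            z = {"lo": lo[2], "hi": hi[2], "mid": 0.5 * (lo[2] + hi[2])}[edge]
            return z + off * scale

        lo_t, hi_t = phantom.region_bbox_cm("residual")
        trunk_width = hi_t[0] - lo_t[0]
        return anchor(self.z_lo), anchor(self.z_hi), \
            self.width_fraction * trunk_width


@dataclass(frozen=True)
class ImagingField:
    field_id: str
    projection: str
    fluoro_seconds: float
    spot_film: bool
    box: FieldBox
    contrast: dict[str, MixtureSpec] = field(default_factory=dict)


@dataclass(frozen=True)
class ExaminationProtocol:
    age_class: str
    diagnosis: str
    fields: tuple[ImagingField, ...]
    pulse_rate_hz: float = PULSE_RATE_HZ

    @property
    def total_fluoro_seconds(self) -> float:
        return sum(f.fluoro_seconds for f in self.fields)

    @property
    def n_spot_films(self) -> int:
        return sum(1 for f in self.fields if f.spot_film)

    def contrast_distribution(self) -> ContrastDistribution:
        return ContrastDistribution(
            {f.field_id: f.contrast for f in self.fields})

    def beam_for_field(self, phantom: VoxelPhantom,
                       f: ImagingField) -> BeamField:
        import numpy as np
        z_lo, z_hi, width = f.box.resolve(phantom)
        # aim through the trunk axis (midline)
        target = np.array([0.0, 0.0, 0.5 * (z_lo + z_hi)])
        return BeamField(projection=f.projection,
                         window_cm=window_for_box(width, z_hi - z_lo),
                         target_cm=target)


def _mixture(parts) -> MixtureSpec:
    return MixtureSpec(tuple((str(mid), float(vf)) for mid, vf in parts))


def load_protocol(age: str, diagnosis: str) -> ExaminationProtocol:
    """Load and validate a packaged protocol."""
    key = (age, diagnosis)
    if key not in TOTAL_FLUORO_SECONDS:
        raise ValueError(f"unknown protocol {age!r}/{diagnosis!r}")
    name = f"{age}_{diagnosis}.json"
    ref = resources.files("ugidose.data.protocols").joinpath(name)
    payload = json.loads(ref.read_text())
    fields = []
    for rec in payload["fields"]:
        contrast = {region: _mixture(parts)
                    for region, parts in rec.get("contrast", {}).items()}
        for region in contrast:
            if region not in CONTRAST_REGIONS:
                raise ValueError(f"{name}: bad contrast region {region!r}")
        box = FieldBox(z_lo=tuple(rec["box"]["z_lo"]),
                       z_hi=tuple(rec["box"]["z_hi"]),
                       width_fraction=rec["box"]["width_fraction"])
        fields.append(ImagingField(
            field_id=rec["id"], projection=rec["projection"],
            fluoro_seconds=rec["fluoro_seconds"],
            spot_film=rec["spot_film"], box=box, contrast=contrast))
    protocol = ExaminationProtocol(age_class=payload["age_class"],
                                   diagnosis=payload["diagnosis"],
                                   fields=tuple(fields),
                                   pulse_rate_hz=payload["pulse_rate_hz"])
    violations = validate_protocol(protocol)
    if violations:
        raise ValueError(f"{name}: invalid protocol: {violations}")
    return protocol


def validate_protocol(p: ExaminationProtocol) -> list[str]:
    """Empty list iff all protocol invariants hold."""
    out = []
    ids = [f.field_id for f in p.fields]
    if len(set(ids)) != len(ids):
        out.append("duplicate field ids")
    expected_total = TOTAL_FLUORO_SECONDS.get((p.age_class, p.diagnosis))
    if expected_total is not None and \
            abs(p.total_fluoro_seconds - expected_total) > 1e-9:
        out.append(f"total fluoroscopy time {p.total_fluoro_seconds} s != "
                   f"{expected_total} s")
    if p.n_spot_films != SPOT_FILMS_PER_EXAM:
        out.append(f"N spot films = {p.n_spot_films}, expected "
                   f"{SPOT_FILMS_PER_EXAM}")
    for f in p.fields:
        if f.fluoro_seconds not in ALLOWED_FLUORO_SECONDS:
            out.append(f"field {f.field_id}: fluoro seconds "
                       f"{f.fluoro_seconds} not in {ALLOWED_FLUORO_SECONDS}")
        if f.projection not in PROJECTION_ANGLES:
            out.append(f"field {f.field_id}: unknown projection "
                       f"{f.projection}")
    if p.diagnosis == "normal":
        expect_films = {"4N", "5N", "6N", "7N", "8N", "9N"}
    else:
        expect_films = {"1A", "3A", "4A", "5A", "6A", "7A"}
    films = {f.field_id for f in p.fields if f.spot_film}
    if films != expect_films:
        out.append(f"spot films on {sorted(films)}, expected "
                   f"{sorted(expect_films)}")
    return out
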