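"""Synthetic voxel phantoms emulating the reference newborn and 1-year-old
female anatomy (arms removed), and per-field contrast-media application.

The anatomy is built deterministically from scaled geometric primitives
(ellipsoids, cylinders, boxes) positioned to plausible infant anatomy and
sized to reference-style organ masses.  It reproduces the *structure* the
dosimetry pipeline needs -- labelled rigid organs with wall/contents pairs
for stomach and small intestine, a homogenised skeleton, reference
morphometry (height, body mass) -- not the licensed reference phantom
voxel data.

Frame convention: x = patient left, y = patient anterior, z = patient
superior; 0-based voxel indices; the voxel grid origin (corner of voxel
[0,0,0]) is stored in cm in the same frame, with z = 0 at the soles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .materials import (ElementalComposition, MixtureSpec, REFERENCE_MATERIALS,
                        mix_by_volume)

# Reference morphometry: age class -> (height cm, body mass kg)
REFERENCE_MORPHOMETRY = {"newborn": (51.0, 3.5), "one_year": (76.0, 10.0)}

# Regions that contrast media may replace or mix into.
CONTRAST_REGIONS = ("tongue", "oesophagus", "stomach_contents", "si_contents")

#: region name -> reference material id
REGION_MATERIALS = {
    "air": "air",
    "residual": "soft_tissue",
    "skin": "skin",
    "skeleton": "skeleton",
    "brain": "brain",
    "lungs": "lung",
    "heart_wall": "muscle",
    "thymus": "soft_tissue",
    "thyroid": "soft_tissue",
    "oesophagus": "soft_tissue",
    "tongue": "tongue",
    "stomach_wall": "soft_tissue",
    "stomach_contents": "gi_contents",
    "si_wall": "soft_tissue",
    "si_contents": "gi_contents",
    "colon": "soft_tissue",
    "liver": "soft_tissue",
    "spleen": "soft_tissue",
    "kidneys": "soft_tissue",
    "bladder": "soft_tissue",
    "ovaries": "soft_tissue",
    "breast": "adipose",
}
REGION_LABELS = {name: i for i, name in enumerate(REGION_MATERIALS)}


@dataclass
class VoxelPhantom:
    """Labelled rigid voxel anatomy plus region -> material assignment."""

    labels: np.ndarray                  # uint16, shape (nx, ny, nz)
    voxel_cm: tuple[float, float, float]
    origin_cm: tuple[float, float, float]
    regions: dict[int, tuple[str, str]]  # label -> (region name, material id)
    materials: dict[str, ElementalComposition]
    age_class: str
    height_cm: float

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.voxel_cm
        return dx * dy * dz

    def label_of(self, region: str) -> int:
        for lab, (name, _) in self.regions.items():
            if name == region:
                return lab
        raise KeyError(f"unknown region {region!r}")

    def material_of_region(self, region: str) -> ElementalComposition:
        return self.materials[self.regions[self.label_of(region)][1]]

    def region_masses(self) -> dict[str, float]:
        """Region masses in grams (voxel count x volume x density)."""
        counts = np.bincount(self.labels.ravel(),
                             minlength=max(self.regions) + 1)
        out = {}
        for lab, (name, mat_id) in self.regions.items():
            out[name] = counts[lab] * self.voxel_volume_cm3 \
                * self.materials[mat_id].density
        return out

    def body_mass_kg(self) -> float:
        masses = self.region_masses()
        return sum(m for name, m in masses.items() if name != "air") / 1e3

    def region_centroid_cm(self, region: str) -> np.ndarray:
        idx = np.argwhere(self.labels == self.label_of(region))
        if idx.size == 0:
            raise ValueError(f"region {region!r} is empty")
        c = (idx.mean(axis=0) + 0.5) * np.asarray(self.voxel_cm)
        return c + np.asarray(self.origin_cm)

    def region_bbox_cm(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.argwhere(self.labels == self.label_of(region))
        if idx.size == 0:
            raise ValueError(f"region {region!r} is empty")
        v = np.asarray(self.voxel_cm)
        o = np.asarray(self.origin_cm)
        return idx.min(axis=0) * v + o, (idx.max(axis=0) + 1) * v + o

    # -- persistence --------------------------------------------------------

    def save(self, stem: str | Path) -> None:
        """Write `<stem>.raw` (little-endian uint16) + `<stem>.json` sidecar."""
        stem = Path(stem)
        self.labels.astype("<u2").tofile(stem.with_suffix(".raw"))
        sidecar = {
            "frame": "x=patient-left, y=patient-anterior, z=patient-superior",
            "shape": list(self.labels.shape),
            "voxel_cm": list(self.voxel_cm),
            "origin_cm": list(self.origin_cm),
            "age_class": self.age_class,
            "height_cm": self.height_cm,
            "regions": {str(k): list(v) for k, v in self.regions.items()},
            "materials": {
                mid: {"density": m.density, "fractions": m.fractions}
                for mid, m in self.materials.items()},
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(stem: str | Path) -> "VoxelPhantom":
        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        labels = np.fromfile(stem.with_suffix(".raw"), dtype="<u2").reshape(
            sidecar["shape"]).astype(np.uint16)
        materials = {
            mid: ElementalComposition.normalized(mid, rec["density"],
                                                 dict(rec["fractions"]))
            for mid, rec in sidecar["materials"].items()}
        return VoxelPhantom(
            labels=labels,
            voxel_cm=tuple(sidecar["voxel_cm"]),
            origin_cm=tuple(sidecar["origin_cm"]),
            regions={int(k): tuple(v) for k, v in sidecar["regions"].items()},
            materials=materials,
            age_class=sidecar["age_class"],
            height_cm=sidecar["height_cm"],
        )


# --------------------------------------------------------------------------
# Anatomy construction
# --------------------------------------------------------------------------

class _Painter:
    def __init__(self, shape, voxel_cm, origin_cm):
        self.labels = np.zeros(shape, dtype=np.uint16)
        v = np.asarray(voxel_cm)
        o = np.asarray(origin_cm)
        self.x = o[0] + (np.arange(shape[0]) + 0.5) * v[0]
        self.y = o[1] + (np.arange(shape[1]) + 0.5) * v[1]
        self.z = o[2] + (np.arange(shape[2]) + 0.5) * v[2]
        self.X = self.x[:, None, None]
        self.Y = self.y[None, :, None]
        self.Z = self.z[None, None, :]
        self.body = np.zeros(shape, dtype=bool)

    def ellipsoid(self, c, s):
        return (((self.X - c[0]) / s[0]) ** 2 + ((self.Y - c[1]) / s[1]) ** 2
                + ((self.Z - c[2]) / s[2]) ** 2) <= 1.0

    def cylinder_z(self, cx, cy, rx, ry, z0, z1):
        return ((((self.X - cx) / rx) ** 2 + ((self.Y - cy) / ry) ** 2) <= 1.0) \
            & (self.Z >= z0) & (self.Z <= z1)

    def paint(self, mask, region, clip_to_body=True):
        if clip_to_body:
            mask = mask & self.body
        self.labels[mask] = REGION_LABELS[region]
        return mask


def _newborn_params() -> dict:
    """Canonical newborn primitive parameters (cm, z measured from soles)."""
    return {
        "trunk": dict(cx=0.0, cy=0.0, rx=6.1, ry=5.1, z0=17.0, z1=38.0),
        "neck": dict(cx=0.0, cy=0.0, rx=2.1, ry=2.1, z0=38.0, z1=40.4),
        "head": dict(c=(0.0, 0.0, 45.6), s=(4.6, 5.4, 5.4)),
        "legs_x": 2.7, "legs_r": 2.3, "legs_z1": 17.0,
        "skull_outer": (4.25, 5.05, 5.15), "skull_c": (0.0, 0.0, 45.6),
        "brain": (3.8, 4.6, 4.7),
        "tongue": dict(c=(0.0, 2.6, 41.4), s=(1.2, 1.1, 0.7)),
        "thyroid": dict(c=(0.0, 1.2, 38.9), s=(0.85, 0.55, 0.7)),
        "oesophagus": dict(cx=0.0, cy=-1.4, r=0.3, z0=27.8, z1=39.2),
        "ribs": dict(outer=(5.3, 4.3), inner=(4.95, 3.95), z0=29.5, z1=37.4),
        "lungs": dict(xoff=2.75, c=(-0.3, 33.4), s=(2.05, 3.1, 4.2)),
        "heart": dict(c=(0.7, 1.0, 31.8), s=(1.8, 1.6, 1.7)),
        "thymus": dict(c=(0.0, 2.7, 35.6), s=(1.6, 1.0, 1.9)),
        "liver": dict(c=(-2.0, 0.3, 26.5), s=(3.3, 3.5, 2.7)),
        "stomach": dict(c=(2.7, 0.9, 27.5), s=(2.2, 1.9, 2.6)),
        "spleen": dict(c=(3.7, -2.0, 26.2), s=(1.0, 1.2, 1.6)),
        "kidneys": dict(xoff=2.3, c=(-2.4, 23.5), s=(1.2, 1.1, 2.1)),
        "si": dict(c=(0.0, 1.2, 21.0), s=(3.2, 2.4, 2.6)),
        "colon": dict(x=3.6, y=0.4, r=0.62, z0=18.0, z1=24.6,
                      ty=1.9, tz=24.3),
        "bladder": dict(c=(0.0, 1.6, 18.3), s=(1.0, 0.9, 0.8)),
        "ovaries": dict(xoff=1.6, c=(0.2, 19.6), r=0.42),
        "breast": dict(xoff=1.8, c=(4.45, 33.0), s=(0.75, 0.5, 0.75)),
        "spine": dict(cx=0.0, cy=-3.1, r=0.9, z0=17.0, z1=38.6),
        "pelvis": dict(outer=(5.0, 3.9), inner=(4.3, 3.2), z0=17.0, z1=19.6),
        "femur_x": 2.7, "femur_r": 0.7, "femur_z": (2.0, 17.0),
        "height": 51.0,
    }


def _scaled_params(age: str) -> dict:
    p = _newborn_params()
    if age == "newborn":
        return p
    if age != "one_year":
        raise ValueError(f"unknown age class {age!r}")
    h0, m0 = REFERENCE_MORPHOMETRY["newborn"]
    h1, m1 = REFERENCE_MORPHOMETRY["one_year"]
    sz = h1 / h0
    sxy = float(np.sqrt((m1 / m0) / sz))

    def sc(obj, kind):
        if kind == "xy":
            return obj * sxy
        if kind == "z":
            return obj * sz
        raise ValueError(kind)

    q = {}
    for key, val in p.items():
        if key == "height":
            q[key] = val * sz
        elif key in ("trunk", "neck"):
            q[key] = dict(cx=sc(val["cx"], "xy"), cy=sc(val["cy"], "xy"),
                          rx=sc(val["rx"], "xy"), ry=sc(val["ry"], "xy"),
                          z0=sc(val["z0"], "z"), z1=sc(val["z1"], "z"))
        elif key in ("head",):
            c, s = val["c"], val["s"]
            q[key] = dict(c=(sc(c[0], "xy"), sc(c[1], "xy"), sc(c[2], "z")),
                          s=(sc(s[0], "xy"), sc(s[1], "xy"), sc(s[2], "z")))
        elif key in ("skull_outer", "brain"):
            q[key] = (sc(val[0], "xy"), sc(val[1], "xy"), sc(val[2], "z"))
        elif key == "skull_c":
            q[key] = (sc(val[0], "xy"), sc(val[1], "xy"), sc(val[2], "z"))
        elif key in ("tongue", "thyroid", "heart", "thymus", "liver",
                     "stomach", "spleen", "si", "bladder"):
            c, s = val["c"], val["s"]
            q[key] = dict(c=(sc(c[0], "xy"), sc(c[1], "xy"), sc(c[2], "z")),
                          s=(sc(s[0], "xy"), sc(s[1], "xy"), sc(s[2], "z")))
        elif key == "oesophagus":
            q[key] = dict(cx=sc(val["cx"], "xy"), cy=sc(val["cy"], "xy"),
                          r=sc(val["r"], "xy"), z0=sc(val["z0"], "z"),
                          z1=sc(val["z1"], "z"))
        elif key == "ribs":
            q[key] = dict(outer=tuple(sc(v, "xy") for v in val["outer"]),
                          inner=tuple(sc(v, "xy") for v in val["inner"]),
                          z0=sc(val["z0"], "z"), z1=sc(val["z1"], "z"))
        elif key == "lungs":
            q[key] = dict(xoff=sc(val["xoff"], "xy"),
                          c=(sc(val["c"][0], "xy"), sc(val["c"][1], "z")),
                          s=(sc(val["s"][0], "xy"), sc(val["s"][1], "xy"),
                             sc(val["s"][2], "z")))
        elif key == "kidneys":
            q[key] = dict(xoff=sc(val["xoff"], "xy"),
                          c=(sc(val["c"][0], "xy"), sc(val["c"][1], "z")),
                          s=(sc(val["s"][0], "xy"), sc(val["s"][1], "xy"),
                             sc(val["s"][2], "z")))
        elif key == "colon":
            q[key] = dict(x=sc(val["x"], "xy"), y=sc(val["y"], "xy"),
                          r=sc(val["r"], "xy"), z0=sc(val["z0"], "z"),
                          z1=sc(val["z1"], "z"), ty=sc(val["ty"], "xy"),
                          tz=sc(val["tz"], "z"))
        elif key == "ovaries":
            q[key] = dict(xoff=sc(val["xoff"], "xy"),
                          c=(sc(val["c"][0], "xy"), sc(val["c"][1], "z")),
                          r=sc(val["r"], "xy"))
        elif key == "breast":
            q[key] = dict(xoff=sc(val["xoff"], "xy"),
                          c=(sc(val["c"][0], "xy"), sc(val["c"][1], "z")),
                          s=(sc(val["s"][0], "xy"), sc(val["s"][1], "xy"),
                             sc(val["s"][2], "z")))
        elif key == "spine":
            q[key] = dict(cx=sc(val["cx"], "xy"), cy=sc(val["cy"], "xy"),
                          r=sc(val["r"], "xy"), z0=sc(val["z0"], "z"),
                          z1=sc(val["z1"], "z"))
        elif key == "pelvis":
            q[key] = dict(outer=tuple(sc(v, "xy") for v in val["outer"]),
                          inner=tuple(sc(v, "xy") for v in val["inner"]),
                          z0=sc(val["z0"], "z"), z1=sc(val["z1"], "z"))
        elif key in ("legs_x", "legs_r", "femur_x", "femur_r"):
            q[key] = sc(val, "xy")
        elif key == "legs_z1":
            q[key] = sc(val, "z")
        elif key == "femur_z":
            q[key] = tuple(sc(v, "z") for v in val)
        else:
            q[key] = val
    return q


def build_phantom(age: str, voxel_mm: float = 2.0) -> VoxelPhantom:
    """Deterministically voxelise the synthetic anatomy for an age class."""
    if not 1.0 <= voxel_mm <= 5.0:
        raise ValueError(f"voxel size {voxel_mm} mm outside the 1-5 mm range")
    p = _scaled_params(age)
    v = voxel_mm / 10.0
    height = p["height"]
    half_x = p["trunk"]["rx"] + 1.2
    half_y = p["trunk"]["ry"] + 1.2
    nx = int(np.ceil(2 * half_x / v)) + 2
    ny = int(np.ceil(2 * half_y / v)) + 2
    nz = int(np.ceil(height / v)) + 2
    origin = (-nx * v / 2.0, -ny * v / 2.0, -v)
    pt = _Painter((nx, ny, nz), (v, v, v), origin)

    # body envelope
    trunk = pt.cylinder_z(p["trunk"]["cx"], p["trunk"]["cy"], p["trunk"]["rx"],
                          p["trunk"]["ry"], p["trunk"]["z0"], p["trunk"]["z1"])
    neck = pt.cylinder_z(p["neck"]["cx"], p["neck"]["cy"], p["neck"]["rx"],
                         p["neck"]["ry"], p["neck"]["z0"], p["neck"]["z1"])
    head = pt.ellipsoid(p["head"]["c"], p["head"]["s"]) & (pt.Z <= height)
    legs = (pt.cylinder_z(-p["legs_x"], 0.0, p["legs_r"], p["legs_r"], 0.0,
                          p["legs_z1"])
            | pt.cylinder_z(p["legs_x"], 0.0, p["legs_r"], p["legs_r"], 0.0,
                            p["legs_z1"]))
    pt.body = trunk | neck | head | legs
    pt.labels[pt.body] = REGION_LABELS["residual"]

    # skeleton
    skull = pt.ellipsoid(p["skull_c"], p["skull_outer"]) \
        & ~pt.ellipsoid(p["skull_c"], p["brain"])
    ribs = (pt.cylinder_z(0.0, -0.1, *p["ribs"]["outer"], p["ribs"]["z0"],
                          p["ribs"]["z1"])
            & ~pt.cylinder_z(0.0, -0.1, *p["ribs"]["inner"], p["ribs"]["z0"],
                             p["ribs"]["z1"]))
    pelvis = (pt.cylinder_z(0.0, -0.4, *p["pelvis"]["outer"], p["pelvis"]["z0"],
                            p["pelvis"]["z1"])
              & ~pt.cylinder_z(0.0, -0.4, *p["pelvis"]["inner"],
                               p["pelvis"]["z0"], p["pelvis"]["z1"])
              & (pt.Y < 1.0))
    spine = pt.cylinder_z(p["spine"]["cx"], p["spine"]["cy"], p["spine"]["r"],
                          p["spine"]["r"], p["spine"]["z0"], p["spine"]["z1"])
    femurs = (pt.cylinder_z(-p["femur_x"], 0.0, p["femur_r"], p["femur_r"],
                            *p["femur_z"])
              | pt.cylinder_z(p["femur_x"], 0.0, p["femur_r"], p["femur_r"],
                              *p["femur_z"]))
    pt.paint(skull | ribs | pelvis | spine | femurs, "skeleton")

    # organs (paint order resolves small deliberate overlaps)
    pt.paint(pt.ellipsoid(p["skull_c"], p["brain"]), "brain")
    pt.paint(pt.ellipsoid(p["tongue"]["c"], p["tongue"]["s"]), "tongue")
    pt.paint(pt.ellipsoid(p["thyroid"]["c"], p["thyroid"]["s"]), "thyroid")
    lx, (lcy, lcz), ls = p["lungs"]["xoff"], p["lungs"]["c"], p["lungs"]["s"]
    pt.paint(pt.ellipsoid((-lx, lcy, lcz), ls)
             | pt.ellipsoid((lx, lcy, lcz), ls), "lungs")
    pt.paint(pt.ellipsoid(p["heart"]["c"], p["heart"]["s"]), "heart_wall")
    pt.paint(pt.ellipsoid(p["thymus"]["c"], p["thymus"]["s"]), "thymus")
    o = p["oesophagus"]
    pt.paint(pt.cylinder_z(o["cx"], o["cy"], o["r"], o["r"], o["z0"], o["z1"]),
             "oesophagus")
    pt.paint(pt.ellipsoid(p["liver"]["c"], p["liver"]["s"]), "liver")
    c = p["colon"]
    colon = (pt.cylinder_z(-c["x"], c["y"], c["r"], c["r"], c["z0"], c["z1"])
             | pt.cylinder_z(c["x"], c["y"], c["r"], c["r"], c["z0"], c["z1"])
             | ((np.abs(pt.X) <= c["x"]) & (np.abs(pt.Y - c["ty"]) <= c["r"])
                & (np.abs(pt.Z - c["tz"]) <= c["r"])))
    pt.paint(colon, "colon")

    wall_t = max(0.45, 1.6 * v)
    si_outer = np.asarray(p["si"]["s"])
    si_inner = np.maximum(si_outer - wall_t, 0.3)
    pt.paint(pt.ellipsoid(p["si"]["c"], si_outer), "si_wall")
    pt.paint(pt.ellipsoid(p["si"]["c"], si_inner), "si_contents")
    st_outer = np.asarray(p["stomach"]["s"])
    st_inner = np.maximum(st_outer - wall_t, 0.3)
    pt.paint(pt.ellipsoid(p["stomach"]["c"], st_outer), "stomach_wall")
    pt.paint(pt.ellipsoid(p["stomach"]["c"], st_inner), "stomach_contents")

    pt.paint(pt.ellipsoid(p["spleen"]["c"], p["spleen"]["s"]), "spleen")
    kx, (kcy, kcz), ks = p["kidneys"]["xoff"], p["kidneys"]["c"], p["kidneys"]["s"]
    pt.paint(pt.ellipsoid((-kx, kcy, kcz), ks)
             | pt.ellipsoid((kx, kcy, kcz), ks), "kidneys")
    pt.paint(pt.ellipsoid(p["bladder"]["c"], p["bladder"]["s"]), "bladder")
    ox, (ocy, ocz), orr = p["ovaries"]["xoff"], p["ovaries"]["c"], p["ovaries"]["r"]
    pt.paint(pt.ellipsoid((-ox, ocy, ocz), (orr, orr, orr))
             | pt.ellipsoid((ox, ocy, ocz), (orr, orr, orr)), "ovaries")
    bx, (bcy, bcz), bs = p["breast"]["xoff"], p["breast"]["c"], p["breast"]["s"]
    pt.paint(pt.ellipsoid((-bx, bcy, bcz), bs)
             | pt.ellipsoid((bx, bcy, bcz), bs), "breast")

    # skin: body voxels with an air face-neighbour
    body = pt.labels != REGION_LABELS["air"]
    interior = np.ones_like(body)
    interior[1:, :, :] &= body[:-1, :, :]
    interior[:-1, :, :] &= body[1:, :, :]
    interior[:, 1:, :] &= body[:, :-1, :]
    interior[:, :-1, :] &= body[:, 1:, :]
    interior[:, :, 1:] &= body[:, :, :-1]
    interior[:, :, :-1] &= body[:, :, 1:]
    pt.labels[body & ~interior] = REGION_LABELS["skin"]

    regions = {lab: (name, REGION_MATERIALS[name])
               for name, lab in REGION_LABELS.items()}
    materials = {mid: REFERENCE_MATERIALS[mid]
                 for mid in set(REGION_MATERIALS.values())}
    return VoxelPhantom(labels=pt.labels, voxel_cm=(v, v, v),
                        origin_cm=origin, regions=regions,
                        materials=materials, age_class=age, height_cm=height)


# --------------------------------------------------------------------------
# Contrast application
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastDistribution:
    """Per-field contrast recipes: field id -> region -> volume mixture.

    Mixture part ids refer to the phantom material library plus the agent
    ids ``ez_paque`` / ``omnipaque_140``.
    """

    per_field: dict[str, dict[str, MixtureSpec]]

    def __post_init__(self):
        for fid, recipes in self.per_field.items():
            for region in recipes:
                if region not in CONTRAST_REGIONS:
                    raise ValueError(
                        f"field {fid!r}: region {region!r} may not receive "
                        f"contrast (allowed: {CONTRAST_REGIONS})")


def apply_contrast(phantom: VoxelPhantom, dist: ContrastDistribution,
                   field_id: str) -> VoxelPhantom:
    """Return a phantom with contrast-bearing materials for one field.

    Voxel labels are untouched (rigid organs); only the material
    assignments of the listed regions change.
    """
    if field_id not in dist.per_field:
        raise KeyError(f"field {field_id!r} not in contrast distribution")
    recipes = dist.per_field[field_id]
    if not recipes:
        return phantom
    library = dict(phantom.materials)
    library.setdefault("ez_paque", REFERENCE_MATERIALS["ez_paque"])
    library.setdefault("omnipaque_140", REFERENCE_MATERIALS["omnipaque_140"])
    regions = dict(phantom.regions)
    materials = dict(phantom.materials)
    for region, spec in recipes.items():
        lab = phantom.label_of(region)
        base_mat = phantom.regions[lab][1]
        parts = tuple((mid if mid != "__base__" else base_mat, vf)
                      for mid, vf in spec.parts)
        mixed = mix_by_volume(MixtureSpec(parts), library,
                              name=f"{region}[{field_id}]")
        mat_id = f"{region}_{field_id}"
        materials[mat_id] = mixed
        regions[lab] = (region, mat_id)
    return replace(phantom, regions=regions, materials=materials)
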