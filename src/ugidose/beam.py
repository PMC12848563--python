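"""Beam geometry: point source, rectangular collimated diverging field,
projections, and the field area at the reference plane.

Phantom frame convention (documented in the phantom header): x = patient
left, y = patient anterior, z = patient superior.  The collimator window
is defined 10 cm from the source; field area scales with the square of the
distance (similar triangles).  The source sits on the beam axis at
``source_distance_cm`` from the phantom midline (under-table geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COLLIMATOR_DISTANCE_CM = 10.0
REFERENCE_DISTANCE_CM = 20.0
# Source to phantom-midline distance (typical under-table geometry).
SOURCE_TO_MIDLINE_CM = 60.0

#: projection name -> rotation angle (degrees) about the longitudinal axis.
#: PA: source posterior, beam travelling +y (posterior -> anterior).
PROJECTION_ANGLES = {
    "PA": 0.0,
    "left-lateral": -90.0,   # source at patient right, beam toward patient left
    "right-lateral": 90.0,
    "LPO15": 15.0,
    "RPO15": -15.0,
}


def orient(projection: str) -> np.ndarray:
    """Rotation matrix (phantom frame) for a named projection.

    Rotates the PA beam frame about the phantom's longitudinal (z) axis.
    """
    try:
        angle = np.deg2rad(PROJECTION_ANGLES[projection])
    except KeyError:
        raise ValueError(
            f"unknown projection {projection!r}; expected one of "
            f"{sorted(PROJECTION_ANGLES)}") from None
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class BeamField:
    """A rectangular diverging beam aimed at a point in the phantom frame."""

    projection: str
    window_cm: tuple[float, float]   # (transverse, longitudinal) at 10 cm
    target_cm: np.ndarray            # aim point on the midline, phantom frame
    source_distance_cm: float = SOURCE_TO_MIDLINE_CM

    def __post_init__(self):
        w, h = self.window_cm
        if w <= 0 or h <= 0:
            raise ValueError("collimator window dimensions must be positive")
        object.__setattr__(self, "target_cm",
                           np.asarray(self.target_cm, dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        return orient(self.projection)

    @property
    def axis(self) -> np.ndarray:
        """Unit beam axis in the phantom frame."""
        return self.rotation @ np.array([0.0, 1.0, 0.0])

    @property
    def source_position(self) -> np.ndarray:
        return self.target_cm - self.axis * self.source_distance_cm

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors spanning the collimator window (transverse, axial)."""
        e_t = self.rotation @ np.array([1.0, 0.0, 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        return e_t, e_z

    def field_area_at(self, distance_cm: float) -> float:
        """Field area (cm^2) at `distance_cm` from the source."""
        if distance_cm <= 0:
            raise ValueError("distance must be positive")
        w, h = self.window_cm
        return w * h * (distance_cm / COLLIMATOR_DISTANCE_CM) ** 2

    def sample_directions(self, rng: np.random.Generator,
                          n: int) -> np.ndarray:
        """Unit directions uniform over the collimator window, shape (n, 3)."""
        w, h = self.window_cm
        u = rng.uniform(-w / 2.0, w / 2.0, size=n)
        v = rng.uniform(-h / 2.0, h / 2.0, size=n)
        e_t, e_z = self.basis
        d = (self.axis[None, :] * COLLIMATOR_DISTANCE_CM
             + e_t[None, :] * u[:, None] + e_z[None, :] * v[:, None])
        return d / np.linalg.norm(d, axis=1, keepdims=True)


def field_area_at(beam: BeamField, distance_cm: float) -> float:
    return beam.field_area_at(distance_cm)


def window_for_box(box_width_cm: float, box_height_cm: float,
                   source_distance_cm: float = SOURCE_TO_MIDLINE_CM
                   ) -> tuple[float, float]:
    """Collimator window (at 10 cm) whose field covers a box at the midline."""
    scale = COLLIMATOR_DISTANCE_CM / source_distance_cm
    return (box_width_cm * scale, box_height_cm * scale)
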