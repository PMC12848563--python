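"""Voxel Monte Carlo photon transport with per-region energy-deposition
tallies, batch statistics, and air-kerma / kerma-area-product estimators.

Physics model (kerma approximation):

* free paths by Woodcock (delta) tracking against a per-energy majorant;
* photoelectric absorption deposits the full photon energy locally;
* incoherent scattering samples the free-electron Klein-Nishina
  distribution (Kahn's method); the energy transferred to the electron is
  deposited at the interaction site (no electron transport -- secondary
  electron ranges are sub-voxel below 110 kVp);
* coherent scattering (optional, off by default) deflects with a Thomson
  angular shape and deposits nothing;
* photons falling below the cutoff (default 2 keV) deposit locally.

A second, independent ray-marching kernel (DDA integration of optical
depth) implements the same physics for cross-validation of the tracking
scheme.  Batch b of a run uses seed ``base_seed + b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import xsdata
from .beam import BeamField, REFERENCE_DISTANCE_CM
from .materials import ElementalComposition
from .phantom import VoxelPhantom
from .spectra import Spectrum

KEV_TO_J = 1.602176634e-16
_EGRID_MIN = 1.0
_EGRID_MAX = 150.0
_EGRID_STEP = 0.25


@dataclass(frozen=True)
class TransportConfig:
    histories: int = 100_000
    batches: int = 20
    seed: int = 1
    cutoff_kev: float = 2.0
    coherent: bool = False

    def __post_init__(self):
        if self.batches < 2 or self.histories < self.batches:
            raise ValueError("need histories >= batches >= 2")
        if self.cutoff_kev < 1.0:
            raise ValueError("photon cutoff must be >= 1 keV")


@dataclass
class TallyResult:
    """Per-region absorbed dose per history with batch statistics."""

    regions: tuple[str, ...]
    batch_doses: np.ndarray      # (batches, nregions), Gy per history
    histories: int

    @property
    def dose(self) -> dict[str, float]:
        means = self.batch_doses.mean(axis=0)
        return dict(zip(self.regions, means))

    @property
    def relative_error(self) -> dict[str, float]:
        b = self.batch_doses.shape[0]
        means = self.batch_doses.mean(axis=0)
        sem = self.batch_doses.std(axis=0, ddof=1) / np.sqrt(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            re = np.where(means > 0, sem / np.maximum(means, 1e-300), 0.0)
        return dict(zip(self.regions, re))


def _energy_grid() -> np.ndarray:
    return np.arange(_EGRID_MIN, _EGRID_MAX + _EGRID_STEP / 2, _EGRID_STEP)


def material_mu_arrays(materials: list[ElementalComposition]):
    """Per-material linear coefficients (1/cm) on the transport grid."""
    e = _energy_grid()
    n_m, n_e = len(materials), e.size
    mu_pe = np.zeros((n_m, n_e))
    mu_in = np.zeros((n_m, n_e))
    mu_coh = np.zeros((n_m, n_e))
    for i, m in enumerate(materials):
        for sym, w in m.fractions.items():
            mu_pe[i] += w * xsdata.mu_rho_element(sym, e, "photoelectric")
            mu_in[i] += w * xsdata.mu_rho_element(sym, e, "incoherent")
            mu_coh[i] += w * xsdata.mu_rho_element(sym, e, "coherent")
        mu_pe[i] *= m.density
        mu_in[i] *= m.density
        mu_coh[i] *= m.density
    return e, mu_pe, mu_in, mu_coh


def _air_mu_en(e_kev: np.ndarray) -> np.ndarray:
    return sum(w * xsdata.mu_rho_element(sym, e_kev, "mu_en")
               for sym, w in xsdata.AIR_COMPOSITION.items())


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _kahn_compton(e_kev):
    """Sample Klein-Nishina scatter: returns (scattered energy, cos theta)."""
    a = e_kev / 510.99895
    x = 1.0
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            mu = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (mu * mu + 1.0 / x):
                break
    mu = 1.0 - (x - 1.0) / a
    return e_kev / x, mu


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, mu):
    """Rotate a unit vector by polar angle acos(mu), uniform azimuth."""
    phi = 2.0 * np.pi * np.random.random()
    sin_t = np.sqrt(max(0.0, 1.0 - mu * mu))
    cp, sp = np.cos(phi), np.sin(phi)
    if abs(uz) < 0.999999:
        den = np.sqrt(1.0 - uz * uz)
        vx = ux * mu + sin_t * (ux * uz * cp - uy * sp) / den
        vy = uy * mu + sin_t * (uy * uz * cp + ux * sp) / den
        vz = uz * mu - den * sin_t * cp
    else:
        vx = sin_t * cp
        vy = sin_t * sp
        vz = mu if uz > 0 else -mu
    n = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / n, vy / n, vz / n


@njit(cache=True, inline="always")
def _thomson_mu():
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=True, inline="always")
def _sample_source(cdf, energies, sx, sy, sz, ax, ay, az,
                   tx, ty, tz, ezx, ezy, ezz, whalf, hhalf, coll_dist):
    u = np.random.random()
    lo, hi = 0, cdf.size - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    e = energies[lo] + (np.random.random() - 0.5)
    if e < 1.0:
        e = 1.0
    uu = (2.0 * np.random.random() - 1.0) * whalf
    vv = (2.0 * np.random.random() - 1.0) * hhalf
    dx = ax * coll_dist + tx * uu + ezx * vv
    dy = ay * coll_dist + ty * uu + ezy * vv
    dz = az * coll_dist + tz * uu + ezz * vv
    n = np.sqrt(dx * dx + dy * dy + dz * dz)
    return e, dx / n, dy / n, dz / n


@njit(cache=True, inline="always")
def _box_entry(px, py, pz, dx, dy, dz, x0, y0, z0, x1, y1, z1):
    """Slab-method ray/box intersection; returns (hit, t_entry, t_exit)."""
    tmin, tmax = -1.0e30, 1.0e30
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = px, dx, x0, x1
        elif axis == 1:
            p, d, lo, hi = py, dy, y0, y1
        else:
            p, d, lo, hi = pz, dz, z0, z1
        if abs(d) < 1.0e-12:
            if p < lo or p > hi:
                return False, 0.0, 0.0
        else:
            t1 = (lo - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= max(tmin, 0.0):
        return False, 0.0, 0.0
    return True, max(tmin, 0.0), tmax


@njit(cache=True)
def _woodcock_batch(n_hist, seed, labels, mat_of_label,
                    mu_pe, mu_in, mu_coh, use_coherent, majorant,
                    ox, oy, oz, vx, vy, vz,
                    sx, sy, sz, ax, ay, az, tx, ty, tz,
                    ezx, ezy, ezz, whalf, hhalf, coll_dist,
                    cdf, energies, cutoff, edep):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    x1 = ox + nx * vx
    y1 = oy + ny * vy
    z1 = oz + nz * vz
    emitted = 0.0
    for _ in range(n_hist):
        e, dx, dy, dz = _sample_source(cdf, energies, sx, sy, sz,
                                       ax, ay, az, tx, ty, tz,
                                       ezx, ezy, ezz, whalf, hhalf, coll_dist)
        emitted += e
        hit, t_in, _ = _box_entry(sx, sy, sz, dx, dy, dz,
                                  ox, oy, oz, x1, y1, z1)
        if not hit:
            continue
        px = sx + dx * (t_in + 1.0e-9)
        py = sy + dy * (t_in + 1.0e-9)
        pz = sz + dz * (t_in + 1.0e-9)
        alive = True
        while alive:
            ie = int((e - _EGRID_MIN) / _EGRID_STEP)
            if ie < 0:
                ie = 0
            if ie >= majorant.size:
                ie = majorant.size - 1
            mu_maj = majorant[ie]
            step = -np.log(np.random.random()) / mu_maj
            px += dx * step
            py += dy * step
            pz += dz * step
            i = int(np.floor((px - ox) / vx))
            j = int(np.floor((py - oy) / vy))
            k = int(np.floor((pz - oz) / vz))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            lab = labels[i, j, k]
            m = mat_of_label[lab]
            mu_t = mu_pe[m, ie] + mu_in[m, ie]
            if use_coherent:
                mu_t += mu_coh[m, ie]
            if np.random.random() * mu_maj > mu_t:
                continue  # virtual collision
            xi = np.random.random() * mu_t
            if xi < mu_pe[m, ie]:
                edep[lab] += e
                alive = False
            elif xi < mu_pe[m, ie] + mu_in[m, ie]:
                e_new, mu_sc = _kahn_compton(e)
                edep[lab] += e - e_new
                e = e_new
                dx, dy, dz = _rotate(dx, dy, dz, mu_sc)
                if e < cutoff:
                    edep[lab] += e
                    alive = False
            else:
                dx, dy, dz = _rotate(dx, dy, dz, _thomson_mu())
    return emitted


@njit(cache=True)
def _raymarch_batch(n_hist, seed, labels, mat_of_label,
                    mu_pe, mu_in, mu_coh, use_coherent, majorant,
                    ox, oy, oz, vx, vy, vz,
                    sx, sy, sz, ax, ay, az, tx, ty, tz,
                    ezx, ezy, ezz, whalf, hhalf, coll_dist,
                    cdf, energies, cutoff, edep):
    """Independent oracle: optical-depth integration along voxel segments."""
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    x1 = ox + nx * vx
    y1 = oy + ny * vy
    z1 = oz + nz * vz
    emitted = 0.0
    for _ in range(n_hist):
        e, dx, dy, dz = _sample_source(cdf, energies, sx, sy, sz,
                                       ax, ay, az, tx, ty, tz,
                                       ezx, ezy, ezz, whalf, hhalf, coll_dist)
        emitted += e
        px, py, pz = sx, sy, sz
        alive = True
        while alive:
            hit, t_in, t_out = _box_entry(px, py, pz, dx, dy, dz,
                                          ox, oy, oz, x1, y1, z1)
            if not hit:
                break
            ie = int((e - _EGRID_MIN) / _EGRID_STEP)
            if ie < 0:
                ie = 0
            if ie >= mu_pe.shape[1]:
                ie = mu_pe.shape[1] - 1
            eta = -np.log(np.random.random())
            # Amanatides-Woo traversal from the box entry point
            t = t_in + 1.0e-9
            i = int(np.floor((px + dx * t - ox) / vx))
            j = int(np.floor((py + dy * t - oy) / vy))
            k = int(np.floor((pz + dz * t - oz) / vz))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            if dx > 0.0:
                step_i, t_dx = 1, vx / dx
                tmax_x = (ox + (i + 1) * vx - px) / dx
            elif dx < 0.0:
                step_i, t_dx = -1, -vx / dx
                tmax_x = (ox + i * vx - px) / dx
            else:
                step_i, t_dx, tmax_x = 0, 1.0e30, 1.0e30
            if dy > 0.0:
                step_j, t_dy = 1, vy / dy
                tmax_y = (oy + (j + 1) * vy - py) / dy
            elif dy < 0.0:
                step_j, t_dy = -1, -vy / dy
                tmax_y = (oy + j * vy - py) / dy
            else:
                step_j, t_dy, tmax_y = 0, 1.0e30, 1.0e30
            if dz > 0.0:
                step_k, t_dz = 1, vz / dz
                tmax_z = (oz + (k + 1) * vz - pz) / dz
            elif dz < 0.0:
                step_k, t_dz = -1, -vz / dz
                tmax_z = (oz + k * vz - pz) / dz
            else:
                step_k, t_dz, tmax_z = 0, 1.0e30, 1.0e30
            collided = False
            t_cur = t
            while True:
                t_next = tmax_x
                axis = 0
                if tmax_y < t_next:
                    t_next = tmax_y
                    axis = 1
                if tmax_z < t_next:
                    t_next = tmax_z
                    axis = 2
                stop = False
                if t_next > t_out:
                    t_next = t_out
                    stop = True
                seg = t_next - t_cur
                if seg < 0.0:
                    seg = 0.0
                lab = labels[i, j, k]
                m = mat_of_label[lab]
                mu_t = mu_pe[m, ie] + mu_in[m, ie]
                if use_coherent:
                    mu_t += mu_coh[m, ie]
                if mu_t * seg >= eta:
                    t_coll = t_cur + eta / max(mu_t, 1.0e-30)
                    px = px + dx * t_coll
                    py = py + dy * t_coll
                    pz = pz + dz * t_coll
                    xi = np.random.random() * mu_t
                    if xi < mu_pe[m, ie]:
                        edep[lab] += e
                        alive = False
                    elif xi < mu_pe[m, ie] + mu_in[m, ie]:
                        e_new, mu_sc = _kahn_compton(e)
                        edep[lab] += e - e_new
                        e = e_new
                        dx, dy, dz = _rotate(dx, dy, dz, mu_sc)
                        if e < cutoff:
                            edep[lab] += e
                            alive = False
                    else:
                        dx, dy, dz = _rotate(dx, dy, dz, _thomson_mu())
                    collided = True
                    break
                eta -= mu_t * seg
                t_cur = t_next
                if stop:
                    break
                if axis == 0:
                    i += step_i
                    tmax_x += t_dx
                    if i < 0 or i >= nx:
                        break
                elif axis == 1:
                    j += step_j
                    tmax_y += t_dy
                    if j < 0 or j >= ny:
                        break
                else:
                    k += step_k
                    tmax_z += t_dz
                    if k < 0 or k >= nz:
                        break
            if not collided:
                alive = False  # left the grid without interacting
    return emitted


@njit(cache=True)
def _primary_transmission_batch(n_hist, seed, labels, mat_of_label,
                                mu_pe, mu_in, mu_coh, use_coherent, majorant,
                                ox, oy, oz, vx, vy, vz,
                                sx, sy, sz, ax, ay, az, tx, ty, tz,
                                ezx, ezy, ezz, whalf, hhalf, coll_dist,
                                cdf, energies):
    """Count photons traversing the grid without any real collision."""
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    x1 = ox + nx * vx
    y1 = oy + ny * vy
    z1 = oz + nz * vz
    transmitted = 0
    for _ in range(n_hist):
        e, dx, dy, dz = _sample_source(cdf, energies, sx, sy, sz,
                                       ax, ay, az, tx, ty, tz,
                                       ezx, ezy, ezz, whalf, hhalf, coll_dist)
        hit, t_in, _ = _box_entry(sx, sy, sz, dx, dy, dz,
                                  ox, oy, oz, x1, y1, z1)
        if not hit:
            transmitted += 1
            continue
        px = sx + dx * (t_in + 1.0e-9)
        py = sy + dy * (t_in + 1.0e-9)
        pz = sz + dz * (t_in + 1.0e-9)
        ie = int((e - _EGRID_MIN) / _EGRID_STEP)
        if ie < 0:
            ie = 0
        if ie >= majorant.size:
            ie = majorant.size - 1
        mu_maj = majorant[ie]
        survived = True
        while True:
            step = -np.log(np.random.random()) / mu_maj
            px += dx * step
            py += dy * step
            pz += dz * step
            i = int(np.floor((px - ox) / vx))
            j = int(np.floor((py - oy) / vy))
            k = int(np.floor((pz - oz) / vz))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                break
            m = mat_of_label[labels[i, j, k]]
            mu_t = mu_pe[m, ie] + mu_in[m, ie]
            if use_coherent:
                mu_t += mu_coh[m, ie]
            if np.random.random() * mu_maj <= mu_t:
                survived = False
                break
        if survived:
            transmitted += 1
    return transmitted


def primary_transmission(phantom: VoxelPhantom, beam: BeamField,
                         spectrum: Spectrum, config: TransportConfig
                         ) -> tuple[float, float]:
    """Fraction of primaries crossing the phantom uncollided (mean, SE).

    Validates Woodcock free-path sampling against the closed form
    exp(-integral mu dl) for simple geometries.
    """
    mat_ids = sorted({mid for _, mid in phantom.regions.values()})
    mat_index = {mid: i for i, mid in enumerate(mat_ids)}
    mats = [phantom.materials[mid] for mid in mat_ids]
    _, mu_pe, mu_in, mu_coh = material_mu_arrays(mats)
    n_lab = max(phantom.regions) + 1
    mat_of_label = np.zeros(n_lab, dtype=np.int64)
    for lab, (_, mid) in phantom.regions.items():
        mat_of_label[lab] = mat_index[mid]
    mu_tot = mu_pe + mu_in + (mu_coh if config.coherent else 0.0)
    majorant = mu_tot.max(axis=0)
    cdf, energies = _spectrum_cdf(spectrum)
    beam_args = _beam_arrays(beam)
    ox, oy, oz = phantom.origin_cm
    vx, vy, vz = phantom.voxel_cm
    labels = np.ascontiguousarray(phantom.labels)
    per_batch = config.histories // config.batches
    fracs = np.empty(config.batches)
    for b in range(config.batches):
        n_t = _primary_transmission_batch(
            per_batch, config.seed + b, labels, mat_of_label,
            mu_pe, mu_in, mu_coh, config.coherent, majorant,
            ox, oy, oz, vx, vy, vz, *beam_args, cdf, energies)
        fracs[b] = n_t / per_batch
    return float(fracs.mean()), float(fracs.std(ddof=1) / np.sqrt(config.batches))


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------

def _beam_arrays(beam: BeamField):
    src = beam.source_position
    axis = beam.axis
    e_t, e_z = beam.basis
    w, h = beam.window_cm
    return (src[0], src[1], src[2], axis[0], axis[1], axis[2],
            e_t[0], e_t[1], e_t[2], e_z[0], e_z[1], e_z[2],
            w / 2.0, h / 2.0, 10.0)


def _spectrum_cdf(spectrum: Spectrum):
    cdf = np.cumsum(spectrum.weights)
    return cdf / cdf[-1], spectrum.energies.copy()


def run_transport(phantom: VoxelPhantom, beam: BeamField, spectrum: Spectrum,
                  config: TransportConfig, kernel: str = "woodcock"
                  ) -> TallyResult:
    """Transport `config.histories` photons and tally per-region doses.

    `kernel` selects the production Woodcock tracker or the ray-marching
    oracle ("raymarch").
    """
    mat_ids = sorted({mid for _, mid in phantom.regions.values()})
    mat_index = {mid: i for i, mid in enumerate(mat_ids)}
    mats = [phantom.materials[mid] for mid in mat_ids]
    _, mu_pe, mu_in, mu_coh = material_mu_arrays(mats)
    n_lab = max(phantom.regions) + 1
    mat_of_label = np.zeros(n_lab, dtype=np.int64)
    for lab, (_, mid) in phantom.regions.items():
        mat_of_label[lab] = mat_index[mid]
    mu_tot = mu_pe + mu_in + (mu_coh if config.coherent else 0.0)
    majorant = mu_tot.max(axis=0)
    cdf, energies = _spectrum_cdf(spectrum)
    beam_args = _beam_arrays(beam)
    ox, oy, oz = phantom.origin_cm
    vx, vy, vz = phantom.voxel_cm
    labels = np.ascontiguousarray(phantom.labels)
    fn = _woodcock_batch if kernel == "woodcock" else _raymarch_batch
    if kernel not in ("woodcock", "raymarch"):
        raise ValueError(f"unknown kernel {kernel!r}")

    per_batch = config.histories // config.batches
    batch_doses = np.zeros((config.batches, n_lab))
    masses_g = np.zeros(n_lab)
    counts = np.bincount(labels.ravel(), minlength=n_lab)
    for lab, (_, mid) in phantom.regions.items():
        masses_g[lab] = counts[lab] * phantom.voxel_volume_cm3 \
            * phantom.materials[mid].density
    for b in range(config.batches):
        edep = np.zeros(n_lab)
        emitted = fn(per_batch, config.seed + b, labels, mat_of_label,
                     mu_pe, mu_in, mu_coh, config.coherent, majorant,
                     ox, oy, oz, vx, vy, vz, *beam_args,
                     cdf, energies, config.cutoff_kev, edep)
        if edep.sum() > emitted + 1e-9:
            raise RuntimeError("energy conservation violated in tally")
        with np.errstate(divide="ignore", invalid="ignore"):
            dose = np.where(masses_g > 0,
                            edep * KEV_TO_J / (masses_g * 1e-3) / per_batch,
                            0.0)
        batch_doses[b] = dose
    region_names = tuple(phantom.regions[lab][0] if lab in phantom.regions
                         else f"label{lab}" for lab in range(n_lab))
    return TallyResult(regions=region_names, batch_doses=batch_doses,
                       histories=per_batch * config.batches)


def air_kerma_per_history(beam: BeamField, spectrum: Spectrum,
                          config: TransportConfig,
                          distance_cm: float = REFERENCE_DISTANCE_CM
                          ) -> tuple[float, float]:
    """Air kerma (Gy/history) at `distance_cm`, primaries only, in vacuum.

    Track-length fluence estimator in a thin air slab normal to the beam
    axis covering the full field.  Returns (mean, standard error).
    """
    rng = np.random.default_rng(config.seed)
    area = beam.field_area_at(distance_cm)
    axis = beam.axis
    per_batch = config.histories // config.batches
    vals = np.empty(config.batches)
    for b in range(config.batches):
        e = _sample_spectrum(spectrum, rng, per_batch)
        d = beam.sample_directions(rng, per_batch)
        cos = d @ axis
        mu_en = _air_mu_en(e)
        vals[b] = np.mean(e * KEV_TO_J * mu_en * 1e3 / (area * cos))
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(config.batches))


def _sample_spectrum(spectrum: Spectrum, rng, n):
    cdf, energies = _spectrum_cdf(spectrum)
    idx = np.searchsorted(cdf, rng.random(n), side="left")
    return np.clip(energies[idx] + rng.uniform(-0.5, 0.5, n), 1.0, None)


def kap_per_history(beam: BeamField, spectrum: Spectrum,
                    config: TransportConfig,
                    distance_cm: float = REFERENCE_DISTANCE_CM
                    ) -> tuple[float, float]:
    """Kerma-area product (Gy cm^2 per history); distance-invariant."""
    k, s = air_kerma_per_history(beam, spectrum, config, distance_cm)
    area = beam.field_area_at(distance_cm)
    return k * area, s * area
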