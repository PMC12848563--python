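# Methods

This note documents the models behind `ugidose`, their assumptions, the
defaults that matter, and what the synthetic test-bed does and does not
establish about real examinations.

## Photon interaction data

No offline cross-section library is available in this environment, so the
package assembles its own elemental database (1–150 keV) at import from
embedded anchors:

* **Incoherent scattering** is the exact free-electron Klein–Nishina cross
  section. Binding (incoherent scattering function) corrections are
  omitted; above 20 keV they are a ≤2–4 % effect for low-Z media, and they
  cancel to first order in with/without-contrast ratios.
* **Coherent scattering** uses a one-parameter form-factor suppression of
  the Thomson Z² limit, σ ∝ Z²/(1+(E/3.64·Z^⅓ keV)²)^{3/2}, calibrated
  against light-element reference data. Coherent scattering is *off* by
  default in transport (direction change only, no deposition when enabled)
  and contributes only a few per cent of total attenuation in this band.
* **Photoelectric absorption** is the residual between curated
  total-attenuation anchors (Hubbell/Seltzer-vintage grids for H, C, N, O,
  Al, Ca, Fe, Cu, W) and the analytic scattering terms, evaluated where the
  photoelectric effect dominates (residual ≥ 45 % of total) and continued
  upward as a fitted power law (exponent clamped to [−3.6, −2.4]). Trace
  tissue elements (Na, Mg, P, S, Cl, Ar, K) are interpolated in ln Z
  between curated neighbours; iodine, barium and tungsten use K/L-edge
  anchored ~E⁻³ models (edge energies 33.17, 37.44, 69.53 keV; jump ratio
  5.6), since the K-edge is precisely what drives the contrast effect.
* **Energy absorption** (μen/ρ) is photoelectric plus Klein–Nishina energy
  transfer, *pinned for oxygen and nitrogen* so that the standard dry-air
  and liquid-water reference μen/ρ tables are reproduced exactly by the
  mixture rule at the reference grid — air kerma normalises every dose
  coefficient, so the air table is the accuracy-critical item.
  Fluorescence escape after photoelectric absorption is neglected in the
  constructed μen of other elements, consistent with the transport kernel,
  which deposits the full photoelectric energy locally.

Reconstructed compound totals agree with the reference water/air tables to
within ~2.5 % across 1–150 keV (the residual is dominated by the neglected
binding correction); elemental interpolation is log–log on a dense grid
with explicit edge doublets.

## X-ray spectra

The unfiltered tube spectrum is semi-empirical: a Kramers continuum
N(E) ∝ (E₀−E)/E hardened by tungsten anode self-filtration (default
effective path 0.004 mm W), plus the tungsten K lines (57.98–69.07 keV,
standard relative intensities) above the 69.525 keV K edge with a yield
∝ (kVp/69.525 − 1)^1.63 scaled to the textbook ~10 % characteristic
fluence share at 110 kVp. A tabulated anode model would be preferable but
none is packageable here; only the behaviour of the *HVL-matched* beam is
relied on downstream. HVL is defined on narrow-beam air-kerma
transmission (weights w·E·μen_air(E), exponential primaries, total
attenuation including coherent), solved by bisection to 10⁻⁴ mm; matching
adds aluminium by outer bisection to 0.01 mm, falling back to a fixed
0.9 Cu/0.1 Al mix if aluminium alone cannot reach the target (all six grid
nodes are reachable with aluminium). Matched beams reproduce published
(kVp, HVL → mean energy) benchmarks within ±2 keV on all six grid nodes;
the mean energy is fluence-weighted (whether published values are fluence-
or energy-fluence-weighted is ambiguous; the tolerance covers both).

Clinical technique factors default to 65 kVp / 4.41 mm Al (fluoroscopy)
and 85 kVp / 3.22 mm Al (spot films). Dose coefficients may either be
computed directly at those spectra (default) or on the six-node
(kVp, HVL) grid and interpolated — linear in HVL, log-linear in kVp,
no extrapolation.

## Synthetic phantoms

`build_phantom(age, voxel_mm)` voxelises deterministic geometric
primitives (ellipsoids, elliptic cylinders, boxes) into a labelled uint16
grid: 22 regions including wall/contents pairs for stomach and small
intestine, a single whole-organ oesophagus (no lumen), one tongue region
standing in for the oral cavity, and a homogenised skeleton (no resolved
marrow — fluence-to-dose response functions for marrow/endosteum are out
of scope; the skeleton dose serves as the marrow and bone-surface
surrogate). Arms are absent, matching clinical practice of rotating them
out of the beam. The 1-year-old is an anisotropic scaling of the newborn
(×1.490 longitudinal, ×1.385 transverse) chosen to land on reference
morphometry: built masses are 3.25 kg / 51 cm (newborn) and 9.33 kg /
76 cm (1-year-old), within the 10 % / 5 % targets. Major organ masses
(brain, liver, lungs, kidneys, spleen, thymus) sit within 15 % of
reference infant values; *thin-walled* organs cannot: a reference newborn
stomach wall (~7 g) is ~1 mm thick, below the voxel size, so walls are
built at max(4.5 mm, 1.6 voxels) and come out heavier (~23 g). This
thickens the wall relative to reality and therefore *dilutes* the
contrast-shielding effect slightly; the direction checks are unaffected.

Contrast application never changes voxel labels (rigid organs): it
replaces the material of tongue/oesophagus/stomach-contents/SI-contents
with a by-volume mixture of the reference material and the agent.
E-Z-PAQUE (60 % w/v barium sulfate, solution density 1.4641 g/mL by
inversion of the printed 0.4098 mass fraction) and OMNIPAQUE-140
(302 mg iohexol/mL, density 1.1638 g/mL from 0.2595), including the
printed inactive ingredients.

## Transport

Analog photon Monte Carlo with Woodcock (delta) tracking against a
per-energy majorant over the phantom's materials; interactions sampled
among photoelectric (full local deposition), incoherent (Kahn sampling of
the free-electron Klein–Nishina distribution; transferred energy deposited
at the site — the kerma approximation, replacing the reference 20 keV
electron cutoff since CSDA ranges are sub-voxel at ≤110 kVp), and optional
coherent. Photons below 2 keV (default) deposit locally. Cross sections
are looked up on a 0.25 keV grid (floor indexing). Batch b of a run uses
seed base+b; relative errors are batch standard errors of the mean, which
empirical replication shows to be honest (spread/claimed ≈ 0.9).

The air-kerma estimator is a track-length fluence tally in a thin slab
normal to the beam axis at the 20 cm reference plane, primaries only, in
vacuum; KAP = kerma × field area and is distance-invariant by
construction of the diverging-beam geometry (window area × (d/10 cm)²).

An independent ray-marching kernel (Amanatides–Woo voxel traversal with
optical-depth accumulation) implements identical physics and serves as the
tracking oracle; the two agree within statistics, and both match
closed-form slab transmission and first-collision distributions. A cautionary
implementation note: voxel escape tests must floor() the index — C-style
truncation toward zero silently aliases a one-voxel ghost layer outside
the low grid faces, a ~5 % near-surface dose bias that only the
kernel-vs-kernel comparison exposed.

## Examination synthesis

The per-pulse KAP is solved by pooling the two *normal* reference
examinations against the published 0.02 Gy·cm² median total
(P_pulse = 0.04/(170·7.5 + 2·26·6) Gy·cm² = 0.0252 mGy·cm²); this pooled
rule uniquely reproduces the published per-field and total KAP tables for
all four examinations, including the 20 s field implied by the
3.781×10⁻³ Gy·cm² cell of the 1-year-old abnormal series. Per-field
fluoroscopy seconds are frozen in the packaged protocol JSONs. Field
margins are encoded as anatomical boxes (organ-anchored longitudinal
range + transverse width as a trunk fraction) because published margins
are figure-only; the source sits 60 cm from the phantom midline
(under-table geometry, a named constant).

Each field is simulated with and without contrast; contrast-free fields
share one simulation, making their dose ratios exactly 1.00. Before
detriment weighting, the with-contrast oesophagus and tongue doses are
replaced by the without-contrast values: contrast is mixed into those
whole organs (no lumen/cavity), which would otherwise inflate their
reported doses; the substitution is an explicit pipeline step. The
detriment-weighted dose uses ICRP-103 w_T with a documented
tissue→region map: marrow and bone surface take the homogenised skeleton
dose; salivary glands and unresolved remainder tissues take the
residual-soft-tissue dose; oral mucosa takes the tongue dose. Ratio
reports round to two decimals; totals are ratios of summed doses, not
means of per-field ratios.

## Problem sizes and determinism

Default analysis sizes — 2–4 mm voxels, 10⁵–6×10⁵ histories in 20
batches — put in-field organ relative errors at 1–4 % and run in seconds
to a few minutes on one core; they are a deliberate desk-scale choice and
can be scaled up linearly. Everything is reproducible bit-for-bit for a
fixed seed and configuration.

## What the synthetic test-bed shows — and does not

Passing tests establish: the chemistry and KAP arithmetic reproduce the
published constants exactly; the spectrum model reproduces published
hardness benchmarks; the transport engine is internally consistent and
matches closed forms; and barium/iodine contrast *decreases* the dose to
containing and downstream organs with the published qualitative pattern
(e.g. right-lateral barium-filled stomach: wall ratio ≈ 0.75 here). The
synthetic anatomy does not reproduce reference-phantom organ geometry, so
published per-organ ratio values and absolute detriment-weighted doses
are not quantitative targets: organ positioning, wall thickness and field
margins all move second-decimal ratio values. Automatic brightness/
exposure control — which in practice *raises* output when contrast enters
the field — is out of scope, as are electron transport, scatter from
table/grid, and mesh (deformable) anatomy.
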