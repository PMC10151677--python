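# Methods

This note documents the models, parameters and numerical choices behind
`expanderdose`, and what the synthetic setups do and do not capture.

## Problem

Temporary tissue expanders (TTEs) used in two-stage breast reconstruction
carry injection/drain ports with a high-density NdFeB magnet inside a
titanium (DermaSpan, AlloX2) or PEEK (AlloX2-Pro) casing.  In CT images
the magnet saturates the HU-to-density calibration (maximum convertible
density 2.5 g/cm³) and blooms, so treatment planning needs a density
override.  The package implements and compares the two clinical
strategies — RS1 (window-level threshold, keep the saturated artifact,
set the surround to unit density) and RS2 (rigid registration of the
vendor geometry template with true materials) — and quantifies the
dosimetric impact of each port with a photon Monte Carlo engine in two
synthetic irradiation setups:

* **wax-slab setup**: the port embedded mid-slab in 30×30×1.7 cm³ wax
  (ρ 0.92), 1.5 cm water-equivalent buildup upstream and 10 cm
  downstream; 6 MV AP field, 15×10 cm² at 100 cm SSD, 500 MU;
* **breast setup**: a water-filled balloon (~1 mm silicone shell,
  ρ 1.1) truncated posteriorly into a wax holder, the port assembly near
  the anterior apex, 5 mm wax bolus; 6 MV 3×3 cm² conformal arc from
  gantry 90° through 0° to 270° (parallel-opposed endpoints), 355 MU.

## Port geometry

Printed values are honoured exactly: magnet thickness along the port
axis 2.41 mm (DermaSpan), 2.50 mm (AlloX2, each of two ports), 7.14 mm
(AlloX2-Pro); AlloX2-Pro magnet diameter 10.4 mm; the Ti-encased magnets
are three times wider (31.2 mm).  Casing outer dimensions are not public;
the package freezes canonical defaults chosen from closed-form
transmission reasoning before any transport run: Ti walls 0.6 mm
(DermaSpan) and 0.5 mm (AlloX2) on the beam axis, PEEK walls 1.5 mm, port
separation 40 mm (so the dual-port assembly fits inside the balloon).
Magnet density defaults to 7.4 g/cm³ (the physics value used by the
override analysis; 7.6 g/cm³ is available as `NDFEB_76`).

## Photon physics

Elemental mass attenuation tables (0.01–10 MeV, 60 log-spaced points,
bundled CSV) are authored in `xsgen.py`:

* incoherent scattering: exact free-electron Klein–Nishina × Z/A.
  Binding effects and Doppler broadening are neglected (sub-percent above
  0.1 MeV for the materials used here);
* pair production: universal energy shape extracted from published water
  attenuation anchors (total minus Klein–Nishina), scaled per element as
  Z(Z+1)/A with a Coulomb-correction factor 1 − 0.6 (αZ)²;
* photoelectric: hydrogenic parameterization f(Z)·c·Z⁴·⁵/A·(E⁻³ + rE⁻¹)
  calibrated to published water (10 keV) and lead (1 MeV) values, with a
  K-edge jump correction for Nd.  Accuracy is a few percent for water
  above 0.3 MeV (verified against the anchors) and of order tens of
  percent for metals below ~0.1 MeV, which affects only low-energy
  scattered photons;
* coherent (Rayleigh) scattering is excluded: it transfers no energy and
  contributes a few percent to attenuation only below ~0.1 MeV.

The 6 MV spectrum is a parameterized bremsstrahlung shape
φ(E) ∝ E·exp(−E/0.9 MeV) truncated to 0.25–6 MeV (40 bins), with
fluence-weighted mean 1.80 MeV — inside the 1.6–2.2 MeV range of
published 6 MV spectra.  A monoenergetic override exists for oracles.

## Monte Carlo engine

Voxel photon transport under the collision-kerma approximation: energy
transferred to electrons is deposited at the transfer site (no electron
stepping).  Two modes share the same physics tables:

* **analog** — textbook Woodcock (delta) tracking against an
  energy-dependent majorant with collision-site deposition; photons below
  10 keV (mean free path below the voxel size) deposit locally and
  terminate, which keeps the energy ledger exactly balanced.  This mode
  backs the distribution oracles (first-flight depths vs Exp(μ), energy
  bookkeeping, 1/√N uncertainty scaling).
* **expected-value (default)** — photons are ray-marched voxel-by-voxel
  depositing the expected collision kerma weighted by the accumulated
  transmittance (implicit capture), while one interaction per flight is
  sampled from the analog free-flight density to spawn the scattered
  branch (Klein–Nishina Compton sample; pair production spawns two
  0.511 MeV photons).  Source position, energy, first-interaction depth
  and first-scatter azimuth are sampled with scrambled radical-inverse
  (Halton-type) sequences, randomized per batch, so primary dose is
  essentially stratified.  This is the package's variance-reduction
  choice: the per-voxel 0.5% statistical goal is far out of reach for
  analog kerma scoring at desk-scale history budgets.  An optional
  first-scatter splitting factor exists but defaults to 1 (measured
  inefficient for these geometries).

Doses are scored on the density-grid lattice (2×2×2 mm³ by default, the
clinical dose-grid resolution); rasterization uses supersampled
partial-volume densities for the thin port layers (see below), so the
magnet's areal density is preserved on the coarse lattice.  Uncertainty
is batch-based (10 batches): per-voxel 1σ of the batch mean.  Runs are
bit-reproducible for a fixed seed and single thread.

Energy bookkeeping (launched = deposited + escaped) is exact in analog
mode and statistical (≪0.1% at ≥10⁵ histories) in the default mode,
because the sampled scatter branch carries one realization of the
channel-averaged expectation used for kerma.

Calibration follows the clinical convention: a reference run (10×10 cm²,
SSD 100 cm, water) fixes the output factor so that 1 MU delivers 1 cGy at
the depth of maximum dose for the given engine; an exponential fit
A·exp(−b·d) over 5–15 cm retrieves smoothed point doses at depth.  All
comparison quantities in the studies are ratios, so they are
calibration-independent.

## Analytic raytracer

A deterministic primary-beam stand-in for a TPS algorithm:
MU × (SAD/r)² × exp(−∫μ dl) × B(d_eff) with radiological paths at the
spectrum's effective energy and B(d) = (1 − e^(−βd))(1 + s·d).
β = 2.6 cm⁻¹ places d_max near 1.5 cm; the scatter slope s = 0.020 cm⁻¹
was fitted once against the engine's own Monte Carlo water PDD and then
frozen; with it, raytracer and MC water PDDs agree within 3% beyond the
buildup region.  The raytracer has no lateral scatter, so it is used for
fast checks and calibration tests, never for the acceptance quantities.

## Rasterization

Scenes are voxelized by priority overlay (ports override slab/balloon,
magnet overrides casing), labels by majority-at-center.  Densities of
small solids use supersampled (3³ per voxel) occupancy mixing: without
this, the 2.41 mm magnet on a 2 mm grid aliases its areal density by up
to ±25%, which directly corrupts every attenuation quantity.  The
no-port ground truth is produced by re-voxelizing the scene without the
port solids, so partial-volume halo voxels are also restored.

## Synthetic CT and override strategies

HU = 1000(ρ−1), saturated at 2.5 g/cm³ (HU 1500).  With bloom on, the
bright footprint of Ti-encased ports is dilated along the port axis to
~3× the magnet thickness (the printed artifact-to-magnet ratio); the
PEEK-encased magnet keeps a ~1× footprint.  Optional seeded streaks are
off by default.  RS1 thresholds at the HU of 2.0 g/cm³, keeps the n
largest connected components (n = number of ports) at the saturated
density with water-equivalent composition, and sets the rest of the
override contour (bright-region bounding box, or the bag in the breast
scene, plus a 1 cm margin) to unit density.  RS2 initializes the pose
from artifact/template centroids and refines by exhaustive local search
(translation ±3 voxels per axis, axial rotation ±10° in 1° steps)
maximizing Dice overlap between the artifact and the template's
high-density occupancy footprint; ties break toward the smallest
translation, then rotation.  The registered template is painted with
true materials and partial-volume densities.

## Analysis

Profiles can average laterally over a ±5 mm patch (the 1×1 cm² film
size); this suppresses the upward bias of taking a maximum over noisy
single-voxel profile points.  The port effect is 100(D_no-port −
D_port)/D_no-port with quadrature-propagated uncertainty; the distal
region is 34–130 mm (between slab exit and the end of the downstream
stack) and the proximal backscatter window 8–18 mm (upstream of the
deepest port face).  D1/D10 are linear-interpolated quantiles of the
voxel-dose distribution; DVH difference tables normalize each entry to
the first-named run and quote the dose-weighted mean relative
uncertainty of the contour in quadrature.  The gamma index is the
brute-force definition with global normalization (local behind a flag),
sub-voxel linear interpolation (3 subdivisions per voxel) and a search
radius of 3× the distance criterion.

## Study conditions and problem sizes

The acceptance computation (`scripts/acceptance.py`) uses 10⁷ histories
per wax-slab run (3.2×10⁷ for the DermaSpan with-port run, which also
reports the statistical-uncertainty gate), 8×10⁶ per strategy-comparison
run and 8×10⁶ per partial-arc run split over 91 control points — sizes
chosen so the whole computation completes in minutes on one CPU while
the high-dose median per-voxel uncertainty stays below 0.5%.  The test
suite runs the same code paths at reduced budgets, widening tolerances
by the run's own statistical uncertainty.

## What the synthetic data does and does not capture

The generator reproduces the printed geometry (magnet dimensions, slab
and bolus thicknesses, contour volumes within 20%), CT saturation at
2.5 g/cm³ and the ~3×/~1× artifact-bloom ratios.  It does not attempt
sinogram-domain artifact physics, residual iMAR streak morphology
(available only as a generic seeded perturbation), vendor casing
internals beyond the printed magnet data, or film-response physics
(films are emulated as 1 cm² averaging probes).

Known physics limitations, visible in the acceptance comparisons:

* **Kerma approximation.**  Without electron transport there is no
  buildup region and no electron backscatter.  The proximal overdose
  upstream of the AlloX2-Pro magnet computed here is photon backscatter
  only (≲1%), well below the ~3% reported from film/full-MC, which is
  dominated by backscattered electrons within the first millimetres.
* **Solid-disc magnet model.**  With a solid 10.4 mm × 7.14 mm NdFeB
  disc the primary shadow attenuation is ~20%, and photon in-scatter
  over the 10 cm downstream stack refills it only partially: the
  computed AlloX2-Pro distal underdose is ~10%, far above the reported
  2.0 ± 0.9%.  No solid-disc geometry consistent with the printed
  dimensions and density can reproduce that value under photon
  transport; the real device plausibly differs in ways the printed
  description does not capture (e.g. an annular or lower-effective-
  density magnet).  The same overestimate propagates to every quantity
  that contrasts the full-density magnet with a weaker representation
  (AlloX2-Pro RS1-vs-RS2, AlloX2 posterior D10 deficits).
* **Closed-form attenuation.**  exp(−μρt) for the 2.41–2.5 mm magnet at
  the 1.8 MeV effective energy gives ~7.7%, above the ~5% printed
  back-of-envelope estimate (which itself sits below the reported
  full-MC 6.4%); the discrepancy is the choice of effective energy in a
  hand estimate, not a table error (the tables match published water
  values to 1%).

These are documented honestly rather than tuned away: the geometry and
conditions were frozen before the transport runs.
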