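# Methods

This note documents the physical models, numerical choices and known
limitations of `voxray`, in the spirit of a methods appendix: what is
simulated, what is approximated, and what the tests do and do not show.

## Transport model

Analog, unweighted photon transport: each launched photon is one simulated
history, so "photons launched" maps one-to-one to histories and all scored
quantities are per-launched-photon without statistical weights.  No
variance reduction is used.

**Woodcock (delta) tracking.**  Free paths are sampled from the majorant
attenuation coefficient μ̂(E) = maxₘ μₘ(E) over the materials present in the
phantom, evaluated per photon energy on a 0.25 keV grid (no coarser energy
binning).  A tentative collision is real with probability μ_local/μ̂; the
engine raises if the contract μ_local ≤ μ̂ is ever violated.  Outside the
phantom's bounding box the medium is vacuum: photons fly in straight lines
to the detector plane.  Air *inside* the grid participates normally (its μ
is ~10⁻⁵/mm, so nearly all tentative collisions there are virtual).  A
consequence of the vacuum-outside convention is that the ~600 mm air column
between phantom and detector, which would attenuate the beam by ~1–2 %, is
not modelled; this cancels in every normalized comparison the package makes.

**Interactions.**  Photoelectric absorption deposits the full photon energy
locally and terminates the history (no fluorescence: for the low-Z breast
tissues the K-shell yields are negligible).  Compton scattering samples the
free-electron Klein–Nishina distribution with Kahn's composition–rejection
method and deposits E − E′ locally; electrons are not tracked because their
CSDA range at ≤ 80 keV is below the 1 mm voxel size.  The incoherent
scattering function S(q, Z) and Doppler broadening are not applied — a
deliberate simplification that slightly overestimates forward incoherent
scatter at mammographic energies; the bundled *total* attenuation remains
exact by construction (see Data).  Rayleigh scattering samples the Thomson
cross section modulated by the material's independent-atom form factors.
Photons below the 1 keV cutoff terminate and deposit locally.

**Scoring.**  The detector is an ideal energy integrator: every photon
crossing the detector rectangle adds its current energy to the struck pixel
and terminates (detector-scored photons are counted once, in the detector
channel of the energy ledger).  A primary-only image (photons with zero
interactions) is kept alongside.  Dose is tallied for all tissues on a
1 mm³ grid covering the phantom bounding box; glandular-only analysis is
applied afterwards through the label volume, which is strictly more
information than a glandular-only tally and reduces to it exactly.

**Randomness.**  All streams derive from NumPy's PCG64 via
`default_rng([seed, batch])`; CT views use seed + view_index.  Identical
seed and configuration reproduce detector images and dose grids
bit-identically (tested).

## Cross-section data

No cross-section library is a runtime dependency; the package bundles
tables for H, C, N, O, P, Al, Ar, Cu on a 220-point log grid over
1–200 keV, built by `scripts/build_xs_tables.py` from three ingredients:

1. **Incoherent** = the exact Klein–Nishina total cross section × Z·N_A/A.
   This is also precisely the cross section the sampler uses, so sampling
   and attenuation are mutually consistent.
2. **Coherent** = Thomson × F²(q, Z) integrated over angle, with the
   one-term screened form factor F = Z/(1+(bq)²)², b = β·Z^(−1/3) Å.  The
   single constant β = 0.41 Å was calibrated once by requiring that the
   photoelectric remainder (below) behave as a smooth power law in energy
   for the well-anchored elements; the resulting b values also match the
   known half-fall points of tabulated form factors for H, C, O to ~10 %.
3. **Photoelectric** = total − (1) − (2) at hand-entered anchor values of
   the standard total mass-attenuation compilation (Hubbell & Seltzer),
   interpolated monotonically (PCHIP) in log–log and extrapolated with the
   boundary power laws.

Because (3) absorbs any error of (2) at the anchors, the summed tables
reproduce the compilation totals exactly at the anchor energies; the
builder's self-check reproduces the water μ/ρ compilation to < 0.1 % at
10–200 keV from the H and O tables.  The split between photoelectric and
coherent is therefore approximate at the few-percent level (and the
"photoelectric" column also absorbs the small S(q,Z) difference of the
free-electron incoherent model), but every quantity that depends on total
attenuation — transmission, HVL, interaction density — is anchored to the
compilation.  P and Ar (trace constituents only) are synthesized from the
Al photoelectric curve by Z^4.7/A scaling.  Between grid points all lookups
interpolate linearly in log–log, which is monotone within a segment.
Element tables have no absorption edges in 1–200 keV except Cu's K edge at
9.0 keV, which the smooth fit ignores; the Cu filter sees no flux below
~15 keV in practice.

**Tissues.**  Hammerstein compositions: glandular (H .102, C .184, N .032,
O .677, trace .005; ρ 1.04), adipose (H .112, C .619, N .017, O .251,
trace .001; ρ 0.93), skin (H .098, C .178, N .050, O .667, trace .007;
ρ 1.09).  Trace elements (Na, P, S, Cl, K) are lumped into P — at ≤ 0.7 %
by mass this changes μ by < 0.5 %.  Mixtures mix mass fractions linearly
and densities volume-additively (1/ρ = Σ wᵢ/ρᵢ); the 50/50
glandular/adipose mixture then reproduces exactly the published composition
and its 0.9819 g/cm³ density, which is a strong consistency check of the
tissue constants.

## Spectra

`scripts/build_spectra.py` generates the two fixtures from a Kramers-type
semi-empirical model (photon fluence ∝ (kVp − E)/E, 0.5 keV bins) with
Beer–Lambert filtration through the bundled attenuation tables, plus the W
K lines (6 % of fluence, Kα/Kβ ratios 100:57:33:9) above the K edge:

* `w28kv_al`: 28 kV, 1 mm Al-equivalent inherent + 0.5 mm Al added.
  Computed HVL 0.618 mm Al, mean energy 20.5 keV.  The inherent thickness
  is this package's choice (recorded in the header), made so the beam
  quality is typical of a W/Al mammography system.
* `w80kv_cu`: 80 kV, 2 mm Al inherent + Cu added filtration, with the Cu
  thickness **calibrated once** by bisection so the air-kerma HVL equals
  5.74 mm Al, the beam quality of the first-generation breast-CT systems
  this geometry models.  The calibration converged to 0.1996 mm Cu —
  squarely in the physically expected ~0.2 mm range — and is recorded in
  the fixture header.  Mean energy 52.5 keV.

HVL is defined on air kerma (fluence × E × (μen/ρ)air), the standard
dosimetric definition, and solved by bracketing + bisection to 10⁻⁴ mm.
Energy sampling is discrete per bin (inverse CDF over bins).

## Geometry

Planar: source at the origin, beam along +z, detector plane at
SDD = 660 mm with the source's perpendicular foot on the *top edge
midpoint* (half-field); 285×285 mm², 1900×1900 pixels of 0.15 mm; the
compressed breast sits with its entrance surface at SOD = 595 mm, leaving
the 15 mm airgap to the detector.  CT: vertical rotation axis through the
isocenter; source at 650 mm, detector at 923 mm from the source, half-cone
aligned to the detector's upper side; 360 projections × 1° by default,
scaled runs use n views × (360/n)° so the full circle is always covered.
The phantom stays fixed and source + detector rotate (equivalent to gantry
rotation).  The CT detector pitch is not part of the geometry definition
and defaults to 0.25 mm (1160×920 pixels); dose results are
pitch-independent.  Voxel convention: 0-based indices, voxel-centre world
position = origin + (index + ½)·voxel_size, half-open extents; *coronal*
slices are planes perpendicular to the pendant/rotation axis.

Collimated source sampling draws directions uniformly in the solid angle of
the detector rectangle by rejection from its bounding spherical cap —
exact, unweighted, and every sampled direction hits the detector.

## Phantoms and segmentation

The geometric builders produce the semicircular compressed breast
(r = 100 mm, 50 mm thick, 2 mm skin on the curved and entrance/exit
surfaces, homogeneous 20 % glandular interior) and the homogeneous 50/50
cylinder (⌀140 × 150 mm).  Mixtures are single homogeneous materials, not
voxel-level stochastic mixes.

The breast-CT segmentation classifies each coronal slice into air / skin /
gland / adipose: background threshold (−500 HU) + hole filling; skin by a
local adaptive threshold (15 mm window mean over *tissue* + 60 HU offset)
within 3 mm of the surface, with the innermost 2 mm rind always skin;
gland by intensity threshold (−45 HU) cleaned by erosion with geodesic
reconstruction (opening by reconstruction, which suppresses speckle
without shrinking structures) and hole filling; remaining interior is
adipose; a final through-plane erosion+reconstruction pass along the
pendant axis keeps glandular structures seamless across slices.  Surface
depth is measured with a 3D distance transform so the dome cap is a thin
rind rather than a deep in-plane region.  All numeric parameters are this
package's defaults (exposed in `SegmentationParams`); published
descriptions of this procedure specify the steps but not the numbers.  A
volume with no foreground voxels segments to all air.

The synthetic pendant-breast generator (`synth_breast_hu`) builds a half
ellipsoid with a 2 mm skin shell and carves glandular structure from a
Gaussian-correlated random field (default correlation length 5 mm),
thresholded at the quantile that realizes the requested glandular *mass*
fraction of the whole breast (default 0.17, the glandularity scale of
patient-derived phantoms); intensities are CT-like (air −1000, adipose
−120, gland +30, skin +60, σ = 12 HU noise).  It emulates the gross
intensity structure of a breast CT scan — not ligaments, ducts, vasculature
or beam-hardening artefacts — so segmentation results on it bound the
algorithm's behaviour under ideal contrast, not clinical performance.

## Analysis conventions

* **Dose conversion**: keV per voxel × 1.602×10⁻¹⁶ J/keV / voxel mass,
  rescaled by n_reference/n_launched, reported in mGy.  Voxel mass comes
  from the phantom material(s) underlying each dose voxel; air voxels
  report zero dose and are masked.
* **MGD**: mean (and SD) over glandular-labelled dose voxels; homogeneous-
  mixture phantoms have no discrete gland voxels, so the mean is over all
  mixture voxels — for a uniform mixture the absorbed dose to the mixture
  equals the absorbed dose to its glandular component, so the two
  conventions coincide there.
* **Gamma index**: γ(r) = min over r′ of √(|r−r′|²/DTA² + ΔD²(r,r′)/δ²)
  with δ = dd% of the **global reference maximum** (global normalization,
  the common convention for 3 %/3 mm; stated in every `GammaResult`).
  Evaluated at voxel centres without sub-voxel interpolation (1 mm grid ≪
  3 mm DTA); search capped at 3×DTA with early termination, verified
  identical to exhaustive brute force on random maps.  The cylinder-study
  mask restricts to the central 100 slices of the phantom; no low-dose
  cutoff is applied.
* **Uncertainty**: batch method, default 10 batches; per-pixel relative SE
  of the batch mean, summarized as the mean over in-beam nonzero pixels
  (the "in-beam ROI" reading of a per-pixel uncertainty target — the
  choice is labelled in reports); extrapolation across photon counts uses
  the 1/√N law, verified by the fitted −0.5 scaling slope.

## Problem sizes

The package is designed for desk-scale studies: the bundled presets and
examples use 10⁵–10⁷ photons and 8–36 CT views, and the headline
recomputation (`scripts/acceptance.py`) uses 36 views × 10⁶ photons, which
resolves the cylinder MGD to well under a percent statistically.  Per-pixel
image noise at these scales is large (that is what the 1/√N extrapolation
quantifies); full-exam image quality would need the 10⁹–10¹¹-photon counts
of the corresponding physical exams.

## Known limitations

* Free-electron Compton (no S(q,Z)/Doppler) and one-term form factors:
  angular distributions are approximate at the few-percent level even
  though total attenuation is anchored to the compilation.
* No electron transport, fluorescence, polarization, detector response
  (blur, noise, angular dependence), finite focal spot, heel effect or
  bowtie filtration.
* No absorption edges in the tables (relevant only to the Cu filter below
  ~9 keV, where the transported flux is nil).
* The spectrum fixtures are model beams matched to kVp/filtration/HVL, not
  measured tube spectra; quantities that integrate over the spectrum
  (e.g. MGD per photon) inherit a few-percent model uncertainty.
* DBT acquisition, image reconstruction, and clinical patient phantoms are
  out of scope; the CT pipeline emits projection stacks, not reconstructed
  volumes.
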