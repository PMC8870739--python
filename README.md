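# voxray

Voxel-phantom Monte Carlo photon transport for virtual clinical trials in
X-ray breast imaging and dosimetry.

`voxray` simulates planar (mammography-like) and cone-beam breast-CT
exposures of voxelized breast phantoms and produces the quantities those
studies are built on: detector images (cumulative impinging photon energy
per pixel), 3D absorbed-dose maps at 1 mm³ resolution, the mean glandular
dose (MGD), 3D gamma-index comparisons of dose maps, and batch-method
statistical uncertainties.  It is aimed at medical-physics researchers who
need a transparent, reproducible desk-scale simulator of the breast imaging
chain: digital phantom in, images and dose out, every photon accounted for.

## The model

Photons are transported one interaction at a time with **analog (unweighted)
Monte Carlo**.  Free paths through the voxel grid are sampled with
**Woodcock (delta) tracking**: flight distances are drawn from an
energy-dependent majorant attenuation coefficient
μ̂(E) = max over phantom materials of μ(E), and a tentative collision at a
site with local coefficient μ(E) is real with probability μ/μ̂, otherwise
virtual — no explicit voxel-boundary ray tracing is needed.  Three
interactions are modelled over 1–200 keV:

* **photoelectric absorption** — the photon terminates, its full energy is
  deposited in the local 1 mm³ dose voxel;
* **incoherent (Compton) scattering** — scattered energy and polar angle
  from the free-electron Klein–Nishina cross section (Kahn's
  composition–rejection sampling); the electron energy E − E′ is deposited
  locally (electrons are not tracked: their range is below the voxel size
  at these energies);
* **coherent (Rayleigh) scattering** — Thomson scattering modulated by
  screened atomic form factors, no energy loss.

Photons crossing the detector within bounds add their current energy to the
struck pixel (primaries and scatter alike; a separate primary-only image is
kept).  Energy bookkeeping is exact per batch:
launched = deposited + detector-scored + escaped.

Materials are elemental mixtures with the mixture rule
(μ/ρ)ₘᵢₓ = Σ wᵢ (μ/ρ)ᵢ, built on bundled elemental cross-section tables
(H, C, N, O, P, Al, Ar, Cu).  Breast tissues follow the Hammerstein
compositions; the homogeneous 50/50 glandular/adipose breast-CT mixture has
density 0.9819 g/cm³.  Beam quality is characterized by the air-kerma
half-value layer, HVL = t such that Σᵢ wᵢEᵢ(μen/ρ)ₐᵢᵣ e^(−μ_Al t) is halved.

Two acquisition geometries are built in: a planar half-field setup
(point source 660 mm from a 285×285 mm² detector, focal spot aligned with
the detector's top edge, object at 595 mm) and a rotating half-cone
breast-CT setup (source 650 mm from the isocenter, 923 mm from a
290×230 mm² detector, pendant phantom on the vertical rotation axis).

## Worked example

A scaled breast-CT dose study (`examples/cylinder_ct_mgd.py`): a full
rotation around the homogeneous 140 mm × 150 mm 50/50 cylinder with the
80 kV W/Cu spectrum (HVL 5.74 mm Al), 36 views × 10⁵ photons:

```
36 views x 1e+05 photons (4e+06 total), deposited 23.7% of the launched
energy in the phantom bounding box
MGD = 3.159e-06 mGy for 4e+06 photons -> 8.776e-13 mGy per launched photon
rescaled to a 3.6e11-photon exam: 0.316 mGy
radial dose profile (surface -> centre -> surface):
3.66e-06 / 3.02e-06 / 3.61e-06 mGy
```

The MGD is reported per launched photon so it can be rescaled to any
exposure; the radial profile shows the axially symmetric surface-to-centre
fall-off of a full rotation.  The other examples cover the flat-field
validation against the analytic solid-angle map, planar compressed-breast
imaging and depth dose, gamma-index comparison of two independent dose
maps, and synthetic-breast segmentation:

```bash
python examples/attenuation_and_hvl.py
python examples/flat_field.py
python examples/planar_breast_dose.py
python examples/cylinder_ct_mgd.py
python examples/gamma_comparison.py
python examples/segment_synthetic_breast.py
```

There is also a thin CLI (`voxray --help`) with subcommands for building
phantoms, running the case-study presets from YAML configs, spectrum HVL,
gamma comparisons and profile extraction.

## Data provenance

The elemental cross-section tables are generated by
`scripts/build_xs_tables.py` (incoherent from exact Klein–Nishina,
coherent from a calibrated screened form-factor model, photoelectric as the
remainder of standard Hubbell & Seltzer total-attenuation anchor values);
the script's self-check reproduces the water μ/ρ compilation to < 0.1%
over 10–200 keV.  The spectrum fixtures are generated by
`scripts/build_spectra.py` from a Kramers-type tungsten-anode model; the Cu
filtration of the 80 kV fixture is calibrated once so its HVL is
5.74 mm Al (recorded in the fixture header).
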