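"""Materials, the mixture rule, and spectrum beam quality.

Builds the breast-tissue materials, evaluates mass/linear attenuation at
diagnostic energies, and characterizes the two bundled spectra by their
air-kerma half-value layer in aluminium.
"""
import numpy as np

from voxray import (Spectrum, get_material, hvl_al, linear_attenuation,
                    mass_attenuation, mix_materials)

mix = get_material("glandular_adipose_50_50")
print("50/50 glandular/adipose mixture "
      f"(rho = {mix.density} g/cm^3):")
for e in (20.0, 30.0, 50.0, 80.0):
    print(f"  mu/rho({e:>4.0f} keV) = {mass_attenuation(mix, e):.4f} cm^2/g"
          f"   mu = {linear_attenuation(mix, e):.5f} /mm")
# mu/rho falls steeply with energy below ~50 keV (photoelectric) and gently
# above (Compton-dominated): the basis of beam hardening and dose gradients.

mixed = mix_materials([(get_material("glandular"), 0.5),
                       (get_material("adipose"), 0.5)], "mixed")
print(f"\nmass-weighted 50/50 mixing gives rho = {mixed.density:.4f} g/cm^3 "
      "(equals the library mixture)")

for name in ("w28kv_al", "w80kv_cu"):
    spec = Spectrum.fixture(name)
    print(f"\n{name}: {spec.energies.size} bins, "
          f"mean energy {spec.mean_energy():.2f} keV, "
          f"HVL = {hvl_al(spec):.3f} mm Al")
# The 80 kV W/Cu beam is the breast-CT quality (HVL 5.74 mm Al by fixture
# calibration); the 28 kV W/Al beam is the mammography quality.
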