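# Material library: density [g/cm^3] and elemental mass fractions.
# Breast tissues follow the Hammerstein compositions; trace elements
# (Na, P, S, Cl, K, ~0.1-0.7% by mass) are lumped into P.
# glandular_share is the glandular mass fraction of the material, used by
# glandular dosimetry on homogeneous-mixture phantoms.
air:
  density: 0.0012047
  glandular_share: 0.0
  mass_fractions: {C: 0.000124, N: 0.755267, O: 0.231781, Ar: 0.012828}
water:
  density: 1.0
  glandular_share: 0.0
  mass_fractions: {H: 0.111894, O: 0.888106}
adipose:
  density: 0.93
  glandular_share: 0.0
  mass_fractions: {H: 0.112, C: 0.619, N: 0.017, O: 0.251, P: 0.001}
glandular:
  density: 1.04
  glandular_share: 1.0
  mass_fractions: {H: 0.102, C: 0.184, N: 0.032, O: 0.677, P: 0.005}
skin:
  density: 1.09
  glandular_share: 0.0
  mass_fractions: {H: 0.098, C: 0.178, N: 0.050, O: 0.667, P: 0.007}
# The homogeneous 50% glandular / 50% adipose breast-CT mixture, with the
# exact printed composition and density (equals mass-weighted mixing of the
# glandular and adipose entries above).
glandular_adipose_50_50:
  density: 0.9819
  glandular_share: 0.5
  mass_fractions: {H: 0.107, C: 0.401, N: 0.025, O: 0.464, P: 0.003}
aluminum:
  density: 2.699
  glandular_share: 0.0
  mass_fractions: {Al: 1.0}
copper:
  density: 8.96
  glandular_share: 0.0
  mass_fractions: {Cu: 1.0}
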