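"""Physical constants used throughout the package (CODATA values)."""

R_E_CM = 2.8179403262e-13        # classical electron radius [cm]
MEC2_KEV = 510.998950            # electron rest energy [keV]
N_AVOGADRO = 6.02214076e23       # [1/mol]
HC_KEV_ANGSTROM = 12.39841984    # h*c [keV * Angstrom]
KEV_TO_JOULE = 1.602176634e-16   # [J/keV]

#: photons below this energy are terminated and deposit locally [keV]
ENERGY_CUTOFF_KEV = 1.0

#: validity range of the bundled cross-section tables [keV]
TABLE_EMIN_KEV = 1.0
TABLE_EMAX_KEV = 200.0
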