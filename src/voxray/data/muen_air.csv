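# muen_air: mass energy-absorption coefficient, cm^2/g
# energy_keV mu_en_over_rho
8.000000e+00 9.446000e+00
1.000000e+01 4.742000e+00
1.500000e+01 1.334000e+00
2.000000e+01 5.389000e-01
3.000000e+01 1.537000e-01
4.000000e+01 6.833000e-02
5.000000e+01 4.098000e-02
6.000000e+01 3.041000e-02
8.000000e+01 2.407000e-02
1.000000e+02 2.325000e-02
1.500000e+02 2.496000e-02
2.000000e+02 2.672000e-02
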