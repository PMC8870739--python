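# muen_al: mass energy-absorption coefficient, cm^2/g
# energy_keV mu_en_over_rho
1.000000e+01 2.543000e+01
1.500000e+01 7.487000e+00
2.000000e+01 3.094000e+00
3.000000e+01 8.778000e-01
4.000000e+01 3.601000e-01
5.000000e+01 1.840000e-01
6.000000e+01 1.099000e-01
8.000000e+01 5.511000e-02
1.000000e+02 3.794000e-02
1.500000e+02 2.827000e-02
2.000000e+02 2.745000e-02
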