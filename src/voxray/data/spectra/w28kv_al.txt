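# 28 kV W-anode spectrum, Kramers model,
# 1 mm Al-equivalent inherent + 0.5 mm Al added filtration
# computed air-kerma HVL = 0.618 mm Al
# bin width 0.5 keV
# energy_keV relative_fluence
8.000000e+00 1.971911e-09
8.500000e+00 4.825199e-08
9.000000e+00 6.056771e-07
9.500000e+00 4.585908e-06
1.000000e+01 2.354643e-05
1.050000e+01 8.952512e-05
1.100000e+01 2.688578e-04
1.150000e+01 6.682624e-04
1.200000e+01 1.425370e-03
1.250000e+01 2.683616e-03
1.300000e+01 4.560504e-03
1.350000e+01 7.119893e-03
1.400000e+01 1.035786e-02
1.450000e+01 1.420063e-02
1.500000e+01 1.852015e-02
1.550000e+01 2.315432e-02
1.600000e+01 2.792678e-02
1.650000e+01 3.265356e-02
1.700000e+01 3.716119e-02
1.750000e+01 4.129898e-02
1.800000e+01 4.494451e-02
1.850000e+01 4.800444e-02
1.900000e+01 5.041392e-02
1.950000e+01 5.213469e-02
2.000000e+01 5.315158e-02
2.050000e+01 5.347049e-02
2.100000e+01 5.311153e-02
2.150000e+01 5.210472e-02
2.200000e+01 5.048787e-02
2.250000e+01 4.830454e-02
2.300000e+01 4.560158e-02
2.350000e+01 4.242721e-02
2.400000e+01 3.882975e-02
2.450000e+01 3.485648e-02
2.500000e+01 3.055279e-02
2.550000e+01 2.596058e-02
2.600000e+01 2.112120e-02
2.650000e+01 1.607259e-02
2.700000e+01 1.084912e-02
2.750000e+01 5.482123e-03
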