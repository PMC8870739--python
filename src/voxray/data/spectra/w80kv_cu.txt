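# 80 kV W-anode spectrum, Kramers model + W K lines,
# 2 mm Al inherent + 0.1996 mm Cu added filtration
# (Cu thickness calibrated once so the air-kerma HVL is 5.74 mm Al; computed HVL = 5.7400 mm Al)
# bin width 0.5 keV
# energy_keV relative_fluence
8.000000e+00 1.536993e-43
8.500000e+00 4.343836e-37
9.000000e+00 6.437000e-32
9.500000e+00 1.008143e-27
1.000000e+01 2.746537e-24
1.050000e+01 1.729781e-21
1.100000e+01 3.868734e-19
1.150000e+01 3.775497e-17
1.200000e+01 1.872197e-15
1.250000e+01 5.314420e-14
1.300000e+01 9.498501e-13
1.350000e+01 1.154804e-11
1.400000e+01 1.015033e-10
1.450000e+01 6.787066e-10
1.500000e+01 3.596287e-09
1.550000e+01 1.563572e-08
1.600000e+01 5.737334e-08
1.650000e+01 1.818769e-07
1.700000e+01 5.080010e-07
1.750000e+01 1.271042e-06
1.800000e+01 2.888746e-06
1.850000e+01 6.035501e-06
1.900000e+01 1.171120e-05
1.950000e+01 2.129020e-05
2.000000e+01 3.653729e-05
2.050000e+01 5.961118e-05
2.100000e+01 9.300319e-05
2.150000e+01 1.394140e-04
2.200000e+01 2.016179e-04
2.250000e+01 2.823177e-04
2.300000e+01 3.839935e-04
2.350000e+01 5.087618e-04
2.400000e+01 6.582662e-04
2.450000e+01 8.335992e-04
2.500000e+01 1.035256e-03
2.550000e+01 1.263087e-03
2.600000e+01 1.516373e-03
2.650000e+01 1.793870e-03
2.700000e+01 2.093855e-03
2.750000e+01 2.414207e-03
2.800000e+01 2.752223e-03
2.850000e+01 3.105405e-03
2.900000e+01 3.470958e-03
2.950000e+01 3.845828e-03
3.000000e+01 4.226958e-03
3.050000e+01 4.612127e-03
3.100000e+01 4.998710e-03
3.150000e+01 5.383937e-03
3.200000e+01 5.765678e-03
3.250000e+01 6.141588e-03
3.300000e+01 6.509273e-03
3.350000e+01 6.867393e-03
3.400000e+01 7.213820e-03
3.450000e+01 7.547284e-03
3.500000e+01 7.866916e-03
3.550000e+01 8.170738e-03
3.600000e+01 8.459032e-03
3.650000e+01 8.730186e-03
3.700000e+01 8.984313e-03
3.750000e+01 9.220896e-03
3.800000e+01 9.439453e-03
3.850000e+01 9.640567e-03
3.900000e+01 9.823214e-03
3.950000e+01 9.988889e-03
4.000000e+01 1.013621e-02
4.050000e+01 1.026729e-02
4.100000e+01 1.038082e-02
4.150000e+01 1.047895e-02
4.200000e+01 1.056034e-02
4.250000e+01 1.062721e-02
4.300000e+01 1.067830e-02
4.350000e+01 1.071581e-02
4.400000e+01 1.073870e-02
4.450000e+01 1.074889e-02
4.500000e+01 1.074577e-02
4.550000e+01 1.073078e-02
4.600000e+01 1.070391e-02
4.650000e+01 1.066591e-02
4.700000e+01 1.061750e-02
4.750000e+01 1.055862e-02
4.800000e+01 1.049084e-02
4.850000e+01 1.041314e-02
4.900000e+01 1.032756e-02
4.950000e+01 1.023351e-02
5.000000e+01 1.013201e-02
5.050000e+01 1.002359e-02
5.100000e+01 9.908078e-03
5.150000e+01 9.786820e-03
5.200000e+01 9.659218e-03
5.250000e+01 9.526395e-03
5.300000e+01 9.388600e-03
5.350000e+01 9.245686e-03
5.400000e+01 9.098782e-03
5.450000e+01 8.947466e-03
5.500000e+01 8.792444e-03
5.550000e+01 8.634263e-03
5.600000e+01 8.472308e-03
5.650000e+01 8.307761e-03
5.700000e+01 8.140561e-03
5.750000e+01 7.970643e-03
5.800000e+01 8.870386e-02
5.850000e+01 7.624816e-03
5.900000e+01 7.448952e-03
5.950000e+01 1.529749e-01
6.000000e+01 7.092877e-03
6.050000e+01 6.912796e-03
6.100000e+01 6.731851e-03
6.150000e+01 6.549741e-03
6.200000e+01 6.366919e-03
6.250000e+01 6.183638e-03
6.300000e+01 5.999628e-03
6.350000e+01 5.815288e-03
6.400000e+01 5.630827e-03
6.450000e+01 5.446037e-03
6.500000e+01 5.261201e-03
6.550000e+01 5.076527e-03
6.600000e+01 4.891883e-03
6.650000e+01 4.707406e-03
6.700000e+01 5.763260e-02
6.750000e+01 4.339584e-03
6.800000e+01 4.156170e-03
6.850000e+01 3.973339e-03
6.900000e+01 1.856637e-02
6.950000e+01 3.609355e-03
7.000000e+01 3.428321e-03
7.050000e+01 3.248057e-03
7.100000e+01 3.068470e-03
7.150000e+01 2.889674e-03
7.200000e+01 2.711763e-03
7.250000e+01 2.534731e-03
7.300000e+01 2.358525e-03
7.350000e+01 2.183295e-03
7.400000e+01 2.009057e-03
7.450000e+01 1.835761e-03
7.500000e+01 1.663470e-03
7.550000e+01 1.492235e-03
7.600000e+01 1.322065e-03
7.650000e+01 1.152912e-03
7.700000e+01 9.848621e-04
7.750000e+01 8.179209e-04
7.800000e+01 6.520841e-04
7.850000e+01 4.873543e-04
7.900000e+01 3.237625e-04
7.950000e+01 1.613107e-04
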