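{
 "model": "F(q,Z) = Z/(1+(b*q)^2)^2, q in 1/Angstrom",
 "beta_angstrom": 0.41,
 "elements": {
  "H": {
   "Z": 1,
   "A": 1.008,
   "b_angstrom": 0.41
  },
  "C": {
   "Z": 6,
   "A": 12.011,
   "b_angstrom": 0.2256316953411328
  },
  "N": {
   "Z": 7,
   "A": 14.007,
   "b_angstrom": 0.21433076301563117
  },
  "O": {
   "Z": 8,
   "A": 15.999,
   "b_angstrom": 0.205
  },
  "Al": {
   "Z": 13,
   "A": 26.9815,
   "b_angstrom": 0.17436905181602597
  },
  "P": {
   "Z": 15,
   "A": 30.974,
   "b_angstrom": 0.16624685454567295
  },
  "Ar": {
   "Z": 18,
   "A": 39.948,
   "b_angstrom": 0.156444279815622
  },
  "Cu": {
   "Z": 29,
   "A": 63.546,
   "b_angstrom": 0.13344977854244372
  }
 }
}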