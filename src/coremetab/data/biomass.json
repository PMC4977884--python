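{
 "comment": "Twelve central-carbon biomass precursors with classic E. coli flux-balance coefficients (mmol per gDW); CoA thioesters return free CoA; cofactor terms: ATP hydrolyzed, NADPH consumed, NADH released (negative = released).",
 "precursors": [
  {"compound": "g6p_c", "coefficient": 0.205},
  {"compound": "f6p_c", "coefficient": 0.071},
  {"compound": "r5p_c", "coefficient": 0.898},
  {"compound": "e4p_c", "coefficient": 0.361},
  {"compound": "g3p_c", "coefficient": 0.129},
  {"compound": "3pg_c", "coefficient": 1.496},
  {"compound": "pep_c", "coefficient": 0.519},
  {"compound": "pyr_c", "coefficient": 2.833},
  {"compound": "accoa_c", "coefficient": 3.748},
  {"compound": "akg_c", "coefficient": 1.079},
  {"compound": "oaa_c", "coefficient": 1.787},
  {"compound": "succoa_c", "coefficient": 0.1}
 ],
 "cofactors": {"atp": 41.257, "nadh": -3.547, "nadph": 18.225}
}
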