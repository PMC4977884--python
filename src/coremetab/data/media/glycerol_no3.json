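{
 "name": "glycerol_no3",
 "carbon_source": "glyc_e",
 "electron_acceptor": "no3_e",
 "exchange_bounds": {
  "h_e": [
   1000,
   1000
  ],
  "h2o_e": [
   1000,
   1000
  ],
  "co2_e": [
   1000,
   1000
  ],
  "nh4_e": [
   1000,
   1000
  ],
  "pi_e": [
   1000,
   1000
  ],
  "so4_e": [
   1000,
   1000
  ],
  "glyc_e": [
   10,
   0
  ],
  "no3_e": [
   1000,
   1000
  ]
 }
}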