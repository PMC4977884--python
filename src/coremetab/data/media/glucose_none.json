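{
 "name": "glucose_none",
 "carbon_source": "glc__D_e",
 "electron_acceptor": null,
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
  "glc__D_e": [
   10,
   0
  ]
 }
}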