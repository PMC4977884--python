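{
 "genome_id": "clostridium_like",
 "taxon_label": "Clostridium acetobutylicum-like",
 "seq_key": "16S:0003",
 "quality": 0.9,
 "reactions": [
  "ACACT1r",
  "ACALD",
  "ACKr",
  "ACt_out",
  "ADC",
  "ALCD2x",
  "ATPS4r",
  "BCD",
  "BTALDH",
  "BTOLDH",
  "BUK",
  "BUTt_out",
  "CTFAB",
  "ECOAH1",
  "ENO",
  "FBA",
  "G6PDH2r",
  "GAPD",
  "GLCpts",
  "GND",
  "HACD1",
  "HYDA",
  "LACt2r",
  "LDH_D",
  "PC",
  "PFK",
  "PFOR",
  "PGI",
  "PGK",
  "PGL",
  "PGM",
  "PTA",
  "PTB",
  "PYK",
  "RPE",
  "RPI",
  "TALA",
  "TKT1",
  "TKT2",
  "TPI"
 ],
 "pathways": {
  "glycolysis": true,
  "entner_doudoroff": false,
  "tca": false,
  "pentose_phosphate": true,
  "lactate": true,
  "acetate": true,
  "formate": false,
  "ethanol": true,
  "butanediol": false,
  "butyrate": true,
  "butanol": true,
  "acetone": true
 },
 "respiration": "none",
 "atp_yields": {},
 "notes": "Obligate fermenter: no respiratory chain; solventogenic ABE pathways."
}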