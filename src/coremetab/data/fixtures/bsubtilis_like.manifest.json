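{
 "genome_id": "bsubtilis_like",
 "taxon_label": "Bacillus subtilis-like",
 "seq_key": "16S:0002",
 "quality": 0.95,
 "reactions": [
  "ACALD",
  "ACKr",
  "ACONT",
  "ACt_out",
  "AKGDH",
  "ALCD2x",
  "ALDC",
  "ALS",
  "ATPS4r",
  "BTDD",
  "CS",
  "CYTBD",
  "ENO",
  "FBA",
  "FBP",
  "FUM",
  "G3PD7",
  "G6PDH2r",
  "GAPD",
  "GLCpts",
  "GLYK",
  "GND",
  "ICDHyr",
  "LACt2r",
  "LDH_D",
  "MDH",
  "NADH5",
  "NARK",
  "NTRAR",
  "PC",
  "PDH",
  "PFK",
  "PGI",
  "PGK",
  "PGL",
  "PGM",
  "PPCK",
  "PTA",
  "PYK",
  "RBK",
  "RIBt2",
  "RPE",
  "RPI",
  "SUCDi",
  "SUCOAS",
  "TALA",
  "TKT1",
  "TKT2",
  "TPI",
  "UDHA"
 ],
 "pathways": {
  "glycolysis": true,
  "entner_doudoroff": false,
  "tca": true,
  "pentose_phosphate": true,
  "lactate": true,
  "acetate": true,
  "formate": false,
  "ethanol": true,
  "butanediol": true,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "facultative",
 "atp_yields": {},
 "notes": "Labelled an obligate aerobe in the public domain, yet carries a nitrate respiratory chain; Gram-positive anaplerosis via pyruvate carboxylase."
}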