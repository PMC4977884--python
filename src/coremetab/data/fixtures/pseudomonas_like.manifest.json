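{
 "genome_id": "pseudomonas_like",
 "taxon_label": "Pseudomonas-like",
 "seq_key": "16S:0004",
 "quality": 0.92,
 "reactions": [
  "ACKr",
  "ACONT",
  "ACt_out",
  "AKGDH",
  "ATPS4r",
  "CS",
  "CYTBD",
  "CYTBO3",
  "EDA",
  "EDD",
  "ENO",
  "FBA",
  "FBP",
  "FUM",
  "G3PD7",
  "G6PDH2r",
  "GAPD",
  "GLCt2",
  "GLK",
  "GLYK",
  "ICDHyr",
  "LACD2",
  "LACt2r",
  "LDH_D",
  "MDH",
  "NADH16",
  "NARK",
  "NTRAR",
  "PDH",
  "PGI",
  "PGK",
  "PGL",
  "PGM",
  "PPC",
  "PPCK",
  "PTA",
  "PYK",
  "RPE",
  "RPI",
  "SUCCt2",
  "SUCCt_out",
  "SUCDi",
  "SUCOAS",
  "TALA",
  "THD2",
  "TKT1",
  "TKT2",
  "TPI",
  "UDHA"
 ],
 "pathways": {
  "glycolysis": false,
  "entner_doudoroff": true,
  "tca": true,
  "pentose_phosphate": false,
  "lactate": true,
  "acetate": true,
  "formate": false,
  "ethanol": false,
  "butanediol": false,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "facultative",
 "atp_yields": {},
 "notes": "Entner-Doudoroff glucose oxidation (no phosphofructokinase); denitrifier-style nitrate chain."
}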