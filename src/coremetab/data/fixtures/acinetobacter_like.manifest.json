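{
 "genome_id": "acinetobacter_like",
 "taxon_label": "Acinetobacter-like",
 "seq_key": "16S:0006",
 "quality": 0.88,
 "reactions": [
  "ACKr",
  "ACONT",
  "ACt_out",
  "AKGDH",
  "ATPS4r",
  "CS",
  "CYTBD",
  "EDA",
  "EDD",
  "ENO",
  "FBA",
  "FBP",
  "FUM",
  "G6PDH2r",
  "GAPD",
  "GLCt2",
  "GLK",
  "GND",
  "ICDHyr",
  "MDH",
  "NADH16",
  "PDH",
  "PGI",
  "PGK",
  "PGM",
  "PPC",
  "PPCK",
  "PTA",
  "PYK",
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
  "glycolysis": false,
  "entner_doudoroff": false,
  "tca": true,
  "pentose_phosphate": false,
  "lactate": false,
  "acetate": true,
  "formate": false,
  "ethanol": false,
  "butanediol": false,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "aerobic",
 "atp_yields": {},
 "notes": "All Entner-Doudoroff enzymes annotated except the gluconolactonase step, so the ED pathway is called absent (the lactone hydrolysis may in fact proceed spontaneously in vivo)."
}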