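{
 "genome_id": "ecoli_like",
 "taxon_label": "Escherichia coli K-12-like",
 "seq_key": "16S:0001",
 "quality": 0.99,
 "reactions": [
  "ACALD",
  "ACKr",
  "ACONT",
  "ACt_out",
  "AKGDH",
  "ALCD2x",
  "ATPS4r",
  "CS",
  "CYTBD",
  "CYTBO3",
  "EDA",
  "EDD",
  "ENO",
  "FBA",
  "FBP",
  "FORt_out",
  "FRD2",
  "FUM",
  "G3PD7",
  "G6PDH2r",
  "GAPD",
  "GLCpts",
  "GLCt2",
  "GLK",
  "GLYK",
  "GND",
  "ICDHyr",
  "LACD2",
  "LACt2r",
  "LDH_D",
  "MDH",
  "NADH16",
  "NADH5",
  "NARK",
  "NTRAR",
  "PDH",
  "PFK",
  "PFL",
  "PGI",
  "PGK",
  "PGL",
  "PGM",
  "PPC",
  "PPCK",
  "PTA",
  "PYK",
  "RBK",
  "RIBt2",
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
  "TMAOR",
  "TPI",
  "UDHA"
 ],
 "pathways": {
  "glycolysis": true,
  "entner_doudoroff": true,
  "tca": true,
  "pentose_phosphate": true,
  "lactate": true,
  "acetate": true,
  "formate": true,
  "ethanol": true,
  "butanediol": false,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "facultative",
 "atp_yields": {
  "glucose_o2": 26.5,
  "glucose_none": 2.75
 },
 "notes": "Facultative anaerobe; mixed-acid fermenter; full glucose-oxidation repertoire."
}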