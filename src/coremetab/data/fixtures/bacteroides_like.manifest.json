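{
 "genome_id": "bacteroides_like",
 "taxon_label": "Bacteroides-like obligate anaerobe",
 "seq_key": "16S:0007",
 "quality": 0.85,
 "reactions": [
  "ACALD",
  "ACKr",
  "ACt_out",
  "ALCD2x",
  "ATPS4r",
  "CYTBO3",
  "ENO",
  "FBA",
  "FORt_out",
  "G6PDH2r",
  "GAPD",
  "GLCpts",
  "GND",
  "LACt2r",
  "LDH_D",
  "NADH5",
  "PDH",
  "PFK",
  "PFL",
  "PGI",
  "PGK",
  "PGL",
  "PGM",
  "PTA",
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
  "formate": true,
  "ethanol": true,
  "butanediol": false,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "aerobic",
 "atp_yields": {},
 "notes": "Obligate anaerobe carrying a spurious generic ubiquinol-oxidase annotation, so it is classified aerobic; the phylogenetic outlier report is the intended catch for this error."
}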