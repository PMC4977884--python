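{
 "genome_id": "parasite_like",
 "taxon_label": "Mycoplasma-like reduced genome",
 "seq_key": "16S:0005",
 "quality": 0.6,
 "reactions": [
  "ACALD",
  "ACKr",
  "ACt_out",
  "ALCD2x",
  "ENO",
  "FBA",
  "GAPD",
  "GLCpts",
  "LACt2r",
  "LDH_D",
  "PDH",
  "PFK",
  "PGI",
  "PGK",
  "PGM",
  "PTA",
  "PYK",
  "TPI"
 ],
 "pathways": {
  "glycolysis": true,
  "entner_doudoroff": false,
  "tca": false,
  "pentose_phosphate": false,
  "lactate": true,
  "acetate": true,
  "formate": false,
  "ethanol": true,
  "butanediol": false,
  "butyrate": false,
  "butanol": false,
  "acetone": false
 },
 "respiration": "none",
 "atp_yields": {},
 "notes": "Parasite-style gene loss: no TCA cycle or pentose phosphate pathway, so several biomass precursors are unproducible and gapfilling is required."
}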