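{
 "glycolysis": [["PGI"], ["PFK"], ["FBA"], ["TPI"], ["GAPD"], ["PGK"], ["PGM"], ["ENO"], ["PYK"]],
 "entner_doudoroff": [["G6PDH2r"], ["PGL"], ["EDD"], ["EDA"]],
 "tca": [["CS"], ["ACONT"], ["ICDHyr"], ["AKGDH"], ["SUCOAS"], ["SUCDi", "FRD2"], ["FUM"], ["MDH"]],
 "pentose_phosphate": [["G6PDH2r"], ["PGL"], ["GND"], ["RPE"], ["RPI"], ["TKT1"], ["TALA"], ["TKT2"]],
 "lactate": [["LDH_D"], ["LACt2r"]],
 "acetate": [["PTA"], ["ACKr"], ["ACt_out"]],
 "formate": [["PFL"], ["FORt_out"]],
 "ethanol": [["ACALD"], ["ALCD2x"]],
 "butanediol": [["ALS"], ["ALDC"], ["BTDD"]],
 "butyrate": [["ACACT1r"], ["HACD1"], ["ECOAH1"], ["BCD"], ["PTB"], ["BUK"], ["BUTt_out"]],
 "butanol": [["ACACT1r"], ["HACD1"], ["ECOAH1"], ["BCD"], ["BTALDH"], ["BTOLDH"]],
 "acetone": [["ACACT1r"], ["CTFAB"], ["ADC"]]
}
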