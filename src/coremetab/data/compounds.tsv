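id	name	formula	charge	compartment
glc__D_c	D-Glucose	C6H12O6	0	cytosol
g6p_c	D-Glucose 6-phosphate	C6H11O9P	-2	cytosol
f6p_c	D-Fructose 6-phosphate	C6H11O9P	-2	cytosol
fdp_c	D-Fructose 1,6-bisphosphate	C6H10O12P2	-4	cytosol
dhap_c	Dihydroxyacetone phosphate	C3H5O6P	-2	cytosol
g3p_c	Glyceraldehyde 3-phosphate	C3H5O6P	-2	cytosol
13dpg_c	3-Phospho-D-glyceroyl phosphate	C3H4O10P2	-4	cytosol
3pg_c	3-Phospho-D-glycerate	C3H4O7P	-3	cytosol
2pg_c	2-Phospho-D-glycerate	C3H4O7P	-3	cytosol
pep_c	Phosphoenolpyruvate	C3H2O6P	-3	cytosol
pyr_c	Pyruvate	C3H3O3	-1	cytosol
6pgl_c	6-Phospho-D-glucono-1,5-lactone	C6H9O9P	-2	cytosol
6pgc_c	6-Phospho-D-gluconate	C6H10O10P	-3	cytosol
2ddg6p_c	2-Dehydro-3-deoxy-D-gluconate 6-phosphate	C6H8O9P	-3	cytosol
ru5p__D_c	D-Ribulose 5-phosphate	C5H9O8P	-2	cytosol
xu5p__D_c	D-Xylulose 5-phosphate	C5H9O8P	-2	cytosol
r5p_c	D-Ribose 5-phosphate	C5H9O8P	-2	cytosol
s7p_c	Sedoheptulose 7-phosphate	C7H13O10P	-2	cytosol
e4p_c	D-Erythrose 4-phosphate	C4H7O7P	-2	cytosol
rib__D_c	D-Ribose	C5H10O5	0	cytosol
accoa_c	Acetyl-CoA	C23H34N7O17P3S	-4	cytosol
coa_c	Coenzyme A	C21H32N7O16P3S	-4	cytosol
cit_c	Citrate	C6H5O7	-3	cytosol
icit_c	Isocitrate	C6H5O7	-3	cytosol
akg_c	2-Oxoglutarate	C5H4O5	-2	cytosol
succoa_c	Succinyl-CoA	C25H35N7O19P3S	-5	cytosol
succ_c	Succinate	C4H4O4	-2	cytosol
fum_c	Fumarate	C4H2O4	-2	cytosol
mal__L_c	L-Malate	C4H4O5	-2	cytosol
oaa_c	Oxaloacetate	C4H2O5	-2	cytosol
nad_c	Nicotinamide adenine dinucleotide	C21H26N7O14P2	-1	cytosol
nadh_c	Nicotinamide adenine dinucleotide - reduced	C21H27N7O14P2	-2	cytosol
nadp_c	Nicotinamide adenine dinucleotide phosphate	C21H25N7O17P3	-3	cytosol
nadph_c	Nicotinamide adenine dinucleotide phosphate - reduced	C21H26N7O17P3	-4	cytosol
atp_c	ATP	C10H12N5O13P3	-4	cytosol
adp_c	ADP	C10H12N5O10P2	-3	cytosol
pi_c	Phosphate	HO4P	-2	cytosol
q8_c	Ubiquinone-8	C49H74O4	0	cytosol
q8h2_c	Ubiquinol-8	C49H76O4	0	cytosol
h_c	H+	H	1	cytosol
h2o_c	H2O	H2O	0	cytosol
o2_c	O2	O2	0	cytosol
co2_c	CO2	CO2	0	cytosol
nh4_c	Ammonium	H4N	1	cytosol
so4_c	Sulfate	O4S	-2	cytosol
no3_c	Nitrate	NO3	-1	cytosol
no2_c	Nitrite	NO2	-1	cytosol
tmao_c	Trimethylamine N-oxide	C3H9NO	0	cytosol
tma_c	Trimethylamine	C3H10N	1	cytosol
lac__D_c	D-Lactate	C3H5O3	-1	cytosol
ac_c	Acetate	C2H3O2	-1	cytosol
actp_c	Acetyl phosphate	C2H3O5P	-2	cytosol
acald_c	Acetaldehyde	C2H4O	0	cytosol
etoh_c	Ethanol	C2H6O	0	cytosol
for_c	Formate	CHO2	-1	cytosol
alac__S_c	(S)-2-Acetolactate	C5H7O4	-1	cytosol
actn__R_c	(R)-Acetoin	C4H8O2	0	cytosol
btd__RR_c	(R,R)-2,3-Butanediol	C4H10O2	0	cytosol
aacoa_c	Acetoacetyl-CoA	C25H36N7O18P3S	-4	cytosol
3hbcoa_c	(S)-3-Hydroxybutyryl-CoA	C25H38N7O18P3S	-4	cytosol
b2coa_c	Crotonyl-CoA	C25H36N7O17P3S	-4	cytosol
btcoa_c	Butyryl-CoA	C25H38N7O17P3S	-4	cytosol
butp_c	Butyryl phosphate	C4H7O5P	-2	cytosol
but_c	Butyrate	C4H7O2	-1	cytosol
btal_c	Butyraldehyde	C4H8O	0	cytosol
btoh_c	1-Butanol	C4H10O	0	cytosol
acac_c	Acetoacetate	C4H5O3	-1	cytosol
act_c	Acetone	C3H6O	0	cytosol
glyc_c	Glycerol	C3H8O3	0	cytosol
glyc3p_c	Glycerol 3-phosphate	C3H7O6P	-2	cytosol
glc__D_e	D-Glucose	C6H12O6	0	extracellular
glyc_e	Glycerol	C3H8O3	0	extracellular
rib__D_e	D-Ribose	C5H10O5	0	extracellular
o2_e	O2	O2	0	extracellular
co2_e	CO2	CO2	0	extracellular
h_e	H+	H	1	extracellular
h2o_e	H2O	H2O	0	extracellular
nh4_e	Ammonium	H4N	1	extracellular
pi_e	Phosphate	HO4P	-2	extracellular
so4_e	Sulfate	O4S	-2	extracellular
no3_e	Nitrate	NO3	-1	extracellular
no2_e	Nitrite	NO2	-1	extracellular
tmao_e	Trimethylamine N-oxide	C3H9NO	0	extracellular
tma_e	Trimethylamine	C3H10N	1	extracellular
lac__D_e	D-Lactate	C3H5O3	-1	extracellular
ac_e	Acetate	C2H3O2	-1	extracellular
for_e	Formate	CHO2	-1	extracellular
etoh_e	Ethanol	C2H6O	0	extracellular
succ_e	Succinate	C4H4O4	-2	extracellular
btd__RR_e	(R,R)-2,3-Butanediol	C4H10O2	0	extracellular
but_e	Butyrate	C4H7O2	-1	extracellular
btoh_e	1-Butanol	C4H10O	0	extracellular
act_e	Acetone	C3H6O	0	extracellular
fdxo_c	Ferredoxin (oxidized)	Fe8S8	0	cytosol
fdxr_c	Ferredoxin (reduced)	Fe8S8	-1	cytosol
h2_c	Hydrogen	H2	0	cytosol
h2_e	Hydrogen	H2	0	extracellular
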