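ecoli_like	2-keto-3-deoxy-6-phosphogluconate aldolase (ec 4.1.2.14)
ecoli_like	2-oxoglutarate dehydrogenase e1 component (ec 1.2.4.2)
ecoli_like	6-phosphofructokinase (ec 2.7.1.11)
ecoli_like	6-phosphogluconate dehydrogenase, decarboxylating (ec 1.1.1.44)
ecoli_like	6-phosphogluconolactonase (ec 3.1.1.31)
ecoli_like	acetaldehyde dehydrogenase (ec 1.2.1.10)
ecoli_like	acetate kinase (ec 2.7.2.1)
ecoli_like	acetate permease actp
ecoli_like	aconitate hydratase (ec 4.2.1.3)
ecoli_like	aerobic c4-dicarboxylate transporter dcta
ecoli_like	alcohol dehydrogenase (ec 1.1.1.1)
ecoli_like	anaerobic c4-dicarboxylate transporter dcub
ecoli_like	atp synthase alpha chain (ec 3.6.3.14)
ecoli_like	atp synthase beta chain (ec 3.6.3.14)
ecoli_like	citrate synthase (si) (ec 2.3.3.1)
ecoli_like	cytochrome d ubiquinol oxidase subunit i (ec 1.10.3.-)
ecoli_like	cytochrome d ubiquinol oxidase subunit ii (ec 1.10.3.-)
ecoli_like	cytochrome o ubiquinol oxidase subunit i (ec 1.10.3.-)
ecoli_like	cytochrome o ubiquinol oxidase subunit ii (ec 1.10.3.-)
ecoli_like	d-lactate dehydrogenase (ec 1.1.1.28)
ecoli_like	d-lactate dehydrogenase, fad-binding (ec 1.1.99.6)
ecoli_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
ecoli_like	dihydrolipoamide succinyltransferase component (e2) of 2-oxoglutarate dehydrogenase complex (ec 2.3.1.61)
ecoli_like	enolase (ec 4.2.1.11)
ecoli_like	formate efflux transporter foca
ecoli_like	fructose-1,6-bisphosphatase, type i (ec 3.1.3.11)
ecoli_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
ecoli_like	fumarate hydratase class i (ec 4.2.1.2)
ecoli_like	fumarate reductase flavoprotein subunit (ec 1.3.5.4)
ecoli_like	galactose/glucose:h+ symporter galp
ecoli_like	glucokinase (ec 2.7.1.2)
ecoli_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
ecoli_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
ecoli_like	glycerol kinase (ec 2.7.1.30)
ecoli_like	glycerol-3-phosphate dehydrogenase (ec 1.1.5.3)
ecoli_like	isocitrate dehydrogenase [nadp] (ec 1.1.1.42)
ecoli_like	l-lactate permease lldp
ecoli_like	malate dehydrogenase (ec 1.1.1.37)
ecoli_like	nad(p) transhydrogenase subunit alpha (ec 1.6.1.2)
ecoli_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
ecoli_like	nadh dehydrogenase, type ii (ec 1.6.99.3)
ecoli_like	nadh-ubiquinone oxidoreductase chain a (ec 1.6.5.3)
ecoli_like	nadh-ubiquinone oxidoreductase chain l (ec 1.6.5.3)
ecoli_like	nitrate/nitrite antiporter nark
ecoli_like	phosphate acetyltransferase (ec 2.3.1.8)
ecoli_like	phosphoenolpyruvate carboxykinase [atp] (ec 4.1.1.49)
ecoli_like	phosphoenolpyruvate carboxylase (ec 4.1.1.31)
ecoli_like	phosphoenolpyruvate-protein phosphotransferase of pts system, enzyme i (ec 2.7.3.9)
ecoli_like	phosphogluconate dehydratase (ec 4.2.1.12)
ecoli_like	phosphoglycerate kinase (ec 2.7.2.3)
ecoli_like	phosphoglycerate mutase (ec 5.4.2.11)
ecoli_like	phosphotransferase system, glucose-specific iibc component (ec 2.7.1.69)
ecoli_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
ecoli_like	pyruvate formate-lyase (ec 2.3.1.54)
ecoli_like	pyruvate kinase (ec 2.7.1.40)
ecoli_like	respiratory nitrate reductase alpha chain (ec 1.7.99.4)
ecoli_like	respiratory nitrate reductase beta chain (ec 1.7.99.4)
ecoli_like	ribokinase (ec 2.7.1.15)
ecoli_like	ribose abc transport system, permease protein rbsc
ecoli_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
ecoli_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
ecoli_like	soluble pyridine nucleotide transhydrogenase (ec 1.6.1.1)
ecoli_like	succinate dehydrogenase flavoprotein subunit (ec 1.3.5.1)
ecoli_like	succinyl-coa ligase [adp-forming] alpha chain (ec 6.2.1.5)
ecoli_like	transaldolase (ec 2.2.1.2)
ecoli_like	transketolase (ec 2.2.1.1)
ecoli_like	trimethylamine-n-oxide reductase (ec 1.7.2.3)
ecoli_like	triosephosphate isomerase (ec 5.3.1.1)
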