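pseudomonas_like	2-keto-3-deoxy-6-phosphogluconate aldolase (ec 4.1.2.14)
pseudomonas_like	2-oxoglutarate dehydrogenase e1 component (ec 1.2.4.2)
pseudomonas_like	6-phosphogluconolactonase (ec 3.1.1.31)
pseudomonas_like	acetate kinase (ec 2.7.2.1)
pseudomonas_like	acetate permease actp
pseudomonas_like	aconitate hydratase (ec 4.2.1.3)
pseudomonas_like	aerobic c4-dicarboxylate transporter dcta
pseudomonas_like	anaerobic c4-dicarboxylate transporter dcub
pseudomonas_like	atp synthase alpha chain (ec 3.6.3.14)
pseudomonas_like	atp synthase beta chain (ec 3.6.3.14)
pseudomonas_like	citrate synthase (si) (ec 2.3.3.1)
pseudomonas_like	cytochrome d ubiquinol oxidase subunit i (ec 1.10.3.-)
pseudomonas_like	cytochrome d ubiquinol oxidase subunit ii (ec 1.10.3.-)
pseudomonas_like	cytochrome o ubiquinol oxidase subunit i (ec 1.10.3.-)
pseudomonas_like	cytochrome o ubiquinol oxidase subunit ii (ec 1.10.3.-)
pseudomonas_like	d-lactate dehydrogenase (ec 1.1.1.28)
pseudomonas_like	d-lactate dehydrogenase, fad-binding (ec 1.1.99.6)
pseudomonas_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
pseudomonas_like	dihydrolipoamide succinyltransferase component (e2) of 2-oxoglutarate dehydrogenase complex (ec 2.3.1.61)
pseudomonas_like	enolase (ec 4.2.1.11)
pseudomonas_like	fructose-1,6-bisphosphatase, type i (ec 3.1.3.11)
pseudomonas_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
pseudomonas_like	fumarate hydratase class i (ec 4.2.1.2)
pseudomonas_like	galactose/glucose:h+ symporter galp
pseudomonas_like	glucokinase (ec 2.7.1.2)
pseudomonas_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
pseudomonas_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
pseudomonas_like	glycerol kinase (ec 2.7.1.30)
pseudomonas_like	glycerol-3-phosphate dehydrogenase (ec 1.1.5.3)
pseudomonas_like	isocitrate dehydrogenase [nadp] (ec 1.1.1.42)
pseudomonas_like	l-lactate permease lldp
pseudomonas_like	malate dehydrogenase (ec 1.1.1.37)
pseudomonas_like	nad(p) transhydrogenase subunit alpha (ec 1.6.1.2)
pseudomonas_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
pseudomonas_like	nadh-ubiquinone oxidoreductase chain a (ec 1.6.5.3)
pseudomonas_like	nadh-ubiquinone oxidoreductase chain l (ec 1.6.5.3)
pseudomonas_like	nitrate/nitrite antiporter nark
pseudomonas_like	phosphate acetyltransferase (ec 2.3.1.8)
pseudomonas_like	phosphoenolpyruvate carboxykinase [atp] (ec 4.1.1.49)
pseudomonas_like	phosphoenolpyruvate carboxylase (ec 4.1.1.31)
pseudomonas_like	phosphogluconate dehydratase (ec 4.2.1.12)
pseudomonas_like	phosphoglycerate kinase (ec 2.7.2.3)
pseudomonas_like	phosphoglycerate mutase (ec 5.4.2.11)
pseudomonas_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
pseudomonas_like	pyruvate kinase (ec 2.7.1.40)
pseudomonas_like	respiratory nitrate reductase alpha chain (ec 1.7.99.4)
pseudomonas_like	respiratory nitrate reductase beta chain (ec 1.7.99.4)
pseudomonas_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
pseudomonas_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
pseudomonas_like	soluble pyridine nucleotide transhydrogenase (ec 1.6.1.1)
pseudomonas_like	succinate dehydrogenase flavoprotein subunit (ec 1.3.5.1)
pseudomonas_like	succinyl-coa ligase [adp-forming] alpha chain (ec 6.2.1.5)
pseudomonas_like	transaldolase (ec 2.2.1.2)
pseudomonas_like	transketolase (ec 2.2.1.1)
pseudomonas_like	triosephosphate isomerase (ec 5.3.1.1)
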