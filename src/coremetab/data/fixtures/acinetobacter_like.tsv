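acinetobacter_like	2-keto-3-deoxy-6-phosphogluconate aldolase (ec 4.1.2.14)
acinetobacter_like	2-oxoglutarate dehydrogenase e1 component (ec 1.2.4.2)
acinetobacter_like	6-phosphogluconate dehydrogenase, decarboxylating (ec 1.1.1.44)
acinetobacter_like	acetate kinase (ec 2.7.2.1)
acinetobacter_like	acetate permease actp
acinetobacter_like	aconitate hydratase (ec 4.2.1.3)
acinetobacter_like	atp synthase alpha chain (ec 3.6.3.14)
acinetobacter_like	atp synthase beta chain (ec 3.6.3.14)
acinetobacter_like	citrate synthase (si) (ec 2.3.3.1)
acinetobacter_like	cytochrome d ubiquinol oxidase subunit i (ec 1.10.3.-)
acinetobacter_like	cytochrome d ubiquinol oxidase subunit ii (ec 1.10.3.-)
acinetobacter_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
acinetobacter_like	dihydrolipoamide succinyltransferase component (e2) of 2-oxoglutarate dehydrogenase complex (ec 2.3.1.61)
acinetobacter_like	enolase (ec 4.2.1.11)
acinetobacter_like	fructose-1,6-bisphosphatase, type i (ec 3.1.3.11)
acinetobacter_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
acinetobacter_like	fumarate hydratase class i (ec 4.2.1.2)
acinetobacter_like	galactose/glucose:h+ symporter galp
acinetobacter_like	glucokinase (ec 2.7.1.2)
acinetobacter_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
acinetobacter_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
acinetobacter_like	isocitrate dehydrogenase [nadp] (ec 1.1.1.42)
acinetobacter_like	malate dehydrogenase (ec 1.1.1.37)
acinetobacter_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
acinetobacter_like	nadh-ubiquinone oxidoreductase chain a (ec 1.6.5.3)
acinetobacter_like	nadh-ubiquinone oxidoreductase chain l (ec 1.6.5.3)
acinetobacter_like	phosphate acetyltransferase (ec 2.3.1.8)
acinetobacter_like	phosphoenolpyruvate carboxykinase [atp] (ec 4.1.1.49)
acinetobacter_like	phosphoenolpyruvate carboxylase (ec 4.1.1.31)
acinetobacter_like	phosphogluconate dehydratase (ec 4.2.1.12)
acinetobacter_like	phosphoglycerate kinase (ec 2.7.2.3)
acinetobacter_like	phosphoglycerate mutase (ec 5.4.2.11)
acinetobacter_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
acinetobacter_like	pyruvate kinase (ec 2.7.1.40)
acinetobacter_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
acinetobacter_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
acinetobacter_like	soluble pyridine nucleotide transhydrogenase (ec 1.6.1.1)
acinetobacter_like	succinate dehydrogenase flavoprotein subunit (ec 1.3.5.1)
acinetobacter_like	succinyl-coa ligase [adp-forming] alpha chain (ec 6.2.1.5)
acinetobacter_like	transaldolase (ec 2.2.1.2)
acinetobacter_like	transketolase (ec 2.2.1.1)
acinetobacter_like	triosephosphate isomerase (ec 5.3.1.1)
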