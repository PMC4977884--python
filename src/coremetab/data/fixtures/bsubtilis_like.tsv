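bsubtilis_like	2,3-butanediol dehydrogenase (ec 1.1.1.4)
bsubtilis_like	2-oxoglutarate dehydrogenase e1 component (ec 1.2.4.2)
bsubtilis_like	6-phosphofructokinase (ec 2.7.1.11)
bsubtilis_like	6-phosphogluconate dehydrogenase, decarboxylating (ec 1.1.1.44)
bsubtilis_like	6-phosphogluconolactonase (ec 3.1.1.31)
bsubtilis_like	acetaldehyde dehydrogenase (ec 1.2.1.10)
bsubtilis_like	acetate kinase (ec 2.7.2.1)
bsubtilis_like	acetate permease actp
bsubtilis_like	acetolactate synthase large subunit (ec 2.2.1.6)
bsubtilis_like	aconitate hydratase (ec 4.2.1.3)
bsubtilis_like	alcohol dehydrogenase (ec 1.1.1.1)
bsubtilis_like	alpha-acetolactate decarboxylase (ec 4.1.1.5)
bsubtilis_like	atp synthase alpha chain (ec 3.6.3.14)
bsubtilis_like	atp synthase beta chain (ec 3.6.3.14)
bsubtilis_like	citrate synthase (si) (ec 2.3.3.1)
bsubtilis_like	cytochrome d ubiquinol oxidase subunit i (ec 1.10.3.-)
bsubtilis_like	cytochrome d ubiquinol oxidase subunit ii (ec 1.10.3.-)
bsubtilis_like	d-lactate dehydrogenase (ec 1.1.1.28)
bsubtilis_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
bsubtilis_like	dihydrolipoamide succinyltransferase component (e2) of 2-oxoglutarate dehydrogenase complex (ec 2.3.1.61)
bsubtilis_like	enolase (ec 4.2.1.11)
bsubtilis_like	fructose-1,6-bisphosphatase, type i (ec 3.1.3.11)
bsubtilis_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
bsubtilis_like	fumarate hydratase class i (ec 4.2.1.2)
bsubtilis_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
bsubtilis_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
bsubtilis_like	glycerol kinase (ec 2.7.1.30)
bsubtilis_like	glycerol-3-phosphate dehydrogenase (ec 1.1.5.3)
bsubtilis_like	isocitrate dehydrogenase [nadp] (ec 1.1.1.42)
bsubtilis_like	l-lactate permease lldp
bsubtilis_like	malate dehydrogenase (ec 1.1.1.37)
bsubtilis_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
bsubtilis_like	nadh dehydrogenase, type ii (ec 1.6.99.3)
bsubtilis_like	nitrate/nitrite antiporter nark
bsubtilis_like	phosphate acetyltransferase (ec 2.3.1.8)
bsubtilis_like	phosphoenolpyruvate carboxykinase [atp] (ec 4.1.1.49)
bsubtilis_like	phosphoenolpyruvate-protein phosphotransferase of pts system, enzyme i (ec 2.7.3.9)
bsubtilis_like	phosphoglycerate kinase (ec 2.7.2.3)
bsubtilis_like	phosphoglycerate mutase (ec 5.4.2.11)
bsubtilis_like	phosphotransferase system, glucose-specific iibc component (ec 2.7.1.69)
bsubtilis_like	pyruvate carboxylase (ec 6.4.1.1)
bsubtilis_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
bsubtilis_like	pyruvate kinase (ec 2.7.1.40)
bsubtilis_like	respiratory nitrate reductase alpha chain (ec 1.7.99.4)
bsubtilis_like	respiratory nitrate reductase beta chain (ec 1.7.99.4)
bsubtilis_like	ribokinase (ec 2.7.1.15)
bsubtilis_like	ribose abc transport system, permease protein rbsc
bsubtilis_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
bsubtilis_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
bsubtilis_like	soluble pyridine nucleotide transhydrogenase (ec 1.6.1.1)
bsubtilis_like	succinate dehydrogenase flavoprotein subunit (ec 1.3.5.1)
bsubtilis_like	succinyl-coa ligase [adp-forming] alpha chain (ec 6.2.1.5)
bsubtilis_like	transaldolase (ec 2.2.1.2)
bsubtilis_like	transketolase (ec 2.2.1.1)
bsubtilis_like	triosephosphate isomerase (ec 5.3.1.1)
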