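clostridium_like	3-hydroxybutyryl-coa dehydratase (ec 4.2.1.55)
clostridium_like	3-hydroxybutyryl-coa dehydrogenase (ec 1.1.1.157)
clostridium_like	6-phosphofructokinase (ec 2.7.1.11)
clostridium_like	6-phosphogluconate dehydrogenase, decarboxylating (ec 1.1.1.44)
clostridium_like	6-phosphogluconolactonase (ec 3.1.1.31)
clostridium_like	acetaldehyde dehydrogenase (ec 1.2.1.10)
clostridium_like	acetate kinase (ec 2.7.2.1)
clostridium_like	acetate permease actp
clostridium_like	acetoacetate decarboxylase (ec 4.1.1.4)
clostridium_like	acetyl-coa acetyltransferase (ec 2.3.1.9)
clostridium_like	alcohol dehydrogenase (ec 1.1.1.1)
clostridium_like	atp synthase alpha chain (ec 3.6.3.14)
clostridium_like	atp synthase beta chain (ec 3.6.3.14)
clostridium_like	butyraldehyde dehydrogenase (ec 1.2.1.57)
clostridium_like	butyrate kinase (ec 2.7.2.7)
clostridium_like	butyrate-acetoacetate coa-transferase subunit a (ec 2.8.3.9)
clostridium_like	butyrate-acetoacetate coa-transferase subunit b (ec 2.8.3.9)
clostridium_like	butyrate:h+ symporter atoe
clostridium_like	butyryl-coa dehydrogenase (ec 1.3.99.2)
clostridium_like	d-lactate dehydrogenase (ec 1.1.1.28)
clostridium_like	enolase (ec 4.2.1.11)
clostridium_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
clostridium_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
clostridium_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
clostridium_like	iron-only hydrogenase, large subunit (ec 1.12.7.2)
clostridium_like	l-lactate permease lldp
clostridium_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
clostridium_like	nadh-dependent butanol dehydrogenase a (ec 1.1.1.-)
clostridium_like	phosphate acetyltransferase (ec 2.3.1.8)
clostridium_like	phosphate butyryltransferase (ec 2.3.1.19)
clostridium_like	phosphoenolpyruvate-protein phosphotransferase of pts system, enzyme i (ec 2.7.3.9)
clostridium_like	phosphoglycerate kinase (ec 2.7.2.3)
clostridium_like	phosphoglycerate mutase (ec 5.4.2.11)
clostridium_like	phosphotransferase system, glucose-specific iibc component (ec 2.7.1.69)
clostridium_like	pyruvate carboxylase (ec 6.4.1.1)
clostridium_like	pyruvate kinase (ec 2.7.1.40)
clostridium_like	pyruvate:ferredoxin oxidoreductase (ec 1.2.7.1)
clostridium_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
clostridium_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
clostridium_like	transaldolase (ec 2.2.1.2)
clostridium_like	transketolase (ec 2.2.1.1)
clostridium_like	triosephosphate isomerase (ec 5.3.1.1)
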