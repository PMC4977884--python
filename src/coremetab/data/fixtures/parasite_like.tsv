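parasite_like	6-phosphofructokinase (ec 2.7.1.11)
parasite_like	acetaldehyde dehydrogenase (ec 1.2.1.10)
parasite_like	acetate kinase (ec 2.7.2.1)
parasite_like	acetate permease actp
parasite_like	alcohol dehydrogenase (ec 1.1.1.1)
parasite_like	d-lactate dehydrogenase (ec 1.1.1.28)
parasite_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
parasite_like	enolase (ec 4.2.1.11)
parasite_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
parasite_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
parasite_like	l-lactate permease lldp
parasite_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
parasite_like	phosphate acetyltransferase (ec 2.3.1.8)
parasite_like	phosphoenolpyruvate-protein phosphotransferase of pts system, enzyme i (ec 2.7.3.9)
parasite_like	phosphoglycerate kinase (ec 2.7.2.3)
parasite_like	phosphoglycerate mutase (ec 5.4.2.11)
parasite_like	phosphotransferase system, glucose-specific iibc component (ec 2.7.1.69)
parasite_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
parasite_like	pyruvate kinase (ec 2.7.1.40)
parasite_like	triosephosphate isomerase (ec 5.3.1.1)
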