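bacteroides_like	6-phosphofructokinase (ec 2.7.1.11)
bacteroides_like	6-phosphogluconate dehydrogenase, decarboxylating (ec 1.1.1.44)
bacteroides_like	6-phosphogluconolactonase (ec 3.1.1.31)
bacteroides_like	acetaldehyde dehydrogenase (ec 1.2.1.10)
bacteroides_like	acetate kinase (ec 2.7.2.1)
bacteroides_like	acetate permease actp
bacteroides_like	alcohol dehydrogenase (ec 1.1.1.1)
bacteroides_like	atp synthase alpha chain (ec 3.6.3.14)
bacteroides_like	atp synthase beta chain (ec 3.6.3.14)
bacteroides_like	d-lactate dehydrogenase (ec 1.1.1.28)
bacteroides_like	dihydrolipoamide acetyltransferase component of pyruvate dehydrogenase complex (ec 2.3.1.12)
bacteroides_like	enolase (ec 4.2.1.11)
bacteroides_like	formate efflux transporter foca
bacteroides_like	fructose-bisphosphate aldolase class ii (ec 4.1.2.13)
bacteroides_like	glucose-6-phosphate 1-dehydrogenase (ec 1.1.1.49)
bacteroides_like	glucose-6-phosphate isomerase (ec 5.3.1.9)
bacteroides_like	l-lactate permease lldp
bacteroides_like	nad-dependent glyceraldehyde-3-phosphate dehydrogenase (ec 1.2.1.12)
bacteroides_like	nadh dehydrogenase, type ii (ec 1.6.99.3)
bacteroides_like	phosphate acetyltransferase (ec 2.3.1.8)
bacteroides_like	phosphoenolpyruvate-protein phosphotransferase of pts system, enzyme i (ec 2.7.3.9)
bacteroides_like	phosphoglycerate kinase (ec 2.7.2.3)
bacteroides_like	phosphoglycerate mutase (ec 5.4.2.11)
bacteroides_like	phosphotransferase system, glucose-specific iibc component (ec 2.7.1.69)
bacteroides_like	pyruvate dehydrogenase e1 component (ec 1.2.4.1)
bacteroides_like	pyruvate formate-lyase (ec 2.3.1.54)
bacteroides_like	pyruvate kinase (ec 2.7.1.40)
bacteroides_like	ribose-5-phosphate isomerase a (ec 5.3.1.6)
bacteroides_like	ribulose-phosphate 3-epimerase (ec 5.1.3.1)
bacteroides_like	transaldolase (ec 2.2.1.2)
bacteroides_like	transketolase (ec 2.2.1.1)
bacteroides_like	triosephosphate isomerase (ec 5.3.1.1)
bacteroides_like	ubiquinol cytochrome oxidase
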