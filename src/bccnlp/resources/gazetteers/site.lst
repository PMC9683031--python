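cheek	site	cheek	
nose	site	nose	
nasal tip	site	nasal_tip	
forehead	site	forehead	
temple	site	temple	
scalp	site	scalp	
ear	site	ear	
neck	site	neck	
back	site	back	
chest	site	chest	
shoulder	site	shoulder	
arm	site	arm	
hand	site	hand	
leg	site	leg	
eyebrow	site	eyebrow	
lip	site	lip	
chin	site	chin	
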