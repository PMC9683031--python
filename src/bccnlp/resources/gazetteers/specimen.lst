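skin ellipse	specimen_type	ellipse	
ellipse of skin	specimen_type	ellipse	
punch biopsy	specimen_type	punch	
shave biopsy	specimen_type	shave	
incisional biopsy	specimen_type	incisional	
curettings	specimen_type	curettings	
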