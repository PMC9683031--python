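lesion	lesion_kw	lesion	
nodule	lesion_kw	nodule	
papule	lesion_kw	papule	
plaque	lesion_kw	plaque	
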