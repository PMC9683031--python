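dermatology	department	dermatology	
plastic surgery	department	plastic_surgery	
general practice	department	general_practice	
oncology	department	oncology	
maxillofacial surgery	department	maxillofacial_surgery	
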