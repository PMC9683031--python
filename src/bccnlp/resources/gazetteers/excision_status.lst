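completely excised	excision_status	complete	
excision appears complete	excision_status	complete	
excision complete	excision_status	complete	
incompletely excised	excision_status	incomplete	
margins involved	excision_status	incomplete	
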