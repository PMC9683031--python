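accession no	field_label	accession	
accession number	field_label	accession	
lab no	field_label	accession	
lab number	field_label	accession	
excision date	field_label	excision_date	
date of excision	field_label	excision_date	
requested by	field_label	requestor	
requestor	field_label	requestor	
referring clinician	field_label	requestor	
authorised by	field_label	report	
reported by	field_label	report	
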