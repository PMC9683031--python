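# BCC diagnosis surface forms
basal cell carcinoma	diagnosis	bcc	C0007117
bcc	diagnosis	bcc	C0007117
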