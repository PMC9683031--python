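# prognostic factors / polarity targets
perineural invasion	prognostic	perineural_invasion	C0457193
lymphovascular invasion	prognostic	lymphovascular_invasion	
ulceration	prognostic	ulceration	C0041582
residual disease	prognostic	residual_disease	
residual tumour	prognostic	residual_disease	
tumour	prognostic	tumour	
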