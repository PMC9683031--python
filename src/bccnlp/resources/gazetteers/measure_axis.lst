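tumour thickness	measure_axis	thickness	
tumour diameter	measure_axis	diameter	
peripheral clearance	measure_axis	peripheral	
peripheral margin	measure_axis	peripheral	
deep clearance	measure_axis	deep	
deep margin	measure_axis	deep	
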