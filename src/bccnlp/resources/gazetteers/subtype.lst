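# WHO-derived BCC growth-pattern subtypes
nodular	subtype	nodular	C1710262
superficial	subtype	superficial	C1710547
infiltrative	subtype	infiltrative	C1334273
micronodular	subtype	micronodular	C1710319
morphoeic	subtype	morphoeic	C0334251
basosquamous	subtype	basosquamous	C0280807
cystic	subtype	cystic	
adenoid	subtype	adenoid	
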