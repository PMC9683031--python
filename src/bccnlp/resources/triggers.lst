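# ConText trigger lexicon: term<TAB>context<TAB>category:direction
no	context	negation:forward	
no evidence of	context	negation:forward	
without	context	negation:forward	
negative for	context	negation:forward	
free of	context	negation:forward	
not seen	context	negation:backward	
not identified	context	negation:backward	
absent	context	negation:backward	
confined	context	affirmation:backward	
present	context	affirmation:backward	
identified	context	affirmation:backward	
clear of	context	affirmation:forward	
well away from	context	affirmation:forward	
no increase	context	pseudo:forward	
no change	context	pseudo:forward	
but	context	termination:bidirectional	
however	context	termination:bidirectional	
apart from	context	termination:bidirectional	
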